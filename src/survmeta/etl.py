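"""Apply metadata to raw tables and filter cohorts.

Loading recodes every categorical column through its layer-3 dictionary and
coerces continuous columns to floats; anything unparseable or unmapped
becomes a missing cell and is reported, never silently dropped.  Filtering
implements conjunctive inclusion/exclusion criteria with first-failure
attribution so excluded subjects can be accounted to a specific criterion.

Missing values fail every criterion except ``missing`` / ``not-missing``;
complete-case elimination happens inside each downstream statistical
operation, not at load time.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CriterionError, LoadError
from .metadata import MetadataBundle


@dataclass
class CodedDataset:
    """Recoded, type-coerced analysis table.

    ``data`` holds one float column per layer-2 variable (categorical
    variables carry their integer codes, missing cells are NaN);
    ``missing_mask`` is the per-cell missingness indicator.
    """

    data: pd.DataFrame
    bundle: MetadataBundle
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        time_col = self.bundle.layer1.time_column
        event_col = self.bundle.layer1.event_column
        t = self.data[time_col]
        if (t.dropna() < 0).any():
            raise LoadError(f"negative values in time column {time_col!r}")
        ev = self.data[event_col].dropna()
        if not ev.isin([0, 1]).all():
            raise LoadError(f"event column {event_col!r} has codes outside {{0,1}}")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def subset(self, row_mask: pd.Series | np.ndarray) -> "CodedDataset":
        return CodedDataset(
            self.data.loc[row_mask].reset_index(drop=True),
            self.bundle,
            dict(self.provenance),
            list(self.warnings),
        )


def load_dataset(path: str | Path, bundle: MetadataBundle) -> CodedDataset:
    """Load a raw CSV under a metadata bundle into a :class:`CodedDataset`."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.rename(columns=bundle.layer1.rename_map)
    ds = code_table(raw, bundle)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    ds.provenance.update({"source": str(path), "sha256_16": digest})
    return ds


def code_table(raw: pd.DataFrame, bundle: MetadataBundle) -> CodedDataset:
    """Recode an in-memory raw (string) table through the bundle."""
    out: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    n = len(raw)
    for spec in bundle.layer2:
        if spec.name not in raw.columns:
            raise LoadError(f"layer-2 variable {spec.name!r} absent from the dataset")
        tokens = raw[spec.name].astype(str).str.strip()
        if spec.analysis_class == "continuous":
            vals = pd.to_numeric(tokens, errors="coerce")  # "" coerces to NaN
            n_bad = int((vals.isna() & (tokens != "")).sum())
            if n_bad:
                warnings.append(
                    f"{spec.name}: {n_bad} non-numeric value(s) treated as missing"
                )
            out[spec.name] = vals.to_numpy(dtype=float)
        else:
            cmap = bundle.category_map(spec.name)
            if cmap is None:
                raise LoadError(f"categorical variable {spec.name!r} has no layer-3 map")
            codes = np.full(n, np.nan)
            unmapped_rows: list[int] = []
            lut = {tok: e.code for e in cmap.entries for tok in e.labels}
            for i, tok in enumerate(tokens):
                if tok == "":
                    continue
                code = lut.get(tok)
                if code is None:
                    unmapped_rows.append(i)
                else:
                    codes[i] = code
            if unmapped_rows:
                warnings.append(
                    f"{spec.name}: {len(unmapped_rows)} unmapped token(s) treated as "
                    f"missing (rows {unmapped_rows[:10]}{'...' if len(unmapped_rows) > 10 else ''})"
                )
            out[spec.name] = codes
    return CodedDataset(pd.DataFrame(out), bundle, warnings=warnings)


def missing_report(ds: CodedDataset) -> pd.DataFrame:
    """Per-variable missingness: columns ``n_missing`` and ``fraction``."""
    mask = ds.missing_mask
    n = max(ds.n_rows, 1)
    return pd.DataFrame(
        {"n_missing": mask.sum(), "fraction": mask.sum() / n}
    )


# ---------------------------------------------------------------------------
# filtering

_ORDER_OPS = ("<", "<=", ">", ">=")
_OPS = ("==", "!=", "<=", ">=", "<", ">", "in", "not-in", "missing", "not-missing")

_CRIT_RE = re.compile(
    r"^\s*(?P<var>[A-Za-z_][A-Za-z0-9_.]*)\s*"
    r"(?P<op>==|!=|<=|>=|<|>|\s+not-in\s+|\s+in\s+|\s+not-missing\s*$|\s+missing\s*$)"
    r"(?P<val>.*)$"
)


@dataclass
class FilterCriterion:
    """One inclusion criterion: ``variable op value``.

    ``op`` is one of ``== != < <= > >= in not-in missing not-missing``;
    ``value`` is a number (or code) for scalar ops and a list of codes for
    ``in`` / ``not-in``.  Order comparisons are only legal on continuous
    variables.
    """

    variable: str
    op: str
    value: float | list[float] | None = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise CriterionError(f"unknown operator {self.op!r}")
        if self.op in ("in", "not-in"):
            if not isinstance(self.value, (list, tuple)) or not self.value:
                raise CriterionError(f"{self.op} requires a non-empty value list")
            self.value = [float(v) for v in self.value]
        elif self.op in ("missing", "not-missing"):
            self.value = None
        else:
            self.value = float(self.value)  # type: ignore[arg-type]

    @classmethod
    def parse(cls, text: str) -> "FilterCriterion":
        """Parse the CLI grammar, e.g. ``age<65`` or ``extent in 2,3``."""
        m = _CRIT_RE.match(text)
        if not m:
            raise CriterionError(f"cannot parse criterion {text!r}")
        var, op, val = m.group("var"), m.group("op").strip(), m.group("val").strip()
        if op in ("missing", "not-missing"):
            return cls(var, op)
        if op in ("in", "not-in"):
            return cls(var, op, [v.strip() for v in val.split(",") if v.strip()])
        return cls(var, op, val)

    def check_against(self, bundle: MetadataBundle) -> None:
        spec = bundle.variable(self.variable)
        if self.op in _ORDER_OPS and spec.analysis_class != "continuous":
            raise CriterionError(
                f"order comparison {self.op!r} illegal on categorical "
                f"variable {self.variable!r}"
            )

    def mask(self, ds: CodedDataset) -> np.ndarray:
        """Row-satisfaction mask; missing fails everything but the missing ops."""
        col = ds.column(self.variable).to_numpy(dtype=float)
        isna = np.isnan(col)
        if self.op == "missing":
            return isna
        if self.op == "not-missing":
            return ~isna
        with np.errstate(invalid="ignore"):
            if self.op == "==":
                ok = col == self.value
            elif self.op == "!=":
                ok = col != self.value
            elif self.op == "<":
                ok = col < self.value
            elif self.op == "<=":
                ok = col <= self.value
            elif self.op == ">":
                ok = col > self.value
            elif self.op == ">=":
                ok = col >= self.value
            elif self.op == "in":
                ok = np.isin(col, self.value)
            else:  # not-in
                ok = ~np.isin(col, self.value)
        ok[isna] = False
        return ok

    def __str__(self) -> str:
        if self.op in ("missing", "not-missing"):
            return f"{self.variable} {self.op}"
        if self.op in ("in", "not-in"):
            vals = ",".join(f"{v:g}" for v in self.value)  # type: ignore[union-attr]
            return f"{self.variable} {self.op} {vals}"
        return f"{self.variable}{self.op}{self.value:g}"


@dataclass
class FilterOutcome:
    """Result of applying an ordered conjunctive criteria list."""

    included: CodedDataset
    n_excluded_per_criterion: list[int]
    n_excluded_total: int
    criteria: list[FilterCriterion]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [str(c) for c in self.criteria],
                "n_excluded": self.n_excluded_per_criterion,
            }
        )


def apply_filters(
    ds: CodedDataset, criteria: Sequence[FilterCriterion]
) -> FilterOutcome:
    """Keep rows satisfying every criterion.

    Each excluded row is attributed to the FIRST criterion it fails, so the
    per-criterion counts sum to the total exclusions; the included set is
    independent of criterion order.
    """
    criteria = list(criteria)
    for c in criteria:
        c.check_against(ds.bundle)
    n = ds.n_rows
    keep = np.ones(n, dtype=bool)
    attributed = np.zeros(n, dtype=bool)
    per_criterion: list[int] = []
    for c in criteria:
        ok = c.mask(ds)
        newly = (~ok) & (~attributed)
        per_criterion.append(int(newly.sum()))
        attributed |= newly
        keep &= ok
    return FilterOutcome(
        included=ds.subset(keep),
        n_excluded_per_criterion=per_criterion,
        n_excluded_total=int((~keep).sum()),
        criteria=criteria,
    )
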