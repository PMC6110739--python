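"""Three-layer clinical metadata (codebook) format.

A dataset is described by three small CSV files:

* **layer 1** — roles of the standard columns: which raw column carries the
  observed time, which carries the event flag, an optional subject id, and
  any extra raw-name -> canonical-name aliases ("extend standard columns").
* **layer 2** — one row per variable giving its measurement scale
  (nominal / ordinal / interval / ratio) and its analysis role
  (time / event / covariate / stratifier / ignore).  Interval and ratio
  scales analyse as continuous; nominal and ordinal as categorical.
* **layer 3** — a dictionary for every categorical variable mapping sets of
  accepted raw tokens to integer codes, e.g. sex: {1, m, M} -> 1 "male",
  {0, f, F} -> 0 "female".

The canonical event coding after layer-3 mapping is 0 = censored/alive,
1 = event/dead.

File dialect (RFC-4180 CSV, UTF-8, header row):

* ``layer1.csv``: columns ``role,raw_column,canonical_name`` with roles
  ``time``, ``event``, ``id`` and ``extend``.
* ``layer2.csv``: columns ``name,measurement,role``.
* ``layer3.csv``: columns ``variable,code,tokens,display``; ``tokens`` is a
  pipe-separated list of accepted raw spellings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import MetadataError, SchemaError

MEASUREMENTS = ("nominal", "ordinal", "interval", "ratio")
ROLES = ("time", "event", "covariate", "stratifier", "ignore")

#: measurement scale -> binary analysis class; total and deterministic.
ANALYSIS_CLASS = {
    "nominal": "categorical",
    "ordinal": "categorical",
    "interval": "continuous",
    "ratio": "continuous",
}


@dataclass
class Layer1Roles:
    """Standard-column roles: time, event, optional id, extra aliases."""

    time_column: str
    event_column: str
    id_column: str | None = None
    #: ordered raw-name -> canonical-name aliases.
    extend_columns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_column == self.event_column:
            raise MetadataError(
                "time column and event column must differ "
                f"(both are {self.time_column!r})"
            )
        canon = list(self.extend_columns.values())
        if len(set(canon)) != len(canon):
            raise MetadataError("canonical names in extend_columns must be unique")

    @property
    def rename_map(self) -> dict[str, str]:
        """Raw -> canonical renaming applied when loading a dataset."""
        return dict(self.extend_columns)


@dataclass
class Layer2VariableSpec:
    """Measurement scale and analysis role of one variable."""

    name: str
    measurement: str
    role: str = "covariate"

    def __post_init__(self) -> None:
        if self.measurement not in MEASUREMENTS:
            raise MetadataError(
                f"variable {self.name!r}: unknown measurement {self.measurement!r}"
            )
        if self.role not in ROLES:
            raise MetadataError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.role == "time" and self.analysis_class != "continuous":
            raise MetadataError(
                f"time variable {self.name!r} must be interval or ratio"
            )
        if self.role == "event" and self.analysis_class != "categorical":
            raise MetadataError(
                f"event variable {self.name!r} must be nominal or ordinal"
            )

    @property
    def analysis_class(self) -> str:
        return ANALYSIS_CLASS[self.measurement]


@dataclass
class CategoryEntry:
    """One dictionary entry: accepted raw tokens -> integer code."""

    code: int
    labels: frozenset[str]
    display: str

    def __post_init__(self) -> None:
        self.code = int(self.code)
        self.labels = frozenset(str(t).strip() for t in self.labels)


@dataclass
class Layer3CategoryMap:
    """Token dictionary for one categorical variable."""

    variable: str
    entries: list[CategoryEntry]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.code)  # canonical order
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise SchemaError(
                f"layer3 variable {self.variable!r}: duplicate codes {codes}"
            )
        seen: dict[str, int] = {}
        for e in self.entries:
            for tok in e.labels:
                if tok in seen and seen[tok] != e.code:
                    raise SchemaError(
                        f"layer3 variable {self.variable!r}: token {tok!r} claimed "
                        f"by codes {seen[tok]} and {e.code}"
                    )
                seen[tok] = e.code

    def lookup(self, token: str) -> int | None:
        """Map a raw token to its code; whitespace-trimmed, case-sensitive."""
        tok = str(token).strip()
        for e in self.entries:
            if tok in e.labels:
                return e.code
        return None

    @property
    def codes(self) -> list[int]:
        return [e.code for e in self.entries]

    def display_of(self, code: int) -> str:
        for e in self.entries:
            if e.code == code:
                return e.display
        return str(code)


@dataclass
class MetadataBundle:
    """The full three-layer codebook governing one dataset."""

    layer1: Layer1Roles
    layer2: list[Layer2VariableSpec]
    layer3: list[Layer3CategoryMap]

    def __post_init__(self) -> None:
        names = [v.name for v in self.layer2]
        if len(set(names)) != len(names):
            raise MetadataError("duplicate variable names in layer 2")
        by_role = {"time": [], "event": []}
        for v in self.layer2:
            if v.role in by_role:
                by_role[v.role].append(v.name)
        for role, cols in by_role.items():
            if len(cols) != 1:
                raise MetadataError(
                    f"exactly one {role} variable required, found {cols or 'none'}"
                )
        if self.layer1.time_column != by_role["time"][0]:
            raise MetadataError(
                f"layer1 time column {self.layer1.time_column!r} does not match "
                f"layer2 time variable {by_role['time'][0]!r}"
            )
        if self.layer1.event_column != by_role["event"][0]:
            raise MetadataError(
                f"layer1 event column {self.layer1.event_column!r} does not match "
                f"layer2 event variable {by_role['event'][0]!r}"
            )
        known = set(names)
        for col in filter(None, [self.layer1.id_column]):
            if col not in known:
                raise MetadataError(f"layer1 id column {col!r} missing from layer 2")
        for col in self.layer1.extend_columns.values():
            if col not in known:
                raise MetadataError(
                    f"layer1 canonical column {col!r} missing from layer 2"
                )
        for m in self.layer3:
            if m.variable not in known:
                raise MetadataError(
                    f"layer3 variable {m.variable!r} missing from layer 2"
                )
            if self.variable(m.variable).analysis_class != "categorical":
                raise MetadataError(
                    f"layer3 variable {m.variable!r} is not categorical in layer 2"
                )

    def variable(self, name: str) -> Layer2VariableSpec:
        for v in self.layer2:
            if v.name == name:
                return v
        raise KeyError(name)

    def category_map(self, name: str) -> Layer3CategoryMap | None:
        for m in self.layer3:
            if m.variable == name:
                return m
        return None

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.layer2]

    def covariates(self) -> list[Layer2VariableSpec]:
        return [v for v in self.layer2 if v.role == "covariate"]


@dataclass
class ValidationReport:
    """Outcome of checking a bundle against a raw table."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, severity: str, variable: str, message: str) -> None:
        self.entries.append((severity, variable, message))

    @property
    def errors(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[0] == "error"]

    @property
    def warnings(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[0] == "warning"]

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        if not self.entries:
            return "metadata valid: no findings"
        lines = [f"[{sev}] {var}: {msg}" for sev, var, msg in self.entries]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reading / writing


def _read_rows(path: str | Path, expected: Sequence[str], layer: str) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{layer} file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != list(
            expected
        ):
            raise SchemaError(
                f"{layer} file {path} must have header {','.join(expected)}, "
                f"found {reader.fieldnames}"
            )
        return [
            {k: (v or "").strip() for k, v in row.items()} for row in reader
        ]


def read_metadata(
    layer1_path: str | Path,
    layer2_path: str | Path,
    layer3_path: str | Path,
) -> MetadataBundle:
    """Read the three layer CSVs into a validated :class:`MetadataBundle`."""
    l1_rows = _read_rows(layer1_path, ("role", "raw_column", "canonical_name"), "layer1")
    time_col = event_col = id_col = None
    extend: dict[str, str] = {}
    for i, row in enumerate(l1_rows, start=2):
        role, raw, canon = row["role"], row["raw_column"], row["canonical_name"]
        canon = canon or raw
        if role == "time":
            time_col = canon
        elif role == "event":
            event_col = canon
        elif role == "id":
            id_col = canon
        elif role == "extend":
            if raw in extend:
                raise SchemaError(f"layer1 row {i}: duplicate extend column {raw!r}")
            extend[raw] = canon
        else:
            raise SchemaError(f"layer1 row {i}: unknown role {role!r}")
    if time_col is None or event_col is None:
        raise SchemaError("layer1 must define one time row and one event row")
    layer1 = Layer1Roles(time_col, event_col, id_col, extend)

    l2_rows = _read_rows(layer2_path, ("name", "measurement", "role"), "layer2")
    layer2 = []
    for i, row in enumerate(l2_rows, start=2):
        try:
            layer2.append(
                Layer2VariableSpec(row["name"], row["measurement"], row["role"])
            )
        except MetadataError as exc:
            raise SchemaError(f"layer2 row {i}: {exc}") from exc

    l3_rows = _read_rows(layer3_path, ("variable", "code", "tokens", "display"), "layer3")
    grouped: dict[str, list[CategoryEntry]] = {}
    for i, row in enumerate(l3_rows, start=2):
        try:
            code = int(row["code"])
        except ValueError as exc:
            raise SchemaError(
                f"layer3 row {i}: code {row['code']!r} is not an integer"
            ) from exc
        tokens = [t for t in row["tokens"].split("|") if t != ""]
        if not tokens:
            raise SchemaError(f"layer3 row {i}: empty token list")
        grouped.setdefault(row["variable"], []).append(
            CategoryEntry(code, frozenset(tokens), row["display"] or str(code))
        )
    layer3 = [Layer3CategoryMap(var, entries) for var, entries in grouped.items()]
    return MetadataBundle(layer1, layer2, layer3)


def write_metadata(bundle: MetadataBundle, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write a bundle as layer1.csv / layer2.csv / layer3.csv under *out_dir*.

    Round-trips: ``read_metadata(*write_metadata(b, d))`` equals ``b``
    field for field.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p1, p2, p3 = out / "layer1.csv", out / "layer2.csv", out / "layer3.csv"

    with open(p1, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["role", "raw_column", "canonical_name"])
        w.writerow(["time", bundle.layer1.time_column, bundle.layer1.time_column])
        w.writerow(["event", bundle.layer1.event_column, bundle.layer1.event_column])
        if bundle.layer1.id_column:
            w.writerow(["id", bundle.layer1.id_column, bundle.layer1.id_column])
        for raw, canon in bundle.layer1.extend_columns.items():
            w.writerow(["extend", raw, canon])

    with open(p2, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "measurement", "role"])
        for v in bundle.layer2:
            w.writerow([v.name, v.measurement, v.role])

    with open(p3, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["variable", "code", "tokens", "display"])
        for m in bundle.layer3:
            for e in sorted(m.entries, key=lambda e: e.code):
                w.writerow([m.variable, e.code, "|".join(sorted(e.labels)), e.display])
    return p1, p2, p3


# ---------------------------------------------------------------------------
# automatic generation


def _is_numeric(series: pd.Series) -> bool:
    vals = series.astype(str).str.strip()
    vals = vals[vals != ""]
    if vals.empty:
        return False
    return pd.to_numeric(vals, errors="coerce").notna().all()


def generate_metadata(
    raw_table: pd.DataFrame,
    overrides: Mapping[str, Layer2VariableSpec] | None = None,
    *,
    time: str | None = None,
    event: str | None = None,
    max_levels: int = 6,
) -> MetadataBundle:
    """Infer a three-layer bundle from a raw table.

    Inference rule: a numeric column with more than *max_levels* distinct
    non-missing values is ratio/continuous; any other column is
    nominal/categorical and receives an auto-built layer-3 dictionary
    (numeric tokens keep their integer value as the code, other tokens are
    coded 0..k-1 in sorted order).  *overrides* win over inference.  The
    time and event columns default to ``TimeOS`` / ``EventDeath`` when
    present.
    """
    if raw_table.shape[0] < 1 or raw_table.shape[1] < 1:
        raise MetadataError("raw table must have at least one row and named columns")
    overrides = dict(overrides or {})
    for name in overrides:
        if name not in raw_table.columns:
            raise MetadataError(f"override references absent column {name!r}")

    if time is None:
        time = next((c for c in raw_table.columns if c == "TimeOS"), None)
    if event is None:
        event = next((c for c in raw_table.columns if c == "EventDeath"), None)
    if time is None or event is None:
        raise MetadataError(
            "cannot infer time/event columns: pass time=... and event=... "
            "(no TimeOS/EventDeath columns found)"
        )
    for col in (time, event):
        if col not in raw_table.columns:
            raise MetadataError(f"column {col!r} absent from table")

    layer2: list[Layer2VariableSpec] = []
    layer3: list[Layer3CategoryMap] = []
    for col in raw_table.columns:
        if col in overrides:
            spec = overrides[col]
        else:
            series = raw_table[col].astype(str).str.strip()
            nonmiss = series[series != ""]
            distinct = nonmiss.unique()
            numeric = _is_numeric(raw_table[col])
            if col == time:
                spec = Layer2VariableSpec(col, "ratio", "time")
            elif col == event:
                spec = Layer2VariableSpec(col, "nominal", "event")
            elif numeric and len(distinct) > max_levels:
                spec = Layer2VariableSpec(col, "ratio", "covariate")
            else:
                spec = Layer2VariableSpec(col, "nominal", "covariate")
        layer2.append(spec)
        if spec.analysis_class == "categorical":
            layer3.append(_auto_category_map(col, raw_table[col]))
    bundle = MetadataBundle(
        Layer1Roles(time, event), layer2, layer3
    )
    return bundle


def _auto_category_map(name: str, series: pd.Series) -> Layer3CategoryMap:
    tokens = series.astype(str).str.strip()
    tokens = sorted(tokens[tokens != ""].unique())
    entries = []
    if tokens and all(_int_like(t) for t in tokens):
        for t in sorted(tokens, key=lambda t: int(float(t))):
            entries.append(CategoryEntry(int(float(t)), frozenset({t}), t))
    else:
        for code, t in enumerate(tokens):
            entries.append(CategoryEntry(code, frozenset({t}), t))
    return Layer3CategoryMap(name, entries)


def _int_like(token: str) -> bool:
    try:
        return float(token) == int(float(token))
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# validation


def validate_metadata(bundle: MetadataBundle, raw_table: pd.DataFrame) -> ValidationReport:
    """Check a bundle against a raw table.

    Problems become report entries, never exceptions: unmapped categorical
    values and unparseable continuous values are errors; raw columns absent
    from layer 2 are warnings (they will be ignored on load).
    """
    report = ValidationReport()
    rename = bundle.layer1.rename_map
    renamed_cols = [rename.get(c, c) for c in raw_table.columns]
    if len(set(renamed_cols)) != len(renamed_cols):
        report.add("error", "<layer1>", "extend aliases collide with raw columns")

    table = raw_table.rename(columns=rename)
    known = set(bundle.variable_names)
    for col in table.columns:
        if col not in known:
            report.add("warning", col, "column not in layer 2; it will be ignored")
    for v in bundle.layer2:
        if v.name not in table.columns:
            report.add("error", v.name, "layer-2 variable absent from the dataset")
            continue
        series = table[v.name].astype(str).str.strip()
        observed = series[series != ""]
        if v.analysis_class == "categorical":
            cmap = bundle.category_map(v.name)
            if cmap is None:
                report.add("error", v.name, "categorical variable has no layer-3 map")
                continue
            unmapped = sorted(
                {tok for tok in observed.unique() if cmap.lookup(tok) is None}
            )
            for tok in unmapped:
                report.add("error", v.name, f"value {tok!r} not covered by layer-3 map")
            if v.role == "event":
                codes = set(cmap.codes)
                if not codes <= {0, 1}:
                    report.add(
                        "error", v.name,
                        f"event codes must be 0 (censored) / 1 (event), got {sorted(codes)}",
                    )
        else:
            bad = pd.to_numeric(observed, errors="coerce").isna()
            for tok in sorted(observed[bad].unique()):
                report.add("error", v.name, f"value {tok!r} is not numeric")
            if v.role == "time":
                num = pd.to_numeric(observed, errors="coerce")
                if (num < 0).any():
                    report.add("error", v.name, "negative survival times present")
    return report
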