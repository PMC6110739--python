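"""Baseline-characteristics ("Table 1") statistics with automatic test selection.

The selection flow is sequential and deterministic:

1. data type — continuous variables go to mean-comparison tests, categorical
   variables to contingency tests;
2. number of strata — two groups vs more than two;
3. normality — Shapiro-Wilk for n <= 5000, Anderson-Darling above, applied
   per group; the parametric branch requires every group to look normal;
4. method — normal: Welch t-test (2 groups) or one-way ANOVA (>2);
   non-normal: Wilcoxon rank-sum (2) or Kruskal-Wallis (>2); categorical:
   Pearson chi-square, with a Fisher exact fallback on 2x2 tables whenever
   an expected cell count drops below 5 (always flagged, never silent).

All tests are two-sided and run on complete cases per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .errors import (
    ComparisonImpossibleError,
    DegenerateGroupError,
    InsufficientDataError,
    StratifierTypeError,
)
from .etl import CodedDataset
from .metadata import Layer2VariableSpec, MetadataBundle

SW_MAX_N = 5000  # Shapiro-Wilk above this n loses accuracy; switch to AD
DEFAULT_ALPHA = 0.05


@dataclass
class NormalityResult:
    method: str  # shapiro_wilk | anderson_darling
    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA

    @property
    def is_normal(self) -> bool:
        return self.p_value >= self.alpha


@dataclass
class TestChoice:
    variable: str
    selected: str
    rationale: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    test: TestChoice
    statistic: float
    df: float | tuple | None
    p_value: float
    group_summaries: pd.DataFrame


@dataclass
class DemographicTable:
    """Stratified descriptive table plus per-variable comparison tests."""

    strat_variable: str
    group_levels: list[float]
    group_labels: dict[float, str]
    continuous_rows: dict[str, ComparisonResult]
    categorical_rows: dict[str, ComparisonResult]
    untestable: dict[str, str]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for var, res in self.continuous_rows.items():
            block = res.group_summaries.copy()
            block.insert(0, "variable", var)
            block.insert(0, "section", "continuous")
            block["test"] = res.test.selected
            block["statistic"] = res.statistic
            block["p_value"] = res.p_value
            frames.append(block)
        for var, res in self.categorical_rows.items():
            block = res.group_summaries.copy()
            block.insert(0, "variable", var)
            block.insert(0, "section", "categorical")
            block["test"] = res.test.selected
            block["statistic"] = res.statistic
            block["p_value"] = res.p_value
            frames.append(block)
        for var, reason in self.untestable.items():
            frames.append(
                pd.DataFrame(
                    {"section": ["untestable"], "variable": [var], "test": [reason]}
                )
            )
        if not frames:
            return pd.DataFrame(columns=["section", "variable"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# normality


def test_normality(
    values, method: str | None = None, alpha: float = DEFAULT_ALPHA
) -> NormalityResult:
    """Test a sample for normality.

    ``method`` is ``shapiro_wilk``, ``anderson_darling`` or None for
    automatic routing (SW for 3 <= n <= 5000, AD for larger samples).
    A constant sample is reported as decisively non-normal (p = 0).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"normality test needs >= 3 values, got {n}")
    if method is None:
        method = "shapiro_wilk" if n <= SW_MAX_N else "anderson_darling"
    if np.ptp(x) == 0:
        return NormalityResult(method, float("nan"), 0.0, alpha)
    if method == "shapiro_wilk":
        stat, p = stats.shapiro(x)
    elif method == "anderson_darling":
        stat, p = normal_ad(x)
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return NormalityResult(method, float(stat), float(p), alpha)


# ---------------------------------------------------------------------------
# test selection


def select_test(
    spec: Layer2VariableSpec | str,
    n_groups: int,
    normality: NormalityResult | bool | None = None,
) -> TestChoice:
    """Map (analysis class, #groups, normality) to a test, with a trace.

    ``normality`` may be a :class:`NormalityResult`, a plain bool, or None
    (only legal for categorical variables, where normality is irrelevant).
    """
    if n_groups < 2:
        raise ComparisonImpossibleError("need >= 2 groups to compare")
    if isinstance(spec, Layer2VariableSpec):
        name, klass = spec.name, spec.analysis_class
    else:
        name, klass = str(spec), str(spec)
        if klass not in ("continuous", "categorical"):
            raise ValueError("spec must be a variable spec or an analysis class")
    trace = [f"data type: {klass}"]
    if klass == "categorical":
        trace.append("categorical -> contingency test")
        return TestChoice(name, "chi_square", trace)
    trace.append(f"strata: {n_groups} groups")
    if isinstance(normality, NormalityResult):
        is_normal = normality.is_normal
    elif normality is None:
        raise ValueError("continuous selection requires a normality verdict")
    else:
        is_normal = bool(normality)
    trace.append("normality: " + ("normal" if is_normal else "non-normal"))
    if is_normal:
        selected = "t_test" if n_groups == 2 else "one_way_anova"
    else:
        selected = "wilcoxon_rank_sum" if n_groups == 2 else "kruskal_wallis"
    trace.append(f"method: {selected}")
    return TestChoice(name, selected, trace)


# ---------------------------------------------------------------------------
# comparisons


def _split_groups(values, group):
    v = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(g))
    v, g = v[ok], g[ok]
    levels = np.unique(g)
    return [v[g == lev] for lev in levels], levels


def compare_continuous(
    values,
    group,
    *,
    variable: str = "value",
    alpha: float = DEFAULT_ALPHA,
    normality_alpha: float = DEFAULT_ALPHA,
    pooled_t: bool = False,
) -> ComparisonResult:
    """Compare a continuous variable across groups with automatic selection.

    Normality is assessed per group; the parametric branch is taken only if
    every group passes.  Groups too small to test normality (n < 3) route
    to the nonparametric branch.  The Welch t-test is the 2-group default;
    ``pooled_t=True`` switches to the pooled-variance form.
    """
    samples, levels = _split_groups(values, group)
    if len(levels) < 2:
        raise ComparisonImpossibleError(
            f"{variable}: only {len(levels)} non-empty group(s)"
        )
    for lev, s in zip(levels, samples):
        if s.size < 2:
            raise DegenerateGroupError(
                f"{variable}: group {lev:g} has {s.size} complete case(s); need >= 2"
            )
    all_normal = True
    for s in samples:
        try:
            res = test_normality(s, alpha=normality_alpha)
            all_normal &= res.is_normal
        except InsufficientDataError:
            all_normal = False
    choice = select_test("continuous", len(levels), all_normal)
    choice.variable = variable

    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:  # all values identical: no evidence of difference
        stat, p, df = 0.0, 1.0, None
    elif choice.selected == "t_test":
        t = stats.ttest_ind(samples[0], samples[1], equal_var=pooled_t)
        stat, p, df = float(t.statistic), float(t.pvalue), float(t.df)
        if np.isnan(stat) and np.isclose(samples[0].mean(), samples[1].mean()):
            stat, p = 0.0, 1.0
    elif choice.selected == "one_way_anova":
        f = stats.f_oneway(*samples)
        k, n = len(samples), pooled.size
        stat, p, df = float(f.statistic), float(f.pvalue), (k - 1, n - k)
    elif choice.selected == "wilcoxon_rank_sum":
        u = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        stat, p, df = float(u.statistic), float(u.pvalue), None
    else:  # kruskal_wallis
        h = stats.kruskal(*samples)
        stat, p, df = float(h.statistic), float(h.pvalue), len(samples) - 1

    summaries = pd.DataFrame(
        {
            "group": levels,
            "n": [s.size for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
            "min": [s.min() for s in samples],
            "max": [s.max() for s in samples],
        }
    )
    return ComparisonResult(choice, stat, df, p, summaries)


def compare_categorical(
    values, group, *, variable: str = "value"
) -> ComparisonResult:
    """Chi-square test of independence on the variable x group table.

    On a 2x2 table with any expected count < 5 the Fisher exact test is
    used instead and recorded in the test choice.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(g))
    v, g = v[ok], g[ok]
    table = pd.crosstab(pd.Series(v, name=variable), pd.Series(g, name="group"))
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ComparisonImpossibleError(
            f"{variable}: contingency table collapses to {table.shape}"
        )
    obs = table.to_numpy()
    expected = stats.contingency.expected_freq(obs)
    choice = select_test("categorical", table.shape[1])
    choice.variable = variable
    if obs.shape == (2, 2) and (expected < 5).any():
        choice.selected = "fisher_exact"
        choice.rationale.append("expected count < 5 on 2x2 -> Fisher exact fallback")
        _, p = stats.fisher_exact(obs)
        stat, df = float("nan"), None
    else:
        chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
        stat = float(chi2)

    counts = table.reset_index().melt(
        id_vars=variable, var_name="group", value_name="count"
    )
    totals = table.sum(axis=0)
    counts["percent"] = [
        100.0 * c / totals[grp] for c, grp in zip(counts["count"], counts["group"])
    ]
    counts = counts.rename(columns={variable: "level"})
    return ComparisonResult(choice, stat, df, float(p), counts)


# ---------------------------------------------------------------------------
# table construction


def build_table1(
    ds: CodedDataset,
    strat: str,
    bundle: MetadataBundle | None = None,
    *,
    normality_alpha: float = DEFAULT_ALPHA,
) -> DemographicTable:
    """Build the stratified baseline-characteristics table.

    Every layer-2 covariate is summarised within each level of *strat* and
    tested with the automatically selected comparison; covariates that
    cannot be tested (fully missing, degenerate groups) are flagged in the
    ``untestable`` section rather than silently dropped.
    """
    bundle = bundle or ds.bundle
    spec = bundle.variable(strat)
    if spec.analysis_class != "categorical":
        raise StratifierTypeError(f"stratifier {strat!r} must be categorical")
    gvals = ds.column(strat).to_numpy(dtype=float)
    levels = sorted(np.unique(gvals[~np.isnan(gvals)]))
    if len(levels) < 2:
        raise StratifierTypeError(f"stratifier {strat!r} has < 2 observed levels")
    cmap = bundle.category_map(strat)
    labels = {lev: (cmap.display_of(int(lev)) if cmap else f"{lev:g}") for lev in levels}

    cont: dict[str, ComparisonResult] = {}
    cat: dict[str, ComparisonResult] = {}
    untestable: dict[str, str] = {}
    for var in bundle.covariates():
        if var.name == strat:
            continue
        vals = ds.column(var.name).to_numpy(dtype=float)
        try:
            if var.analysis_class == "continuous":
                cont[var.name] = compare_continuous(
                    vals, gvals, variable=var.name, normality_alpha=normality_alpha
                )
            else:
                cat[var.name] = compare_categorical(vals, gvals, variable=var.name)
        except (
            ComparisonImpossibleError,
            DegenerateGroupError,
            InsufficientDataError,
        ) as exc:
            untestable[var.name] = str(exc)
    return DemographicTable(strat, list(levels), labels, cont, cat, untestable)
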