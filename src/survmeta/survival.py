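"""Right-censored survival analysis: product-limit estimator, log-rank
test and Cox proportional-hazards regression, implemented from first
principles with optional strata.

Conventions
-----------
* Event flag: 1 = event (death), 0 = right-censored.
* A subject censored at time t stays in the risk set for events at t.
* The product-limit estimate at an event time t is the running product of
  per-event-time conditional survival fractions (n - d)/n over the risk
  sets; its variance is Greenwood's sum; confidence bands are computed on
  the log(-log) scale by default so they remain inside [0, 1].
* The log-rank statistic compares observed event counts with their
  hypergeometric expectations accumulated over event times; the k-group
  statistic is the quadratic form of (O - E) in the inverse of its
  estimated covariance, with k - 1 degrees of freedom.  A risk set of
  size 1 contributes zero variance.  With strata, O - E and the
  covariance are summed over strata before the quadratic form.
* The Cox model is fitted by Newton-Raphson on the partial log-likelihood
  with the Efron tie correction by default (Breslow available), per-stratum
  risk sets, step-halving to keep the likelihood non-decreasing, and
  standard errors from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ComparisonImpossibleError,
    ConvergenceError,
    GroupExplosionError,
    IdentifiabilityError,
    InsufficientDataError,
    SeparationError,
)
from .etl import CodedDataset
from .metadata import MetadataBundle

MAX_FORMULA_GROUPS = 20


@dataclass
class SurvivalSample:
    """Aligned time / event vectors with optional group and strata codes."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.time.size
        if self.event.size != n:
            raise ValueError("time and event must have equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("times must be finite and non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event flags must be 0 or 1")
        for attr in ("group", "strata"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if v.size != n:
                    raise ValueError(f"{attr} length mismatch")
                setattr(self, attr, v)

    @property
    def n(self) -> int:
        return self.time.size


@dataclass
class KMCurve:
    """Product-limit survival curve at the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    conditional_prob: np.ndarray  # (n - d) / n per event time
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    conf_level: float
    n: int
    censor_times: np.ndarray
    label: str | None = None

    def survival_at(self, t: float) -> float:
        """Step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_at_risk,
                "n_event": self.n_events,
                "survival": self.survival,
                "greenwood_var": self.greenwood_var,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass
class LogRankResult:
    groups: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    variance: np.ndarray  # k x k covariance of (O - E)
    statistic: float
    df: int
    p_value: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.groups, "observed": self.observed, "expected": self.expected}
        )


@dataclass
class CoxModel:
    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    loglik_trace: list[float]
    iterations: int
    ties_method: str
    score_at_zero: float
    loglik_at_zero: float
    conf_level: float
    strata_levels: list
    n: int
    n_events: int
    converged: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def z_scores(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_scores))

    def confint(self) -> np.ndarray:
        z = stats.norm.ppf(0.5 + self.conf_level / 2.0)
        lo = self.coefficients - z * self.standard_errors
        hi = self.coefficients + z * self.standard_errors
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.confint()
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.coefficients,
                "se": self.standard_errors,
                "hr": self.hazard_ratios,
                "hr_lower": np.exp(ci[:, 0]),
                "hr_upper": np.exp(ci[:, 1]),
                "z": self.z_scores,
                "p": self.p_values,
            }
        )


@dataclass
class SurvivalFormula:
    """Declarative description of one survival analysis on a coded dataset."""

    time: str
    event: str
    covariates: list[str] = field(default_factory=list)
    strata: list[str] = field(default_factory=list)
    endpoint_level: int | None = None

    def __post_init__(self) -> None:
        if set(self.covariates) & set(self.strata):
            raise ValueError("covariates and strata must be disjoint")


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(
    sample: SurvivalSample,
    conf_level: float = 0.95,
    ci_method: str = "loglog",
) -> KMCurve | dict:
    """Product-limit estimate; one curve per group when the sample is grouped."""
    if sample.group is not None:
        out = {}
        for lev in np.unique(sample.group):
            m = sample.group == lev
            sub = SurvivalSample(sample.time[m], sample.event[m])
            out[lev] = km_estimate(sub, conf_level, ci_method)
            out[lev].label = str(lev)
        return out
    return _km_single(sample.time, sample.event, conf_level, ci_method)


def _km_single(time, event, conf_level, ci_method) -> KMCurve:
    n = time.size
    if n < 1:
        raise InsufficientDataError("empty sample")
    if event.sum() == 0:
        warnings.warn("all observations censored: survival curve is constant at 1")
        return KMCurve(
            event_times=np.array([]),
            n_at_risk=np.array([], dtype=int),
            n_events=np.array([], dtype=int),
            conditional_prob=np.array([]),
            survival=np.array([]),
            greenwood_var=np.array([]),
            ci_lower=np.array([]),
            ci_upper=np.array([]),
            conf_level=conf_level,
            n=n,
            censor_times=np.sort(time),
        )
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    ev_times = np.unique(t_sorted[e_sorted == 1])
    # risk set at t: subjects with observed time >= t (censored-at-t included)
    n_risk = n - np.searchsorted(t_sorted, ev_times, side="left")
    d = np.array(
        [np.sum((t_sorted == t) & (e_sorted == 1)) for t in ev_times], dtype=int
    )
    cond = (n_risk - d) / n_risk
    surv = np.cumprod(cond)
    # Greenwood: Var(S) = S^2 * sum d / (n (n - d)); zero once S hits 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
        gvar = surv**2 * np.cumsum(terms)
    gvar = np.where(surv == 0.0, 0.0, gvar)

    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if ci_method == "loglog":
            # theta = log(-log S); CI = S^exp(+/- z se_theta)
            cum = np.cumsum(terms)
            se_theta = np.sqrt(cum) / np.abs(np.log(surv))
            lo = surv ** np.exp(z * se_theta)
            hi = surv ** np.exp(-z * se_theta)
        elif ci_method == "linear":
            half = z * np.sqrt(gvar)
            lo = np.clip(surv - half, 0.0, 1.0)
            hi = np.clip(surv + half, 0.0, 1.0)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    degenerate = (surv == 0.0) | (surv == 1.0)
    lo = np.where(degenerate, surv, lo)
    hi = np.where(degenerate, surv, hi)
    return KMCurve(
        event_times=ev_times,
        n_at_risk=n_risk.astype(int),
        n_events=d,
        conditional_prob=cond,
        survival=surv,
        greenwood_var=gvar,
        ci_lower=lo,
        ci_upper=hi,
        conf_level=conf_level,
        n=n,
        censor_times=np.sort(time[event == 0]),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with survival <= 0.5; None when never reached."""
    hit = np.nonzero(curve.survival <= 0.5)[0]
    if hit.size == 0:
        return None
    return float(curve.event_times[hit[0]])


# ---------------------------------------------------------------------------
# log-rank


def logrank_test(sample: SurvivalSample) -> LogRankResult:
    """Log-rank comparison of the grouped survival distributions.

    Per event time the event count in each group is compared with its
    expectation under the hypergeometric null; O - E and its covariance are
    accumulated over event times (and summed over strata when present) and
    combined into a chi-squared statistic on k - 1 degrees of freedom.
    """
    if sample.group is None:
        raise ValueError("logrank_test requires a grouped sample")
    groups = np.unique(sample.group)
    k = groups.size
    if k < 2:
        raise ComparisonImpossibleError("log-rank needs >= 2 groups")
    if sample.event.sum() == 0:
        raise InsufficientDataError("log-rank needs >= 1 event")
    strata = sample.strata if sample.strata is not None else np.zeros(sample.n)

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for s in np.unique(strata):
        m = strata == s
        _accumulate_logrank(
            sample.time[m], sample.event[m], sample.group[m], groups, O, E, V
        )
    for g, lev in enumerate(groups):
        if not np.any(sample.group == lev):
            raise ComparisonImpossibleError(f"group {lev!r} empty")

    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    if diff.size == 0 or not np.any(Vsub):
        chi2 = 0.0
    else:
        try:
            chi2 = float(diff @ np.linalg.solve(Vsub, diff))
        except np.linalg.LinAlgError:
            chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogRankResult(groups, O, E, V, chi2, df, p)


def _accumulate_logrank(time, event, group, groups, O, E, V):
    k = groups.size
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        return
    n_total = t.size - np.searchsorted(t, ev_times, side="left")
    # per-group at-risk counts and event counts at each event time
    n_g = np.empty((k, ev_times.size))
    d_g = np.empty((k, ev_times.size))
    for j, lev in enumerate(groups):
        tg = np.sort(t[g == lev])
        n_g[j] = tg.size - np.searchsorted(tg, ev_times, side="left")
        tg_ev = np.sort(t[(g == lev) & (e == 1)])
        d_g[j] = np.searchsorted(tg_ev, ev_times, side="right") - np.searchsorted(
            tg_ev, ev_times, side="left"
        )
    d_total = d_g.sum(axis=0)
    O += d_g.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        E += np.nansum(d_total * n_g / n_total, axis=1)
        # hypergeometric covariance; risk sets of size 1 contribute 0
        scale = np.where(
            n_total > 1, d_total * (n_total - d_total) / (n_total - 1.0), 0.0
        )
        p_g = n_g / n_total  # (k, m)
    for a in range(k):
        for b in range(k):
            delta = 1.0 if a == b else 0.0
            V[a, b] += np.sum(scale * p_g[a] * (delta - p_g[b]))


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_stratum_quantities(beta, time, event, X, ties):
    """Negative quantities are not used; returns (loglik, score, information)
    for one stratum via suffix risk-set sums.

    Breslow contributions are fully vectorised; Efron applies an extra
    correction only at event times with d >= 2 ties.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], X[order]
    eta = x @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    # suffix sums: S0[i] = sum_{j >= i} w_j etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_idx = np.nonzero(e == 1)[0]
    if ev_idx.size == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))
    # risk-set anchor: first sorted position sharing the event's time
    f = np.searchsorted(t, t[ev_idx], side="left")

    r0 = S0[f]
    r1 = S1[f]
    r2 = S2[f]
    z = r1 / r0[:, None]
    ll = float(eta[ev_idx].sum() - np.log(r0).sum())
    score = x[ev_idx].sum(axis=0) - z.sum(axis=0)
    info = (r2 / r0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", z, z)

    if ties == "efron":
        # replace the Breslow contribution at tied event times
        ev_t = t[ev_idx]
        uniq, counts = np.unique(ev_t, return_counts=True)
        for tt, d in zip(uniq[counts > 1], counts[counts > 1]):
            i0 = np.searchsorted(t, tt, side="left")
            tied = ev_idx[ev_t == tt]
            R0, R1, R2 = S0[i0], S1[i0], S2[i0]
            s0t = w[tied].sum()
            s1t = wx[tied].sum(axis=0)
            s2t = wxx[tied].sum(axis=0)
            # remove Breslow terms for these d events
            ll += d * np.log(R0)
            score += d * (R1 / R0)
            info -= d * (R2 / R0 - np.outer(R1 / R0, R1 / R0))
            for l in range(d):
                frac = l / d
                phi0 = R0 - frac * s0t
                phi1 = R1 - frac * s1t
                phi2 = R2 - frac * s2t
                zl = phi1 / phi0
                ll -= np.log(phi0)
                score -= zl
                info += phi2 / phi0 - np.outer(zl, zl)
    elif ties != "breslow":
        raise ValueError(f"unknown ties method {ties!r}")
    return ll, score, info


def _cox_quantities(beta, time, event, X, strata, ties):
    p = X.shape[1]
    ll, score, info = 0.0, np.zeros(p), np.zeros((p, p))
    for s in np.unique(strata):
        m = strata == s
        l_, s_, i_ = _cox_stratum_quantities(beta, time[m], event[m], X[m], ties)
        ll += l_
        score += s_
        info += i_
    return ll, score, info


def fit_coxph(
    sample: SurvivalSample,
    X: np.ndarray,
    names: list[str] | None = None,
    *,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
    conf_level: float = 0.95,
    beta_bound: float = 50.0,
) -> CoxModel:
    """Maximise the Cox partial likelihood by Newton-Raphson.

    Complete cases must be prepared by the caller; ``sample.strata`` gives
    each subject its stratum (separate baseline hazard / risk sets).
    Step-halving enforces a non-decreasing likelihood; convergence is
    declared when the score sup-norm falls below *tol* or the relative
    log-likelihood change does.  Monotone likelihood (separation) is
    reported when a coefficient escapes ``beta_bound`` or its per-SD
    magnitude ``|beta_j| * sd(x_j)`` exceeds 10 (a hazard ratio above
    e^10 per standard deviation has no finite maximiser in practice).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != sample.n:
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if sample.event.sum() < 1:
        raise InsufficientDataError("Cox fit needs >= 1 event")
    if n < p + 1:
        raise InsufficientDataError(f"need >= {p + 1} complete cases, got {n}")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        j = int(np.argmin(sds))
        raise IdentifiabilityError(f"covariate {names[j]!r} is constant")
    strata = sample.strata if sample.strata is not None else np.zeros(n)

    beta = np.zeros(p)
    ll, score, info = _cox_quantities(beta, sample.time, sample.event, X, strata, ties)
    ll0 = ll
    score_stat = float(score @ np.linalg.solve(info, score)) if np.any(info) else 0.0
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        step_scale = 1.0
        improved = False
        while step_scale >= 1e-10:
            cand = beta + step_scale * step
            ll_new, score_new, info_new = _cox_quantities(
                cand, sample.time, sample.event, X, strata, ties
            )
            if ll_new >= ll - 1e-12:
                improved = True
                break
            step_scale /= 2.0
        if not improved:  # no ascent possible: numerically at the optimum
            converged = True
            break
        ll_prev = ll
        beta, ll, score, info = cand, ll_new, score_new, info_new
        trace.append(ll)
        if np.any(np.abs(beta) > beta_bound) or np.any(np.abs(beta) * sds > 10.0):
            raise SeparationError(
                "monotone partial likelihood: coefficient magnitude exceeded "
                f"{beta_bound}; data are separated"
            )
        if np.max(np.abs(score)) < tol or abs(ll - ll_prev) / (abs(ll) + 1.0) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations", trace
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxModel(
        names=list(names),
        coefficients=beta,
        standard_errors=se,
        log_likelihood=float(ll),
        loglik_trace=[float(v) for v in trace],
        iterations=it,
        ties_method=ties,
        score_at_zero=score_stat,
        loglik_at_zero=float(ll0),
        conf_level=conf_level,
        strata_levels=sorted(np.unique(strata).tolist()),
        n=n,
        n_events=int(sample.event.sum()),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# formula-driven entry points on coded datasets


def _complete_cases(ds: CodedDataset, columns: list[str]) -> pd.DataFrame:
    sub = ds.data[columns]
    return sub.dropna().reset_index(drop=True)


def _resolve_event(ev: np.ndarray, endpoint_level: int | None) -> np.ndarray:
    if endpoint_level is None:
        return ev.astype(int)
    return (ev == endpoint_level).astype(int)


def km_by_formula(
    ds: CodedDataset, formula: SurvivalFormula, conf_level: float = 0.95
) -> tuple[dict, LogRankResult | None]:
    """Kaplan-Meier curves per combination of covariate levels + log-rank.

    Each covariate in the formula is expanded over its unique observed
    values; one curve is produced per combination (refused above
    ``MAX_FORMULA_GROUPS``).  With no covariates a single curve and no test
    are returned.  Strata enter the log-rank accumulation only.
    """
    cols = [formula.time, formula.event] + formula.covariates + formula.strata
    cc = _complete_cases(ds, cols)
    time = cc[formula.time].to_numpy(dtype=float)
    event = _resolve_event(cc[formula.event].to_numpy(), formula.endpoint_level)
    strata = None
    if formula.strata:
        strata = _combine_codes(cc[formula.strata])

    if not formula.covariates:
        sub = SurvivalSample(time, event)
        return {"all": km_estimate(sub, conf_level)}, None

    group = _combine_codes(cc[formula.covariates])
    n_groups = np.unique(group).size
    if n_groups > MAX_FORMULA_GROUPS:
        raise GroupExplosionError(
            f"formula expands to {n_groups} groups (> {MAX_FORMULA_GROUPS}); "
            "bin the numeric covariates or set an endpoint level"
        )
    labels = _group_labels(cc[formula.covariates], ds.bundle)
    curves = {}
    for lev in np.unique(group):
        m = group == lev
        curve = km_estimate(SurvivalSample(time[m], event[m]), conf_level)
        curve.label = labels[lev]
        curves[labels[lev]] = curve
    test = None
    if n_groups >= 2 and event.sum() > 0:
        test = logrank_test(SurvivalSample(time, event, group=group, strata=strata))
    return curves, test


def _combine_codes(frame: pd.DataFrame) -> np.ndarray:
    """Collapse one or more code columns into a single integer group code."""
    arr = frame.to_numpy(dtype=float)
    uniq, inv = np.unique(arr, axis=0, return_inverse=True)
    return inv


def _group_labels(frame: pd.DataFrame, bundle: MetadataBundle) -> dict[int, str]:
    arr = frame.to_numpy(dtype=float)
    uniq = np.unique(arr, axis=0)
    labels = {}
    for i, row in enumerate(uniq):
        parts = []
        for col, val in zip(frame.columns, row):
            cmap = bundle.category_map(col)
            disp = cmap.display_of(int(val)) if cmap else f"{val:g}"
            parts.append(f"{col}={disp}")
        labels[i] = ", ".join(parts)
    return labels


def coxph_by_formula(
    ds: CodedDataset,
    formula: SurvivalFormula,
    *,
    ties: str = "efron",
    conf_level: float = 0.95,
    **kwargs,
) -> CoxModel:
    """Fit a Cox model from a coded dataset and a survival formula.

    Missing values are eliminated listwise over the formula's columns
    before the fit; strata columns define per-stratum risk sets.
    """
    if not formula.covariates:
        raise ValueError("Cox formula needs >= 1 covariate")
    cols = [formula.time, formula.event] + formula.covariates + formula.strata
    cc = _complete_cases(ds, cols)
    time = cc[formula.time].to_numpy(dtype=float)
    event = _resolve_event(cc[formula.event].to_numpy(), formula.endpoint_level)
    strata = _combine_codes(cc[formula.strata]) if formula.strata else None
    X = cc[formula.covariates].to_numpy(dtype=float)
    sample = SurvivalSample(time, event, strata=strata)
    return fit_coxph(
        sample, X, names=list(formula.covariates),
        ties=ties, conf_level=conf_level, **kwargs,
    )
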