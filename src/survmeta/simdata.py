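"""Synthetic right-censored cohorts with known ground truth.

Cohorts follow a proportional-hazards data-generating process: covariates x
are drawn per subject, the event time is obtained by inverse-transform
sampling T = H0^{-1}(-log U / exp(beta' x)) from an exponential or Weibull
baseline cumulative hazard H0, and an independent censoring time C yields
the observed pair (min(T, C), 1{T <= C}).

The default cohort mirrors a colon-cancer adjuvant-therapy trial shape:
overall-survival time ``TimeOS`` in days, death flag ``EventDeath``
(0 = alive/censored, 1 = dead), a two-arm treatment indicator ``rx``, age
and positive-lymph-node count as continuous covariates, and sex,
differentiation grade and local-extent stage as categoricals, with roughly
half the cohort censored.  Alongside the dataset the generator can write
the matching three-layer metadata files so the whole pipeline is
exercisable from a single seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .errors import SimSpecError
from .metadata import (
    CategoryEntry,
    Layer1Roles,
    Layer2VariableSpec,
    Layer3CategoryMap,
    MetadataBundle,
)

# ---------------------------------------------------------------------------
# specification


@dataclass
class Exponential:
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise SimSpecError("exponential rate must be > 0")

    def inverse_cumhaz(self, h):
        return h / self.rate

    def survival(self, t, loghr=0.0):
        return np.exp(-self.rate * np.exp(loghr) * t)


@dataclass
class Weibull:
    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise SimSpecError("weibull shape and scale must be > 0")

    def inverse_cumhaz(self, h):
        return self.scale * np.power(h, 1.0 / self.shape)

    def survival(self, t, loghr=0.0):
        return np.exp(-np.exp(loghr) * np.power(t / self.scale, self.shape))


@dataclass
class CategoryLevel:
    """How one simulated code appears in the raw CSV."""

    code: int
    token: str
    aliases: frozenset[str] = frozenset()
    display: str = ""

    def __post_init__(self):
        self.display = self.display or self.token
        self.aliases = frozenset(self.aliases) | {self.token, str(self.code)}


@dataclass
class Bernoulli:
    p: float
    levels: list[CategoryLevel] | None = None

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise SimSpecError("bernoulli p must be in [0, 1]")
        if self.levels is None:
            self.levels = [CategoryLevel(0, "0"), CategoryLevel(1, "1")]

    analysis_class = "categorical"

    def draw(self, rng, n):
        return rng.binomial(1, self.p, n).astype(float)


@dataclass
class Normal:
    mu: float
    sigma: float

    analysis_class = "continuous"

    def __post_init__(self):
        if self.sigma <= 0:
            raise SimSpecError("normal sigma must be > 0")

    def draw(self, rng, n):
        return rng.normal(self.mu, self.sigma, n)


@dataclass
class Categorical:
    probs: list[float]
    levels: list[CategoryLevel] | None = None

    analysis_class = "categorical"

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise SimSpecError("categorical probs must be >= 0 and sum to 1")
        if self.levels is None:
            self.levels = [CategoryLevel(i, str(i)) for i in range(len(self.probs))]
        if len(self.levels) != len(self.probs):
            raise SimSpecError("levels and probs length mismatch")

    def draw(self, rng, n):
        codes = [lev.code for lev in self.levels]
        return rng.choice(codes, size=n, p=self.probs).astype(float)


@dataclass
class Poisson:
    lam: float

    analysis_class = "continuous"  # a count enters the hazard linearly

    def __post_init__(self):
        if self.lam <= 0:
            raise SimSpecError("poisson lam must be > 0")

    def draw(self, rng, n):
        return rng.poisson(self.lam, n).astype(float)


@dataclass
class AdminCensoring:
    time: float


@dataclass
class ExponentialCensoring:
    rate: float


@dataclass
class TargetCensoring:
    """Independent exponential censoring with the rate solved so the expected
    censored fraction matches *fraction*."""

    fraction: float

    def __post_init__(self):
        if not 0 <= self.fraction < 1:
            raise SimSpecError("target censor fraction must be in [0, 1)")


@dataclass
class SimSpec:
    """Complete description of one simulated cohort."""

    n: int
    baseline: Exponential | Weibull
    betas: dict[str, float] = field(default_factory=dict)
    covariate_specs: dict[str, object] = field(default_factory=dict)
    censoring: AdminCensoring | ExponentialCensoring | TargetCensoring | None = None
    seed: int = 0
    time_name: str = "TimeOS"
    event_name: str = "EventDeath"

    def __post_init__(self):
        if self.n < 1:
            raise SimSpecError("n must be >= 1")
        unknown = set(self.betas) - set(self.covariate_specs)
        if unknown:
            raise SimSpecError(f"betas reference unknown covariates {sorted(unknown)}")


@dataclass
class SimResult:
    dataset: pd.DataFrame  # numeric analysis values (codes for categoricals)
    truth: SimSpec
    realized_censor_fraction: float
    censor_rate: float | None = None  # solved exponential rate, if applicable


def colon_like_spec(
    n: int = 600,
    seed: int = 0,
    beta_rx: float = -0.5,
    censor_fraction: float = 0.5,
) -> SimSpec:
    """Default cohort: two-arm adjuvant trial with colon-trial covariates.

    Baseline hazard 4e-4 / day (median untreated survival around 4.7 years),
    treatment reduces the hazard (HR = exp(beta_rx)), each positive node adds
    8% hazard, age adds 1% per year over 60; about half the cohort censored.
    """
    return SimSpec(
        n=n,
        baseline=Exponential(rate=4e-4),
        betas={"rx": beta_rx, "nodes": 0.08, "age": 0.01},
        covariate_specs={
            "rx": Bernoulli(
                0.5,
                levels=[
                    CategoryLevel(0, "control", {"ctrl"}, "control arm"),
                    CategoryLevel(1, "treatment", {"trt"}, "treatment arm"),
                ],
            ),
            "age": Normal(60.0, 12.0),
            "nodes": Poisson(3.6),
            "sex": Bernoulli(
                0.5,
                levels=[
                    CategoryLevel(0, "F", {"f"}, "female"),
                    CategoryLevel(1, "M", {"m"}, "male"),
                ],
            ),
            "differ": Categorical(
                [0.10, 0.73, 0.17],
                levels=[
                    CategoryLevel(1, "1", display="well"),
                    CategoryLevel(2, "2", display="moderate"),
                    CategoryLevel(3, "3", display="poor"),
                ],
            ),
            "extent": Categorical(
                [0.02, 0.11, 0.81, 0.06],
                levels=[
                    CategoryLevel(1, "1", display="submucosa"),
                    CategoryLevel(2, "2", display="muscle"),
                    CategoryLevel(3, "3", display="serosa"),
                    CategoryLevel(4, "4", display="contiguous"),
                ],
            ),
        },
        censoring=TargetCensoring(censor_fraction),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation


def _centered(name: str, x: np.ndarray, spec) -> np.ndarray:
    # center continuous covariates at their design mean so the baseline rate
    # keeps its interpretation for an average subject
    if isinstance(spec, Normal):
        return x - spec.mu
    if isinstance(spec, Poisson):
        return x - spec.lam
    return x


def simulate_cohort(spec: SimSpec) -> SimResult:
    """Draw one cohort; deterministic for a fixed spec (including seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    eta = np.zeros(n)
    for name, cov in spec.covariate_specs.items():
        x = cov.draw(rng, n)
        cols[name] = x
        beta = spec.betas.get(name, 0.0)
        if beta:
            eta += beta * _centered(name, x, cov)

    u = rng.uniform(size=n)
    T = spec.baseline.inverse_cumhaz(-np.log(u) / np.exp(eta))

    censor_rate = None
    if spec.censoring is None:
        C = np.full(n, np.inf)
    elif isinstance(spec.censoring, AdminCensoring):
        C = np.full(n, float(spec.censoring.time))
    elif isinstance(spec.censoring, ExponentialCensoring):
        censor_rate = float(spec.censoring.rate)
        C = rng.exponential(1.0 / censor_rate, n)
    else:
        if spec.censoring.fraction == 0.0:
            C = np.full(n, np.inf)
        else:
            censor_rate = _solve_censor_rate(spec, eta)
            C = rng.exponential(1.0 / censor_rate, n)

    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    data = pd.DataFrame(cols)
    data.insert(0, spec.event_name, event.astype(float))
    data.insert(0, spec.time_name, time)
    return SimResult(
        dataset=data,
        truth=spec,
        realized_censor_fraction=float(1.0 - event.mean()),
        censor_rate=censor_rate,
    )


def _solve_censor_rate(spec: SimSpec, eta: np.ndarray) -> float:
    """Exponential censoring rate mu with mean_i P(C < T_i) = target.

    For an exponential baseline P(C < T_i) = mu / (mu + lambda_i) in closed
    form; for Weibull the probability integral is evaluated numerically.
    """
    target = spec.censoring.fraction

    if isinstance(spec.baseline, Exponential):
        lam = spec.baseline.rate * np.exp(eta)

        def frac(log_mu):
            mu = np.exp(log_mu)
            return np.mean(mu / (mu + lam)) - target

    else:

        def frac(log_mu):
            mu = np.exp(log_mu)

            def integrand(t):
                sbar = np.mean(
                    spec.baseline.survival(t, loghr=eta[:, None]), axis=0
                )
                return mu * np.exp(-mu * t) * sbar

            val, _ = integrate.quad(
                lambda t: float(integrand(np.atleast_1d(t))[0]), 0, np.inf, limit=200
            )
            return val - target

    lo, hi = -30.0, 30.0
    try:
        return float(np.exp(optimize.brentq(frac, lo, hi, xtol=1e-10)))
    except ValueError as exc:
        raise SimSpecError(f"cannot achieve censor fraction {target}") from exc


# ---------------------------------------------------------------------------
# fixture files


def build_bundle(spec: SimSpec) -> MetadataBundle:
    """Three-layer metadata matching a simulated cohort."""
    layer2 = [
        Layer2VariableSpec(spec.time_name, "ratio", "time"),
        Layer2VariableSpec(spec.event_name, "nominal", "event"),
    ]
    layer3 = [
        Layer3CategoryMap(
            spec.event_name,
            [
                CategoryEntry(0, frozenset({"0", "alive"}), "alive"),
                CategoryEntry(1, frozenset({"1", "dead"}), "dead"),
            ],
        )
    ]
    for name, cov in spec.covariate_specs.items():
        if cov.analysis_class == "continuous":
            layer2.append(Layer2VariableSpec(name, "ratio", "covariate"))
        else:
            layer2.append(Layer2VariableSpec(name, "nominal", "covariate"))
            layer3.append(
                Layer3CategoryMap(
                    name,
                    [
                        CategoryEntry(lev.code, lev.aliases, lev.display)
                        for lev in cov.levels
                    ],
                )
            )
    return MetadataBundle(
        Layer1Roles(spec.time_name, spec.event_name), layer2, layer3
    )


def make_fixture_files(
    result: SimResult, out_dir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Write Dataset.csv plus the three layer CSVs for a simulated cohort.

    Categorical cells are written as raw tokens (e.g. ``M`` / ``F``) so that
    loading through the metadata exercises the layer-3 recoding; loading the
    four files reproduces the simulated numeric table exactly.
    """
    from .metadata import write_metadata  # local import to avoid cycle at import time

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = result.truth
    bundle = build_bundle(spec)

    raw = result.dataset.copy()
    for name, cov in spec.covariate_specs.items():
        if cov.analysis_class == "categorical":
            tokens = {lev.code: lev.token for lev in cov.levels}
            raw[name] = [tokens[int(c)] for c in raw[name]]
    raw[spec.event_name] = raw[spec.event_name].astype(int)

    ds_path = out / "Dataset.csv"
    raw.to_csv(ds_path, index=False)
    p1, p2, p3 = write_metadata(bundle, out)
    return ds_path, p1, p2, p3
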