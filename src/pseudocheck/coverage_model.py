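"""Binomial modeling of spurious-pseudogene generation.

The model treats spurious pseudogenes as draws from the finite pool of
coding features: each of the ``n`` coding sequences of an assembly
independently becomes a spurious pseudogene with probability

    pi(coverage, Q) = expit(beta0 + beta_cov * log10(coverage) + beta_q * Q)

so the observed count ``k`` is Binomial(n, pi).  The logit link with
log10-coverage makes the error-versus-coverage decay monotone and
scale-free; mean base quality ``Q`` enters untransformed.  Fitting is
maximum likelihood via iteratively reweighted least squares (IRLS).

Two derived quantities summarize a fitted model: the expected spurious
pseudogene density (per Mbp) at a reporting coverage (50-fold by default in
the workflow), and the coverage required to reach a target density (one
pseudogene per Mbp by default), found by bisection on log10(coverage).

The module also implements the nearest-neighbor anomaly filter: an assembly
with a >= 99.9%-ANI neighbor is rejected when its internal-stop pseudogene
count exceeds the 99th percentile of Binomial(n_cds, neighbor rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import binom

#: minimum ANI (percent) for a neighbor to serve as a filter baseline
ANI_GATE = 99.9
#: binomial quantile used by the anomaly filter
FILTER_QUANTILE = 0.99
_RIDGE = 1e-6
_MAX_ITER = 100
_LL_TOL = 1e-8


@dataclass(frozen=True)
class BinomialObservation:
    """One assembly-level observation: ``k`` spurious pseudogenes (for one
    cause) out of ``n`` coding features at the given coverage and quality."""

    k: int
    n: int
    coverage: float
    quality: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class BinomialFit:
    """A fitted logit-linear binomial model.

    ``beta_q`` is ``None`` when the quality column was constant and the term
    was dropped.  ``boundary`` marks an all-zero (or all-saturated) response
    for which no finite MLE exists; ``separation`` marks a fit that needed a
    small ridge (1e-6) to converge.
    """

    beta0: float | None
    beta_cov: float | None
    beta_q: float | None
    se: dict[str, float] = field(default_factory=dict)
    deviance: float | None = None
    log_likelihood: float | None = None
    n_obs: int = 0
    converged: bool = False
    boundary: bool = False
    separation: bool = False

    def linear_predictor(self, coverage: float, quality: float) -> float:
        if self.boundary:
            raise ValueError("model hit the likelihood boundary; no finite estimates")
        eta = self.beta0 + self.beta_cov * math.log10(coverage)
        if self.beta_q is not None:
            eta += self.beta_q * quality
        return eta

    def predicted_probability(self, coverage: float, quality: float) -> float:
        """Per-CDS spurious-pseudogene probability, in (0, 1)."""
        if coverage <= 0:
            raise ValueError("coverage must be positive")
        return float(expit(self.linear_predictor(coverage, quality)))


def _log_likelihood(k: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(k * np.log(mu) + (n - k) * np.log1p(-mu)))


def _irls(
    X: np.ndarray, k: np.ndarray, n: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Return (beta, covariance, converged)."""
    p = (k + 0.5) / (n + 1.0)
    eta = logit(p)
    ll_prev = -np.inf
    converged = False
    beta = np.zeros(X.shape[1])
    for _ in range(_MAX_ITER):
        mu = expit(eta)
        w = np.clip(n * mu * (1 - mu), 1e-12, None)
        z = eta + (k - n * mu) / w
        A = X.T @ (w[:, None] * X) + ridge * np.eye(X.shape[1])
        beta = np.linalg.solve(A, X.T @ (w * z))
        eta = X @ beta
        ll = _log_likelihood(k, n, expit(eta))
        if abs(ll - ll_prev) < _LL_TOL:
            converged = True
            break
        ll_prev = ll
    mu = expit(eta)
    w = np.clip(n * mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (w[:, None] * X) + ridge * np.eye(X.shape[1]))
    return beta, cov, converged


def fit_binomial(observations: Sequence[BinomialObservation]) -> BinomialFit:
    """Maximum-likelihood fit of the logit-linear binomial model.

    Requires at least 3 distinct coverage values.  A constant quality column
    is dropped (``beta_q = None``).  An all-zero (or all-saturated) response
    sets the ``boundary`` flag and returns no estimates; complete separation
    is handled by refitting with a 1e-6 ridge and flagged, never silent.
    """
    obs = list(observations)
    if len({o.coverage for o in obs}) < 3:
        raise ValueError("need observations at >= 3 distinct coverage values")
    k = np.array([o.k for o in obs], dtype=float)
    n = np.array([o.n for o in obs], dtype=float)
    if np.all(k == 0) or np.all(k == n):
        return BinomialFit(
            beta0=None, beta_cov=None, beta_q=None, n_obs=len(obs), boundary=True
        )
    logcov = np.log10([o.coverage for o in obs])
    quality = np.array([o.quality for o in obs], dtype=float)
    use_quality = len(set(quality.tolist())) > 1
    cols = [np.ones(len(obs)), logcov] + ([quality] if use_quality else [])
    X = np.column_stack(cols)

    beta, cov, converged = _irls(X, k, n, ridge=0.0)
    eta = X @ beta
    separation = (not converged) or bool(np.max(np.abs(eta)) > 30)
    if separation:
        beta, cov, converged = _irls(X, k, n, ridge=_RIDGE)
        eta = X @ beta

    mu = expit(eta)
    ll = _log_likelihood(k, n, mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / (n * mu)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n - n * mu)), 0.0)
    deviance = float(2 * np.sum(t1 + t2))
    names = ["beta0", "beta_cov"] + (["beta_q"] if use_quality else [])
    se = {name: float(np.sqrt(cov[i, i])) for i, name in enumerate(names)}
    return BinomialFit(
        beta0=float(beta[0]),
        beta_cov=float(beta[1]),
        beta_q=float(beta[2]) if use_quality else None,
        se=se,
        deviance=deviance,
        log_likelihood=ll,
        n_obs=len(obs),
        converged=converged,
        boundary=False,
        separation=separation,
    )


def predict_density(
    fit: BinomialFit,
    coverage: float,
    quality: float,
    n_cds: int,
    genome_len: int,
) -> float:
    """Expected spurious-pseudogene density (per Mbp) at the given condition:
    ``expit(eta) * n_cds * 1e6 / genome_len``."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    p = fit.predicted_probability(coverage, quality)
    return p * n_cds * 1e6 / genome_len


@dataclass(frozen=True)
class CoverageSolution:
    """Root of the density curve.  ``status`` is ``ok`` for an interior
    root, ``below_bracket`` when even the minimum bracket coverage already
    meets the target (the bracket lower bound is returned), ``unreachable``
    when the target density is not attained at the maximum bracket coverage
    (``coverage`` is +inf)."""

    coverage: float
    status: str


_LOG10_BRACKET = (-1.0, 6.0)


def coverage_for_density(
    fit: BinomialFit,
    target_density: float = 1.0,
    quality: float = 35.0,
    n_cds: int = 4000,
    genome_len: int = 4_000_000,
) -> CoverageSolution:
    """Coverage at which the expected density equals ``target_density``.

    Solved by bisection on log10(coverage) over [0.1, 1e6] to 1e-6 relative
    tolerance.  Requires a model with density decreasing in coverage
    (``beta_cov < 0``).
    """
    if fit.boundary:
        raise ValueError("boundary fit has no density curve")
    if fit.beta_cov is None or fit.beta_cov >= 0:
        raise ValueError("density is not decreasing in coverage (beta_cov >= 0)")
    lo, hi = _LOG10_BRACKET

    def dens(log10cov: float) -> float:
        return predict_density(fit, 10.0**log10cov, quality, n_cds, genome_len)

    if dens(lo) <= target_density:
        return CoverageSolution(coverage=10.0**lo, status="below_bracket")
    if dens(hi) > target_density:
        return CoverageSolution(coverage=math.inf, status="unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if dens(mid) > target_density:
            lo = mid
        else:
            hi = mid
        # 10**(hi-lo) - 1 < 1e-6 relative tolerance on the coverage itself
        if hi - lo < 1e-6 / math.log(10):
            break
    root = 0.5 * (lo + hi)
    return CoverageSolution(coverage=10.0**root, status="ok")


def coverage_for_density_analytic(
    fit: BinomialFit,
    target_density: float = 1.0,
    quality: float = 35.0,
    n_cds: int = 4000,
    genome_len: int = 4_000_000,
) -> float:
    """Closed-form inversion of the logit-linear density curve (cross-check
    for the bisection solver)."""
    p_target = target_density * genome_len / (1e6 * n_cds)
    if not 0 < p_target < 1:
        raise ValueError("target density implies probability outside (0,1)")
    eta = float(logit(p_target))
    if fit.beta_q is not None:
        eta -= fit.beta_q * quality
    eta -= fit.beta0
    return 10.0 ** (eta / fit.beta_cov)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the nearest-neighbor binomial anomaly test.

    ``evaluated`` is False when the neighbor's ANI is below the 99.9% gate;
    otherwise ``reject`` is True when ``n_stops`` exceeds the 99th-percentile
    binomial threshold implied by the neighbor's internal-stop rate.
    """

    n_stops: int
    n_cds: int
    neighbor_rate: float | None
    threshold: int | None
    reject: bool
    neighbor_ani: float
    evaluated: bool


def binomial_quantile_threshold(n_cds: int, rate: float, q: float = FILTER_QUANTILE) -> int:
    """min { t : CDF_Binomial(t; n_cds, rate) >= q } — the discrete quantile,
    not a normal approximation."""
    if rate <= 0:
        return 0
    return int(binom.ppf(q, n_cds, rate))


def binomial_filter(
    n_stops: int,
    n_cds: int,
    neighbor_stops: int,
    neighbor_n_cds: int,
    neighbor_ani: float,
) -> FilterVerdict:
    """Flag an assembly whose internal-stop pseudogene count is significantly
    above its nearest neighbor's rate.

    The expected count is Binomial(n_cds, neighbor_stops/neighbor_n_cds);
    rejection requires strictly exceeding the 99th percentile.  Assemblies
    without a >= 99.9%-ANI neighbor are returned not-evaluated.
    """
    if n_cds <= 0:
        raise ValueError("n_cds must be positive")
    if neighbor_n_cds <= 0:
        raise ValueError("neighbor_n_cds must be positive")
    if neighbor_ani < ANI_GATE:
        return FilterVerdict(
            n_stops=n_stops,
            n_cds=n_cds,
            neighbor_rate=None,
            threshold=None,
            reject=False,
            neighbor_ani=neighbor_ani,
            evaluated=False,
        )
    rate = neighbor_stops / neighbor_n_cds
    threshold = binomial_quantile_threshold(n_cds, rate)
    return FilterVerdict(
        n_stops=n_stops,
        n_cds=n_cds,
        neighbor_rate=rate,
        threshold=threshold,
        reject=n_stops > threshold,
        neighbor_ani=neighbor_ani,
        evaluated=True,
    )


def deviation_ani_rsq(points: Sequence[tuple[float, float]]) -> float | None:
    """Ordinary least-squares R-squared of |pseudogene density deviation|
    regressed on ANI.  Returns ``None`` when either coordinate has zero
    variance."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    dev = np.array([p[0] for p in points], dtype=float)
    ani = np.array([p[1] for p in points], dtype=float)
    if np.ptp(dev) == 0 or np.ptp(ani) == 0:
        return None
    r = np.corrcoef(ani, dev)[0, 1]
    return float(r * r)
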