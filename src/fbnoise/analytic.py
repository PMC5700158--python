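"""Exact steady-state protein statistics for the reduced bursty model.

The stationary law of the protein copy number under fast promoter
switching is, up to normalization,

    p_n  ∝  (p^n / n!) * (c_0/d) (c_1/d + 1) ... (c_{n-1}/d + n - 1),

where ``c_n`` is the effective transcription rate, ``p`` the per-mRNA
translation success probability and ``d`` the protein degradation rate.
For constant ``c`` this is the negative-binomial law.  From the exact
distribution this module computes moments, the noise decomposition

    eta = 1/<n> + d/(v <m>) + eta_f = 1/(q <n>) + eta_f,

the feedback coefficient ``eta_f = Cov(n, c_n) / (<n> <c_n>)`` whose sign
equals the feedback sign, the noise bounds attainable by negative
feedback, and the filter efficiency ``gamma = -eta_f / (eta - eta_f)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.stats import nbinom

from .kinetics import BurstParameters, RegulatoryFunction

__all__ = [
    "AnalyticError",
    "TruncationError",
    "SteadyStateDistribution",
    "NoiseDecomposition",
    "NoiseBounds",
    "steady_state_distribution",
    "negative_binomial_pmf",
    "distribution_moments",
    "feedback_coefficient_exact",
    "decompose_noise",
    "noise_bounds_negative",
    "efficiency",
    "tail_decay_check",
]

DEFAULT_TAIL_TOL = 1e-12
HARD_N_CAP = 10**6


class AnalyticError(ValueError):
    pass


class TruncationError(AnalyticError):
    """Support grew past the hard cap before reaching the tail tolerance."""


@dataclass
class SteadyStateDistribution:
    """Protein copy-number distribution on the truncated support ``0..N``.

    ``probs[n]`` is the probability of ``n`` proteins; ``truncation_mass``
    bounds the probability beyond the support.  ``log_probs`` is kept for
    analytic sources so tail ratios stay meaningful far below the float
    underflow threshold of ``probs``.
    """

    probs: np.ndarray
    truncation_mass: float
    source: str  # "analytic" | "empirical_simulation" | "empirical_data"
    log_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size == 0:
            raise AnalyticError("probs must be a non-empty 1-d vector")
        if np.any(self.probs < 0):
            raise AnalyticError("probabilities must be non-negative")
        total = self.probs.sum() + self.truncation_mass
        if abs(total - 1.0) > 1e-8:
            raise AnalyticError(f"distribution mass {total} not normalized")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probs.size)

    def to_tsv(self, path) -> None:
        """Write the distribution as a two-column (n, probability) TSV."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("n\tprobability\n")
            for n, pn in enumerate(self.probs):
                fh.write(f"{n}\t{pn:.17g}\n")


@dataclass
class NoiseDecomposition:
    """Decomposition of the protein noise ``eta = var / mean^2``."""

    eta: float
    poisson_term: float
    mrna_term: float
    feedback_free: float
    eta_f: float
    mean_n: float
    var_n: float
    mrna_mean: float
    eta_s: float | None = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


@dataclass
class NoiseBounds:
    """Noise limits achievable by a negative-feedback loop."""

    lower: float
    upper: float
    alpha: float
    efficiency_cap: float


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


def _log_weights(cvals: np.ndarray, p: float, d: float) -> np.ndarray:
    """Unnormalized log-weights of the stationary law on ``0..len(cvals)``.

    ``log w_{n+1} = log w_n + log p + log(c_n/d + n) - log(n+1)``.
    """
    n = np.arange(cvals.size, dtype=np.longdouble)
    cl = cvals.astype(np.longdouble)
    with np.errstate(divide="ignore"):
        steps = np.log(np.longdouble(p)) + np.log(cl / d + n) - np.log(n + 1.0)
    # extended precision throughout: unnormalized log-weights reach 1e4-1e5
    # in magnitude, where float64 rounding alone exceeds 1e-12
    logw = np.empty(cvals.size + 1, dtype=np.longdouble)
    logw[0] = 0.0
    np.cumsum(steps, out=logw[1:])
    # once a step is -inf (c_n/d + n == 0) all later weights are zero
    return logw


def steady_state_distribution(
    c: RegulatoryFunction,
    p: float,
    d: float,
    tail_tol: float = DEFAULT_TAIL_TOL,
    n_cap: int = HARD_N_CAP,
) -> SteadyStateDistribution:
    """Exact stationary protein distribution for regulatory function ``c``.

    All arithmetic is carried out in log space and normalized by
    log-sum-exp.  The support is extended until a conservative geometric
    bound on the remaining mass drops below ``tail_tol``: beyond the last
    computed ``n = M`` the weight ratio is at most
    ``rho = p (M + c_max/d) / (M + 1)``, so the remaining mass is bounded
    by ``w_M rho / (1 - rho)`` once ``rho < 1``.

    Raises
    ------
    TruncationError
        If the bound is not reached within ``n_cap`` support points.
    """
    if not 0.0 < p < 1.0:
        raise AnalyticError("burst probability p must lie in (0, 1)")
    if d <= 0:
        raise AnalyticError("degradation rate d must be > 0")
    if not 0 < tail_tol < 1:
        raise AnalyticError("tail_tol must lie in (0, 1)")

    size = 256
    while True:
        cvals = c.values(size - 1)
        if np.any(cvals < 0):
            raise AnalyticError("regulatory function must be non-negative")
        logw = _log_weights(cvals, p, d)[:size]
        cmax = float(np.max(cvals)) if c.hi is None else max(float(np.max(cvals)), c.hi)
        M = size - 1
        rho = p * (M + cmax / d) / (M + 1.0)
        mx = np.max(logw)
        log_total = mx + np.log(np.sum(np.exp(logw - mx)))  # longdouble LSE
        if rho < 1.0:
            with np.errstate(divide="ignore"):
                log_rem = float(logw[M] - log_total) + np.log(rho) - np.log1p(-rho)
            if log_rem <= np.log(tail_tol):
                break
        if size >= n_cap:
            achieved = np.exp(min(log_rem, 0.0)) if rho < 1 else np.inf
            raise TruncationError(
                f"support cap {n_cap} reached; remaining-mass bound {achieved:.3e} "
                f"exceeds tail_tol={tail_tol:.1e}"
            )
        size = min(2 * size, n_cap)

    log_probs = (logw - log_total).astype(float)
    probs = np.exp(log_probs)
    trunc = float(np.exp(log_rem)) if np.isfinite(log_rem) else 0.0
    return SteadyStateDistribution(
        probs=probs, truncation_mass=trunc, source="analytic", log_probs=log_probs
    )


# Stirling series coefficients B_{2k} / (2k (2k-1)) for log-gamma
_STIRLING = (
    "0.0833333333333333333333333333333333",    # 1/12
    "-0.00277777777777777777777777777777778",   # -1/360
    "0.000793650793650793650793650793650794",   # 1/1260
    "-0.000595238095238095238095238095238095",  # -1/1680
    "0.000841750841750841750841750841750842",   # 1/1188
    "-0.00191752691752691752691752691752692",   # -691/360360
    "0.00641025641025641025641025641025641",    # 1/156
)
_HALF_LOG_2PI = np.longdouble("0.918938533204672741780329736405617639")


def _lgamma_extended(x) -> np.ndarray:
    """log-gamma in extended precision (vectorized, x > 0).

    Shifts the argument above 32 via ``lgamma(x) = lgamma(x+1) - log(x)``
    and applies the Stirling series; absolute error is far below float64
    resolution, which double-precision gammaln cannot guarantee for the
    large arguments arising in long-tailed pmfs.
    """
    y = np.array(x, dtype=np.longdouble, copy=True)
    if np.any(y <= 0):
        raise AnalyticError("lgamma argument must be > 0")
    shift = np.zeros_like(y)
    mask = y < 32.0
    while np.any(mask):
        shift[mask] -= np.log(y[mask])
        y[mask] += 1.0
        mask = y < 32.0
    z = 1.0 / (y * y)
    series = np.longdouble(_STIRLING[-1])
    for coef in _STIRLING[-2::-1]:
        series = series * z + np.longdouble(coef)
    series = series / y
    return (y - 0.5) * np.log(y) - y + _HALF_LOG_2PI + series + shift


def negative_binomial_pmf(
    c: float, d: float, p: float, tail_tol: float = DEFAULT_TAIL_TOL
) -> SteadyStateDistribution:
    """Closed-form no-feedback stationary law (negative binomial).

    ``p_n = (p^n / n!) * Gamma(c/d + n) / Gamma(c/d) * q^(c/d)`` — the
    negative binomial with shape ``c/d`` and success probability ``q``.
    The log-pmf is evaluated in extended precision so it can serve as an
    elementwise reference for the product-form distribution.
    """
    if c < 0:
        raise AnalyticError("transcription rate c must be >= 0")
    if d <= 0:
        raise AnalyticError("degradation rate d must be > 0")
    if not 0.0 < p < 1.0:
        raise AnalyticError("burst probability p must lie in (0, 1)")
    if c == 0:
        return SteadyStateDistribution(
            probs=np.array([1.0]), truncation_mass=0.0, source="analytic",
            log_probs=np.array([0.0]),
        )
    q = 1.0 - p
    rv = nbinom(c / d, q)
    hi = int(rv.ppf(1.0 - tail_tol)) + 2
    while rv.sf(hi - 1) > tail_tol and hi < HARD_N_CAP:
        hi *= 2
    n = np.arange(hi, dtype=np.longdouble)
    cd = np.longdouble(c) / np.longdouble(d)
    lg = (
        n * np.log(np.longdouble(p))
        + _lgamma_extended(cd + n)
        - _lgamma_extended(cd)
        - _lgamma_extended(n + 1.0)
        + cd * np.log(np.longdouble(q))
    )
    log_probs = lg.astype(float)
    return SteadyStateDistribution(
        probs=np.exp(log_probs),
        truncation_mass=float(rv.sf(hi - 1)),
        source="analytic",
        log_probs=log_probs,
    )


# ---------------------------------------------------------------------------
# moments and decomposition
# ---------------------------------------------------------------------------


def distribution_moments(dist: SteadyStateDistribution) -> tuple[float, float]:
    """Truncated-sum mean and variance of a distribution."""
    w = dist.probs
    total = w.sum()
    if total <= 0:
        raise AnalyticError("degenerate all-zero distribution")
    n = dist.support
    mean = float(n @ w) / total
    var = float((n - mean) ** 2 @ w) / total
    return mean, max(var, 0.0)


def feedback_coefficient_exact(
    dist: SteadyStateDistribution, c: RegulatoryFunction
) -> float:
    """Feedback coefficient ``eta_f = Cov(n, c_n) / (<n> <c_n>)``."""
    w = dist.probs / dist.probs.sum()
    n = dist.support.astype(float)
    cvals = c.values(dist.probs.size - 1)
    mean_n = float(n @ w)
    mean_c = float(cvals @ w)
    if mean_n <= 0 or mean_c <= 0:
        raise AnalyticError("feedback coefficient undefined for zero mean")
    cov = float(((n - mean_n) * (cvals - mean_c)) @ w)
    return cov / (mean_n * mean_c)


def decompose_noise(
    dist: SteadyStateDistribution,
    c: RegulatoryFunction,
    bursts: BurstParameters,
    d: float,
    v: float,
) -> NoiseDecomposition:
    """Decompose the protein noise into its biophysical contributions.

    The mRNA mean of the fast-switching reduced model is ``<m> = <c_n>/v``
    so the three-term and two-term decompositions agree identically for
    analytic distributions.  For empirical sources the residual
    ``eta - 1/(q <n>) - eta_f`` is reported as the promoter-switching
    noise ``eta_s``.
    """
    mean_n, var_n = distribution_moments(dist)
    if mean_n <= 0:
        raise AnalyticError("noise undefined for zero mean")
    w = dist.probs / dist.probs.sum()
    cvals = c.values(dist.probs.size - 1)
    mean_c = float(cvals @ w)
    if mean_c <= 0:
        raise AnalyticError("mean transcription rate must be positive")
    eta = var_n / mean_n**2
    eta_f = feedback_coefficient_exact(dist, c)
    feedback_free = 1.0 / (bursts.q * mean_n)
    mrna_mean = mean_c / v
    decomp = NoiseDecomposition(
        eta=eta,
        poisson_term=1.0 / mean_n,
        mrna_term=d / (v * mrna_mean),
        feedback_free=feedback_free,
        eta_f=eta_f,
        mean_n=mean_n,
        var_n=var_n,
        mrna_mean=mrna_mean,
    )
    if dist.source != "analytic":
        decomp.eta_s = eta - feedback_free - eta_f
    return decomp


def noise_bounds_negative(
    q: float, mean_n: float, alpha: float, p: float, d: float
) -> NoiseBounds:
    """Noise limits for a negative-feedback circuit of steepness ``alpha``.

    ``1/(q<n>) * 1/(1 + alpha p / (d q))  <=  eta  <  1/(q<n>)`` and the
    filter efficiency obeys ``gamma <= 1/(1 + d q / (alpha p))``.
    """
    for name, val in (("q", q), ("mean_n", mean_n), ("p", p), ("d", d)):
        if val <= 0:
            raise AnalyticError(f"{name} must be > 0")
    if alpha < 0:
        raise AnalyticError("steepness alpha must be >= 0")
    upper = 1.0 / (q * mean_n)
    if alpha == 0.0:
        warnings.warn(
            "alpha = 0: bounds collapse to the no-feedback value", stacklevel=2
        )
        return NoiseBounds(lower=upper, upper=upper, alpha=0.0, efficiency_cap=0.0)
    lower = upper / (1.0 + alpha * p / (d * q))
    cap = 1.0 / (1.0 + d * q / (alpha * p))
    return NoiseBounds(lower=lower, upper=upper, alpha=alpha, efficiency_cap=cap)


def efficiency(eta: float, eta_f: float) -> float:
    """Noise-filter efficiency ``gamma = -eta_f / (eta - eta_f)``.

    Defined only for negative feedback (``eta_f < 0``); lies in (0, 1).
    """
    if eta <= 0:
        raise AnalyticError("eta must be > 0")
    if eta_f >= 0:
        raise AnalyticError("efficiency is defined only for negative feedback (eta_f < 0)")
    return -eta_f / (eta - eta_f)


def tail_decay_check(
    dist: SteadyStateDistribution, q: float, percentile: float = 0.99
) -> float:
    """Maximal deviation of the log tail ratio from ``log p``.

    Over the support beyond the given percentile, the stationary law
    decays geometrically: ``log(p_{n+1}/p_n) -> log p = log(1 - q)``.
    Returns ``max |log(p_{n+1}/p_n) - log p|`` over the usable tail.
    """
    if dist.log_probs is None:
        raise AnalyticError("tail_decay_check requires an analytic distribution")
    logp = np.log1p(-q)
    cdf = np.cumsum(dist.probs)
    start = int(np.searchsorted(cdf, percentile))
    lp = dist.log_probs
    usable = np.isfinite(lp) & (lp > -690.0)  # keep clear of exp underflow
    idx = np.arange(lp.size - 1)
    mask = (idx >= start) & usable[:-1] & usable[1:]
    if mask.sum() < 3:
        raise AnalyticError("tail too short for a decay-rate check")
    ratios = lp[1:][mask] - lp[:-1][mask]
    return float(np.max(np.abs(ratios - logp)))
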