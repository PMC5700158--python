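"""Feedback-sign inference from single-cell protein measurements.

The feedback coefficient is experimentally accessible through three
digital features of the stationary distribution — mean, variance and
exponential tail-decay rate ``q``:

    eta_f = sigma^2 / <n>^2 - 1 / (q <n>).

Because the noise is dimensionless and ``q`` scales inversely with the
measurement unit while the mean scales with it, the estimate applies
unchanged to protein concentrations (arbitrary fluorescence units), not
only to copy numbers.  Uncertainty comes from a nonparametric bootstrap
over cells, and the feedback call is a two-sided z-test on ``eta_f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InferenceError",
    "SingleCellDataset",
    "TailFit",
    "FeedbackInference",
    "estimate_moments",
    "estimate_decay_rate",
    "infer_feedback",
    "analyze_panel",
    "load_dataset",
]

DEFAULT_WINDOW = (0.60, 0.999)
MIN_USABLE_BINS = 8
DEFAULT_MIN_CELLS = 500


class InferenceError(ValueError):
    pass


@dataclass
class SingleCellDataset:
    """One-condition vector of non-negative single-cell measurements."""

    values: np.ndarray
    is_concentration: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise InferenceError("dataset is empty")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InferenceError("measurements must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.size

    def scaled(self, V: float) -> "SingleCellDataset":
        """Concentration view ``x = n / V`` of the same cells."""
        if V <= 0:
            raise InferenceError("scale V must be > 0")
        return SingleCellDataset(
            values=self.values / V, is_concentration=True, label=self.label
        )


@dataclass
class TailFit:
    """Diagnostics of the exponential tail fit."""

    q_hat: float
    window: tuple[float, float]
    n_bins: int
    bin_width: float
    r_squared: float
    power: float  # fitted exponent of the power-law prefactor
    non_decreasing: bool = False


@dataclass
class FeedbackInference:
    """Point estimates, bootstrap uncertainty and topology call."""

    mean_hat: float
    var_hat: float
    q_hat: float
    eta_hat: float
    feedback_free_hat: float
    eta_f_hat: float
    se_eta_f: float
    z: float
    call: str  # "positive" | "negative" | "none"
    tail_fit: TailFit
    n_cells: int
    label: str = ""
    reliable: bool = True
    n_bootstrap_failures: int = 0
    se_eta: float = np.nan
    se_feedback_free: float = np.nan


def load_dataset(path, is_concentration: bool = False, label: str | None = None) -> SingleCellDataset:
    """Read a one-column CSV/TSV (optional header) of measurements."""
    from pathlib import Path

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, header=None)
    col = df.iloc[:, 0]
    if not np.issubdtype(col.dtype, np.number):  # header row present
        df = pd.read_csv(path, sep=sep)
        col = df.iloc[:, 0]
    return SingleCellDataset(
        values=col.to_numpy(dtype=float),
        is_concentration=is_concentration,
        label=label if label is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def estimate_moments(data: SingleCellDataset) -> tuple[float, float]:
    """Sample mean and unbiased sample variance."""
    v = data.values
    if v.size < 2:
        raise InferenceError("need at least 2 cells to estimate moments")
    mean = float(v.mean())
    var = float(v.var(ddof=1))
    if var == 0.0:
        raise InferenceError("constant data: variance is zero")
    return mean, var


def _lattice_spacing(values: np.ndarray) -> float | None:
    """Granularity of lattice-valued data, or None if effectively continuous.

    Copy-number data live on the integer lattice; the same cells recorded
    in concentration units ``n / V`` live on a lattice of spacing ``1/V``.
    Binning on lattice multiples makes the tail fit exactly equivariant
    under rescaling.
    """
    uniq = np.unique(values)
    if uniq.size < 3:
        return None
    g = float(np.min(np.diff(uniq)))
    if g <= 0:
        return None
    if (uniq[-1] - uniq[0]) / g > 1e5:
        return None  # too fine to be meaningful granularity
    k = values / g
    if np.max(np.abs(k - np.round(k))) > 1e-6:
        return None
    return g


def _tail_histogram(
    values: np.ndarray,
    window: tuple[float, float],
    min_bin_count: int,
    keep_sparse: bool,
) -> tuple[np.ndarray, np.ndarray, float, float | None]:
    """Bin the tail window; returns (centers, counts, width, lattice spacing).

    Lattice data use bins of an integer number of lattice steps with
    edges offset half a step, so every observation is far from a bin
    boundary; continuous data use the Freedman-Diaconis width on the
    window.  ``keep_sparse`` retains low-count (including empty) bins, as
    appropriate for a count-likelihood fit; otherwise bins below
    ``min_bin_count`` are dropped and the width widened until enough
    usable bins remain.
    """
    lo = float(np.quantile(values, window[0]))
    hi = float(np.quantile(values, window[1]))
    tail = values[(values >= lo) & (values <= hi)]
    if tail.size < MIN_USABLE_BINS * max(min_bin_count, 1):
        raise InferenceError(
            f"only {tail.size} cells in the tail window {window}; widen the "
            "window or collect more cells"
        )
    g = _lattice_spacing(values)
    if g is not None:
        lo = g * (np.floor(lo / g) - 0.5)
        widths: Sequence[float] = [g * k for k in (1, 2, 3, 5, 8, 13, 21, 34)]
    else:
        q25, q75 = np.quantile(tail, [0.25, 0.75])
        base = 2.0 * float(q75 - q25) / tail.size ** (1.0 / 3.0)
        if base <= 0:
            raise InferenceError("degenerate tail: zero Freedman-Diaconis width")
        widths = [base, 2 * base, 4 * base]
    for width in widths:
        edges = np.arange(lo, hi + width, width)
        if edges.size < MIN_USABLE_BINS + 1:
            continue
        counts, edges = np.histogram(tail, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if keep_sparse:
            keep = centers > 0
        else:
            keep = (counts >= min_bin_count) & (centers > 0)
        if keep.sum() >= MIN_USABLE_BINS and (keep_sparse or counts[keep].sum() > 0):
            return centers[keep], counts[keep].astype(float), float(width), g
        if keep_sparse:
            break
    raise InferenceError(
        f"fewer than {MIN_USABLE_BINS} usable tail bins; widen the window or "
        "collect more cells"
    )


def _poisson_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Poisson log-linear fit (IRLS) with standardized design columns."""
    mu_x = X[:, 1:].mean(axis=0)
    sd_x = X[:, 1:].std(axis=0)
    sd_x[sd_x == 0] = 1.0
    Z = X.copy()
    Z[:, 1:] = (X[:, 1:] - mu_x) / sd_x
    beta = np.zeros(Z.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-300))
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -500, 500)
        mu = np.exp(eta)
        WZ = Z * mu[:, None]
        try:
            step = np.linalg.solve(Z.T @ WZ, Z.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise InferenceError(f"tail fit failed: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    out = np.empty_like(beta)
    out[1:] = beta[1:] / sd_x
    out[0] = beta[0] - float(out[1:] @ mu_x)
    return out


def estimate_decay_rate(
    data: SingleCellDataset,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_bin_count: int = 5,
    tail_model: str = "exp_powerlaw",
    method: str = "glm",
) -> tuple[float, TailFit]:
    """Exponential decay rate of the distribution tail.

    Fits ``log f(x) = const + power * log(x) + slope * x`` over the tail
    window and returns ``q_hat = -slope`` (per copy for counts, per
    concentration unit otherwise).  The ``log(x)`` regressor absorbs the
    power-law prefactor that the exact stationary law carries in front of
    its geometric tail; without it the fitted slope is biased at any
    finite copy number.  ``method="glm"`` (default) maximizes the Poisson
    likelihood of the bin counts, which is well behaved in sparse tails;
    ``method="ols"`` is a plain least-squares fit of log relative
    frequency using only bins with at least ``min_bin_count`` cells.
    ``tail_model="exp"`` drops the power-law regressor.
    """
    if not (0.0 <= window[0] < window[1] <= 1.0):
        raise InferenceError("window must be an increasing quantile pair in [0, 1]")
    if tail_model not in ("exp_powerlaw", "exp"):
        raise InferenceError(f"unknown tail_model {tail_model!r}")
    if method not in ("glm", "ols"):
        raise InferenceError(f"unknown method {method!r}")
    centers, counts, width, g = _tail_histogram(
        data.values, window, min_bin_count, keep_sparse=(method == "glm")
    )
    n_total = data.values.size
    cols = [np.ones_like(centers), centers]
    if tail_model == "exp_powerlaw":
        cols.append(np.log(centers))
    X = np.column_stack(cols)
    if method == "glm":
        beta = _poisson_irls(X, counts)
        mu = np.exp(np.clip(X @ beta, -500, 500))
        pos = counts > 0
        y = np.log(counts[pos])
        resid = y - np.log(mu[pos])
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        y = np.log(counts / (n_total * width))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    slope = float(beta[1])
    power = float(beta[2]) if tail_model == "exp_powerlaw" else 0.0
    if g is not None and slope < 0:
        # per-lattice-step tail ratio e^(slope g) estimates the burst
        # success probability p directly, so the decay rate in data units
        # is (1 - p) / g; exact for a geometric tail, -> -slope as g -> 0,
        # and exactly equivariant under rescaling the measurement unit
        q_hat = float((1.0 - np.exp(slope * g)) / g)
    else:
        q_hat = -slope  # decay per measurement unit (qV)
    fit = TailFit(
        q_hat=q_hat,
        window=window,
        n_bins=centers.size,
        bin_width=width,
        r_squared=r2,
        power=power,
        non_decreasing=slope >= 0,
    )
    if fit.non_decreasing:
        import warnings

        warnings.warn(
            "tail fit slope is non-negative: distribution tail does not decay",
            stacklevel=2,
        )
    return fit.q_hat, fit


def _point_estimates(values, window, min_bin_count, tail_model, method,
                     is_concentration=False):
    ds = SingleCellDataset(values=values, is_concentration=is_concentration)
    mean, var = estimate_moments(ds)
    q_hat, fit = estimate_decay_rate(ds, window, min_bin_count, tail_model, method)
    if q_hat <= 0 or mean <= 0:
        raise InferenceError("non-positive decay rate or mean")
    eta = var / mean**2
    ff = 1.0 / (q_hat * mean)
    return mean, var, q_hat, eta, ff, eta - ff, fit


def infer_feedback(
    data: SingleCellDataset,
    window: tuple[float, float] = DEFAULT_WINDOW,
    B: int = 200,
    seed: int = 0,
    z_threshold: float = 1.96,
    min_bin_count: int = 5,
    min_cells: int = DEFAULT_MIN_CELLS,
    tail_model: str = "exp_powerlaw",
    method: str = "glm",
) -> FeedbackInference:
    """Estimate the feedback coefficient and call the feedback sign.

    The full pipeline (moments + tail fit) is re-run on ``B`` seeded
    bootstrap resamples of the cells; the bootstrap standard deviation of
    ``eta_f`` yields ``z = eta_f / se``, and the call is positive/negative
    when ``|z|`` exceeds ``z_threshold``, otherwise none.  If more than
    10% of replicates fail the inference is marked unreliable.
    """
    if data.n_cells < min_cells:
        raise InferenceError(
            f"{data.n_cells} cells < configured minimum {min_cells}"
        )
    mean, var, q_hat, eta, ff, eta_f, fit = _point_estimates(
        data.values, window, min_bin_count, tail_model, method,
        data.is_concentration,
    )
    rng = np.random.default_rng(seed)
    boots = np.full(B, np.nan)
    boots_eta = np.full(B, np.nan)
    boots_ff = np.full(B, np.nan)
    failures = 0
    for b in range(B):
        idx = rng.integers(0, data.n_cells, size=data.n_cells)
        try:
            *_rest, eta_b, ff_b, ef_b, _ = _point_estimates(
                data.values[idx], window, min_bin_count, tail_model, method,
                data.is_concentration,
            )
            boots[b] = ef_b
            boots_eta[b] = eta_b
            boots_ff[b] = ff_b
        except InferenceError:
            failures += 1
    ok = np.isfinite(boots)
    if ok.sum() < 2:
        raise InferenceError("bootstrap failed in (almost) every replicate")
    se = float(np.std(boots[ok], ddof=1))
    z = eta_f / se if se > 0 else np.inf * np.sign(eta_f)
    if z > z_threshold:
        call = "positive"
    elif z < -z_threshold:
        call = "negative"
    else:
        call = "none"
    return FeedbackInference(
        mean_hat=mean,
        var_hat=var,
        q_hat=q_hat,
        eta_hat=eta,
        feedback_free_hat=ff,
        eta_f_hat=eta_f,
        se_eta_f=se,
        z=float(z),
        call=call,
        tail_fit=fit,
        n_cells=data.n_cells,
        label=data.label,
        reliable=failures <= 0.1 * B,
        n_bootstrap_failures=failures,
        se_eta=float(np.std(boots_eta[ok], ddof=1)),
        se_feedback_free=float(np.std(boots_ff[ok], ddof=1)),
    )


def analyze_panel(
    datasets: Sequence[SingleCellDataset],
    window: tuple[float, float] = DEFAULT_WINDOW,
    B: int = 200,
    seed: int = 0,
    z_threshold: float = 1.96,
    min_bin_count: int = 5,
    min_cells: int = DEFAULT_MIN_CELLS,
    tail_model: str = "exp_powerlaw",
    method: str = "glm",
) -> pd.DataFrame:
    """Run :func:`infer_feedback` per condition; failures are isolated.

    Returns one row per dataset with the noise, feedback-free noise and
    feedback coefficient (plus bootstrap SEs) needed for a dose-response
    panel plot.
    """
    if len(datasets) == 0:
        raise InferenceError("panel needs at least one dataset")
    rows = []
    for k, ds in enumerate(datasets):
        base = dict(label=ds.label, n_cells=ds.n_cells, error="")
        try:
            inf = infer_feedback(
                ds, window=window, B=B, seed=seed + k, z_threshold=z_threshold,
                min_bin_count=min_bin_count, min_cells=min_cells,
                tail_model=tail_model, method=method,
            )
            base.update(
                mean_hat=inf.mean_hat, var_hat=inf.var_hat, q_hat=inf.q_hat,
                eta_hat=inf.eta_hat, feedback_free_hat=inf.feedback_free_hat,
                eta_f_hat=inf.eta_f_hat, se_eta_f=inf.se_eta_f,
                se_eta=inf.se_eta, se_feedback_free=inf.se_feedback_free,
                z=inf.z, call=inf.call, reliable=inf.reliable,
                tail_r_squared=inf.tail_fit.r_squared,
            )
        except InferenceError as exc:
            base.update(
                mean_hat=np.nan, var_hat=np.nan, q_hat=np.nan, eta_hat=np.nan,
                feedback_free_hat=np.nan, eta_f_hat=np.nan, se_eta_f=np.nan,
                se_eta=np.nan, se_feedback_free=np.nan, z=np.nan,
                call="failed", reliable=False, tail_r_squared=np.nan,
                error=str(exc),
            )
        rows.append(base)
    return pd.DataFrame(rows)
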