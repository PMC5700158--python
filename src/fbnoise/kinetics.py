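"""Kinetic description of an autoregulated gene circuit.

A circuit couples promoter switching (protein-dependent rates ``a_fn`` /
``b_fn``), transcription (rate ``s`` when active, basal rate ``r`` when
inactive), translation (``u`` per mRNA) and first-order degradation of
mRNA (``v``) and protein (``d``).  Under fast promoter switching the
promoter state averages out and transcription proceeds at the effective
rate ``c_n = (a_n s + b_n r) / (a_n + b_n)``, whose monotonicity in the
protein copy number ``n`` encodes the feedback sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "KineticsError",
    "InvalidKineticsError",
    "GeneCircuit",
    "BurstParameters",
    "RegulatoryFunction",
    "SwitchingSpec",
    "effective_transcription_rate",
    "burst_parameters",
    "hill_regulatory_function",
    "hill_steepness",
    "classify_topology",
    "regulatory_function",
    "circuit_from_config",
    "regulatory_from_config",
]


class KineticsError(ValueError):
    """Invalid kinetic parameterization."""


class InvalidKineticsError(KineticsError):
    """Raised when switching rates are degenerate at some copy number."""


# ---------------------------------------------------------------------------
# promoter switching-rate specifications
# ---------------------------------------------------------------------------

_SWITCHING_FORMS = ("constant", "linear_activation", "linear_inactivation", "hill")


@dataclass(frozen=True)
class SwitchingSpec:
    """Parametric form of the promoter switching rates ``a_n`` and ``b_n``.

    Supported forms (``strength`` defaults to 0, ``h`` to 1):

    ``constant``
        ``a_n = a``, ``b_n = b`` (no feedback through switching).
    ``linear_activation``
        ``a_n = a + strength * n``, ``b_n = b`` (positive feedback).
    ``linear_inactivation``
        ``a_n = a``, ``b_n = b + strength * n`` (negative feedback).
    ``hill``
        ``a_n = a``, ``b_n = n ** h``; yields the generalized Hill
        effective rate ``c(x) = (a s + x^h r) / (a + x^h)``.
    """

    form: str
    a: float = 0.0
    b: float = 0.0
    strength: float = 0.0
    h: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in _SWITCHING_FORMS:
            raise KineticsError(
                f"unknown switching form {self.form!r}; expected one of {_SWITCHING_FORMS}"
            )
        for name in ("a", "b", "strength"):
            if getattr(self, name) < 0:
                raise KineticsError(f"switching parameter {name} must be >= 0")
        if self.form == "hill" and self.h < 1:
            raise KineticsError("Hill coefficient h must be >= 1")

    def a_fn(self, n):
        n = np.asarray(n, dtype=float)
        if self.form == "linear_activation":
            return self.a + self.strength * n
        return np.broadcast_to(np.float64(self.a), n.shape).copy() if n.ndim else np.float64(self.a)

    def b_fn(self, n):
        n = np.asarray(n, dtype=float)
        if self.form == "linear_inactivation":
            return self.b + self.strength * n
        if self.form == "hill":
            return np.power(n, self.h)
        return np.broadcast_to(np.float64(self.b), n.shape).copy() if n.ndim else np.float64(self.b)

    def affine_coefficients(self) -> tuple[float, float, float, float] | None:
        """Return ``(a0, a1, b0, b1)`` with ``a_n = a0 + a1 n`` if affine."""
        if self.form == "constant":
            return (self.a, 0.0, self.b, 0.0)
        if self.form == "linear_activation":
            return (self.a, self.strength, self.b, 0.0)
        if self.form == "linear_inactivation":
            return (self.a, 0.0, self.b, self.strength)
        if self.form == "hill" and self.h == 1.0:
            return (self.a, 0.0, 0.0, 1.0)
        return None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCircuit:
    """Full kinetic parameterization of the three-stage circuit.

    Parameters
    ----------
    s, r : float
        Transcription rates with the promoter active / inactive.
    u : float
        Translation rate per mRNA.
    v : float
        mRNA degradation rate.
    d : float
        Protein degradation rate.
    switching : SwitchingSpec
        Protein-dependent promoter switching rates ``a_n`` / ``b_n``.
    """

    s: float
    r: float
    u: float
    v: float
    d: float
    switching: SwitchingSpec

    def __post_init__(self) -> None:
        if self.s < 0 or self.r < 0:
            raise KineticsError("transcription rates s, r must be >= 0")
        for name in ("u", "v", "d"):
            if getattr(self, name) <= 0:
                raise KineticsError(f"rate {name} must be > 0")

    def a_fn(self, n):
        return self.switching.a_fn(n)

    def b_fn(self, n):
        return self.switching.b_fn(n)


@dataclass(frozen=True)
class BurstParameters:
    """Translational burst parameters of the reduced model.

    ``p`` is the probability that an mRNA produces a protein before it
    dies, ``q = 1 - p`` the complement (and the exponential decay rate of
    the protein distribution tail), and ``lam = v / d`` the ratio of
    protein to mRNA lifetimes.
    """

    p: float
    q: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise KineticsError("burst probability p must lie in (0, 1)")
        if self.p + self.q != 1.0:
            raise KineticsError("p + q must equal 1 exactly")
        if self.lam <= 0:
            raise KineticsError("lifetime ratio lam must be > 0")


@dataclass(frozen=True)
class RegulatoryFunction:
    """Effective transcription rate ``c`` as a function of protein level.

    ``c_fn`` accepts a scalar or ndarray of non-negative values (integer
    copy numbers or real concentrations).  ``declared_topology`` records
    the feedback sign implied by construction, or ``"unknown"``.
    """

    c_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    declared_topology: str = "unknown"
    lo: float | None = None  # min(r, s) when built from a circuit
    hi: float | None = None  # max(r, s)

    def __call__(self, x):
        out = self.c_fn(np.asarray(x, dtype=float))
        return np.asarray(out, dtype=float)

    def values(self, n_max: int) -> np.ndarray:
        """Evaluate on the integer grid ``0..n_max`` inclusive."""
        n = np.arange(n_max + 1, dtype=float)
        try:
            vals = np.asarray(self.c_fn(n), dtype=float)
            if vals.shape != n.shape:
                raise ValueError
        except Exception:
            vals = np.array([float(self.c_fn(x)) for x in n])
        return vals


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def effective_transcription_rate(circuit: GeneCircuit, n: int) -> float:
    """Fast-switching effective transcription rate at protein count ``n``.

    Returns ``(a_n s + b_n r) / (a_n + b_n)``, which always lies between
    the basal and active transcription rates.
    """
    a = float(circuit.a_fn(n))
    b = float(circuit.b_fn(n))
    if a < 0 or b < 0:
        raise InvalidKineticsError(f"negative switching rate at n={n}: a={a}, b={b}")
    tot = a + b
    if tot <= 0:
        raise InvalidKineticsError(
            f"a_n + b_n = 0 at n={n}: effective transcription rate undefined"
        )
    return (a * circuit.s + b * circuit.r) / tot


def burst_parameters(circuit: GeneCircuit) -> BurstParameters:
    """Burst parameters ``(p, q, lam)`` of the reduced bursty model.

    The smaller of ``p = u/(u+v)`` and ``q = v/(u+v)`` is computed
    directly and the other as its complement, so ``p + q = 1`` exactly
    and ``p/q = u/v`` holds to full relative precision.
    """
    u, v = circuit.u, circuit.v
    if u <= v:
        p = u / (u + v)
        q = 1.0 - p
    else:
        q = v / (u + v)
        p = 1.0 - q
    return BurstParameters(p=p, q=q, lam=circuit.v / circuit.d)


def regulatory_function(circuit: GeneCircuit, n_probe: int = 1000) -> RegulatoryFunction:
    """Build the regulatory function ``c`` of a circuit.

    The function is defined on real arguments by evaluating the switching
    rates at ``x``; the integer version used by the steady-state
    distribution is the same function sampled at ``x = n``.  The topology
    is classified numerically on ``0..n_probe``.
    """

    s, r = circuit.s, circuit.r

    def c_fn(x):
        a = np.asarray(circuit.a_fn(x), dtype=float)
        b = np.asarray(circuit.b_fn(x), dtype=float)
        tot = a + b
        if np.any(tot <= 0):
            bad = np.argwhere(tot <= 0).ravel()
            raise InvalidKineticsError(f"a + b = 0 at evaluation point index {bad[:1]}")
        return (a * s + b * r) / tot

    rf = RegulatoryFunction(c_fn=c_fn, declared_topology="unknown", lo=min(r, s), hi=max(r, s))
    topo = classify_topology(rf, n_probe)
    return RegulatoryFunction(c_fn=c_fn, declared_topology=topo, lo=min(r, s), hi=max(r, s))


def hill_regulatory_function(a: float, s: float, r: float, h: float = 1.0) -> RegulatoryFunction:
    """Generalized Hill regulatory function ``c(x) = (a s + x^h r) / (a + x^h)``.

    ``c(0) = s`` and ``c(x) -> r`` as ``x -> inf``; the declared topology is
    negative for ``s > r``, positive for ``s < r`` and none for ``s == r``.
    """
    if a <= 0:
        raise KineticsError("Hill parameter a must be > 0")
    if h < 1:
        raise KineticsError("Hill coefficient h must be >= 1")
    if s < 0 or r < 0:
        raise KineticsError("rates s, r must be >= 0")

    def c_fn(x):
        xh = np.power(np.asarray(x, dtype=float), h)
        return (a * s + xh * r) / (a + xh)

    topology = "none" if s == r else ("negative" if s > r else "positive")
    return RegulatoryFunction(c_fn=c_fn, declared_topology=topology, lo=min(r, s), hi=max(r, s))


def hill_steepness(a: float, s: float, r: float, h: float = 1.0) -> float:
    """Maximal slope ``sup |c'(x)|`` of the generalized Hill function.

    Closed form ``(h-1)^(1-1/h) (h+1)^(1+1/h) / (4h) * (s-r) / a^(1/h)``;
    the ``(h-1)^(1-1/h)`` factor is evaluated as its limit 1 at ``h = 1``,
    where the expression reduces to ``(s - r) / a``.
    """
    if a <= 0:
        raise KineticsError("Hill parameter a must be > 0")
    if h < 1:
        raise KineticsError("Hill coefficient h must be >= 1")
    if s < r:
        raise KineticsError("hill_steepness expects s >= r")
    if s == r:
        return 0.0
    if h == 1.0:
        return (s - r) / a
    pref = (h - 1.0) ** (1.0 - 1.0 / h) * (h + 1.0) ** (1.0 + 1.0 / h) / (4.0 * h)
    return pref * (s - r) / a ** (1.0 / h)


def classify_topology(
    c: RegulatoryFunction, n_max: int, rtol: float = 1e-12
) -> str:
    """Classify feedback sign from the monotonicity of ``c`` on ``0..n_max``.

    Differences below ``rtol * max(|c|, 1)`` count as zero so floating
    noise cannot be mistaken for feedback.  Returns one of ``positive``,
    ``negative``, ``none`` or ``non-monotone``.
    """
    if n_max < 2:
        raise KineticsError("n_max must be >= 2")
    vals = c.values(n_max)
    scale = max(float(np.max(np.abs(vals))), 1.0)
    if c.hi is not None:
        scale = max(scale, abs(c.hi))
    tol = rtol * scale
    diffs = np.diff(vals)
    up = np.any(diffs > tol)
    down = np.any(diffs < -tol)
    if up and down:
        return "non-monotone"
    if up:
        return "positive"
    if down:
        return "negative"
    return "none"


# ---------------------------------------------------------------------------
# config parsing
# ---------------------------------------------------------------------------

_CIRCUIT_KEYS = {"s", "r", "u", "v", "d", "switching"}
_SWITCHING_KEYS = {"form", "a", "b", "strength", "h"}


def circuit_from_config(cfg: Mapping) -> GeneCircuit:
    """Build a :class:`GeneCircuit` from a plain config mapping.

    Expected keys: ``s, r, u, v, d`` plus a ``switching`` block
    ``{"form": ..., "a": ..., "b": ..., "strength": ..., "h": ...}``.
    Unknown keys are rejected.
    """
    unknown = set(cfg) - _CIRCUIT_KEYS
    if unknown:
        raise KineticsError(f"unknown circuit config keys: {sorted(unknown)}")
    missing = _CIRCUIT_KEYS - set(cfg)
    if missing:
        raise KineticsError(f"missing circuit config keys: {sorted(missing)}")
    sw = cfg["switching"]
    unknown = set(sw) - _SWITCHING_KEYS
    if unknown:
        raise KineticsError(f"unknown switching config keys: {sorted(unknown)}")
    spec = SwitchingSpec(
        form=sw.get("form", "constant"),
        a=float(sw.get("a", 0.0)),
        b=float(sw.get("b", 0.0)),
        strength=float(sw.get("strength", 0.0)),
        h=float(sw.get("h", 1.0)),
    )
    return GeneCircuit(
        s=float(cfg["s"]), r=float(cfg["r"]), u=float(cfg["u"]),
        v=float(cfg["v"]), d=float(cfg["d"]), switching=spec,
    )


def regulatory_from_config(cfg: Mapping) -> RegulatoryFunction:
    """Build a :class:`RegulatoryFunction` directly from a config mapping.

    Two forms are supported: ``{"form": "constant", "c": value}`` and
    ``{"form": "hill", "a": ..., "s": ..., "r": ..., "h": ...}``.
    """
    form = cfg.get("form")
    if form == "constant":
        unknown = set(cfg) - {"form", "c"}
        if unknown:
            raise KineticsError(f"unknown regulatory config keys: {sorted(unknown)}")
        c0 = float(cfg["c"])
        if c0 < 0:
            raise KineticsError("constant rate c must be >= 0")
        return RegulatoryFunction(
            c_fn=lambda x: np.full_like(np.asarray(x, dtype=float), c0),
            declared_topology="none", lo=c0, hi=c0,
        )
    if form == "hill":
        unknown = set(cfg) - {"form", "a", "s", "r", "h"}
        if unknown:
            raise KineticsError(f"unknown regulatory config keys: {sorted(unknown)}")
        return hill_regulatory_function(
            a=float(cfg["a"]), s=float(cfg["s"]), r=float(cfg["r"]),
            h=float(cfg.get("h", 1.0)),
        )
    raise KineticsError(f"unknown regulatory function form: {form!r}")
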