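"""Parametric FRET-lines: static, dynamic, multi-state and generic generators.

A FRET-line is a parametric curve in the plane of the burst observables
(E, tau_F) obtained by varying a single model parameter while holding the
rest fixed.  Every line here is computed through the same recipe: evaluate
the first two moments of the donor-lifetime distribution as a function of
the parameter, then map them to observables (``E = 1 - m1/tauD0``,
``tau_F = m2/m1``) and to the moment difference Gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .core import (
    FretContext,
    LifetimeMixture,
    MomentPair,
    TAU_EPS,
    mixture_moments,
)

__all__ = [
    "FretState",
    "LineCurve",
    "ContinuousLifetimeDistribution",
    "build_curve",
    "static_line_ideal",
    "dynamic_line_two_state",
    "dynamic_shift",
    "dynamic_shift_numeric",
    "line_from_lifetime_distribution",
    "limiting_lines_three_state",
    "fractions_from_position",
    "mean_variance_dynamic_line",
]

LINE_KINDS = (
    "static_ideal",
    "static_linker",
    "dynamic",
    "gaussian_chain",
    "wlc",
    "order_disorder",
    "static_PR_slow",
    "static_PR_fast",
    "dynamic_PR",
    "mean_variance",
    "custom",
)

CURVE_COLUMNS = ["param", "E", "tauF_ns", "Gamma", "m1_ns", "m2_ns2"]


@dataclass
class FretState:
    """One conformational state of the labeled molecule.

    Specified either by its FRET efficiency ``E`` or by the mean-position
    inter-dye distance ``R_mp`` (Å); exactly one must be given.  States
    may additionally carry a distance-distribution model (for flexibly
    linked dyes or polymers) or precomputed linker-averaged lifetime
    moments — see :mod:`fretlines.distances`.
    """

    label: str = ""
    E: float | None = None
    R_mp: float | None = None
    distance_model: object | None = None  # distances.DistanceDistribution
    linker_moments: MomentPair | None = None

    def __post_init__(self) -> None:
        if (self.E is None) == (self.R_mp is None):
            raise ValueError("exactly one of E or R_mp must be specified")
        if self.E is not None and not (0.0 <= self.E <= 1.0):
            raise ValueError(f"E must lie in [0, 1], got {self.E}")
        if self.R_mp is not None and self.R_mp < 0:
            raise ValueError(f"R_mp must be non-negative, got {self.R_mp}")

    def efficiency(self, ctx: FretContext) -> float:
        if self.E is not None:
            return self.E
        return 1.0 / (1.0 + (self.R_mp / ctx.R0) ** 6)

    def lifetime(self, ctx: FretContext) -> float:
        """Fixed-dye donor lifetime tau_DA = (1-E)·tauD0 in ns."""
        return (1.0 - self.efficiency(ctx)) * ctx.tauD0


@dataclass
class LineCurve:
    """Sampled FRET-line with all derived representations.

    ``samples`` is a DataFrame with columns (param, E, tauF_ns, Gamma,
    m1_ns, m2_ns2), ordered by the curve's natural parameter.  ``metadata``
    records the context and model parameters, including the lifetime
    ``tau_ref_ns`` used to normalize Gamma (the donor-only lifetime, or
    the intensity-weighted donor-only lifetime for donor mixtures).
    """

    kind: str
    param_name: str
    samples: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LINE_KINDS:
            raise ValueError(f"unknown line kind {self.kind!r}")
        missing = [c for c in CURVE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"samples missing columns {missing}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def tau_ref(self) -> float:
        return self.metadata["tau_ref_ns"]

    def consistency_residual(self) -> float:
        """Max |Gamma - (1-E)(1 - tauF/tau_ref)| over the samples."""
        s = self.samples
        expected = (1.0 - s["E"]) * (1.0 - s["tauF_ns"] / self.tau_ref)
        return float(np.max(np.abs(s["Gamma"] - expected)))


def build_curve(
    kind: str,
    param_name: str,
    param: np.ndarray,
    m1: np.ndarray,
    m2: np.ndarray,
    ctx: FretContext,
    E: np.ndarray | None = None,
    tau_ref: float | None = None,
    metadata: dict | None = None,
) -> LineCurve:
    """Assemble a LineCurve from moment arrays.

    ``E`` defaults to ``1 - m1/tauD0``; donor-mixture lines pass their
    proximity ratio explicitly.  ``tau_ref`` (default ``ctx.tauD0``)
    normalizes Gamma.
    """
    param = np.asarray(param, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    t = ctx.tauD0 if tau_ref is None else float(tau_ref)
    if E is None:
        E = 1.0 - m1 / ctx.tauD0
    E = np.asarray(E, dtype=float)
    tauF = np.where(m1 > TAU_EPS, m2 / np.where(m1 > TAU_EPS, m1, 1.0), 0.0)
    gamma = (1.0 - E) * (1.0 - tauF / t)
    df = pd.DataFrame(
        {
            "param": param,
            "E": E,
            "tauF_ns": tauF,
            "Gamma": gamma,
            "m1_ns": m1,
            "m2_ns2": m2,
        }
    )
    meta = {"R0_A": ctx.R0, "tauD0_ns": ctx.tauD0, "tau_ref_ns": t}
    if metadata:
        meta.update(metadata)
    return LineCurve(kind=kind, param_name=param_name, samples=df, metadata=meta)


# ---------------------------------------------------------------------------
# Static and two-state dynamic lines


def static_line_ideal(ctx: FretContext, n_points: int = 201) -> LineCurve:
    """Ideal static FRET-line: single-lifetime species, E = 1 - tauF/tauD0.

    Straight diagonal in (E, tau_F); the parabola Gamma = (1-E)E in the
    moment representation, with its maximum at (1/2, 1/4).
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    E = np.linspace(0.0, 1.0, n_points)
    tau = (1.0 - E) * ctx.tauD0
    return build_curve("static_ideal", "E", E, tau, tau**2, ctx)


def dynamic_line_two_state(
    s1: FretState, s2: FretState, ctx: FretContext, n_points: int = 201
) -> LineCurve:
    """Dynamic FRET-line for two fixed-dye states in kinetic exchange.

    Parameterized by the occupancy fraction ``x1`` of state 1: moments mix
    linearly, so E = 1 - [x1·tau1 + (1-x1)·tau2]/tauD0 while
    tau_F = m2/m1 is hyperbolic, tracing the curved line
    E = 1 - (1/tauD0)·tau1·tau2/(tau1 + tau2 - tauF).  Straight in the
    Gamma representation: Gamma = (1 - E1 - E2)·E + E1·E2.
    """
    if s1.distance_model is not None or s2.distance_model is not None:
        raise ValueError(
            "dynamic_line_two_state is the fixed-dye case; use "
            "distances.dynamic_line_with_linkers for distance models"
        )
    tau1, tau2 = s1.lifetime(ctx), s2.lifetime(ctx)
    if abs(tau1 - tau2) < 1e-12:
        warnings.warn("identical state lifetimes: dynamic line degenerates to a point")
    x1 = np.linspace(0.0, 1.0, n_points)
    m1 = x1 * tau1 + (1 - x1) * tau2
    m2 = x1 * tau1**2 + (1 - x1) * tau2**2
    meta = {
        "E1": s1.efficiency(ctx),
        "E2": s2.efficiency(ctx),
        "tau1_ns": tau1,
        "tau2_ns": tau2,
        "labels": (s1.label, s2.label),
    }
    return build_curve("dynamic", "x1", x1, m1, m2, ctx, metadata=meta)


def dynamic_shift(E1: float, E2: float) -> float:
    """Maximal orthogonal distance between dynamic and static FRET-lines.

    Measured in the normalized (tauF/tauD0, E) plane, where the static line
    is the anti-diagonal E = 1 - tauF/tauD0.  Closed form
    ``(1/sqrt(2)) * (sqrt(1-E1) - sqrt(1-E2))**2``; symmetric in the two
    limiting efficiencies and independent of every other parameter.  A
    model-free indicator of how detectable two-state exchange is; shifts
    above ~0.05 are typically resolvable, ~0.01 with careful calibration.
    """
    for E in (E1, E2):
        if not (0.0 <= E <= 1.0):
            raise ValueError(f"efficiencies must lie in [0, 1], got {E}")
    return (np.sqrt(1.0 - E1) - np.sqrt(1.0 - E2)) ** 2 / np.sqrt(2.0)


def dynamic_shift_numeric(E1: float, E2: float) -> float:
    """Brute-force dynamic shift: maximize the point-to-line distance.

    Walks the dynamic line in the normalized (tauF/tauD0, E) plane and
    maximizes the orthogonal distance to the static line numerically.
    Kept as an independent cross-check of :func:`dynamic_shift`.
    """
    t1, t2 = 1.0 - E1, 1.0 - E2  # tau/tauD0 of the pure states

    def neg_distance(x1: float) -> float:
        m1 = x1 * t1 + (1 - x1) * t2
        m2 = x1 * t1**2 + (1 - x1) * t2**2
        E = 1.0 - m1
        tauF = m2 / m1 if m1 > TAU_EPS else 0.0
        # distance from (tauF, E) to the line E + tauF = 1
        return -abs(E + tauF - 1.0) / np.sqrt(2.0)

    res = minimize_scalar(neg_distance, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    return -res.fun


# ---------------------------------------------------------------------------
# Generic engine


@dataclass
class ContinuousLifetimeDistribution:
    """A continuous lifetime density on [lo, hi] ns for the generic engine."""

    pdf: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]

    def moments(self) -> MomentPair:
        lo, hi = self.support
        norm = quad(self.pdf, lo, hi, limit=200)[0]
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"lifetime density not normalized: integral={norm!r}")
        m1 = quad(lambda t: t * self.pdf(t), lo, hi, limit=200)[0]
        m2 = quad(lambda t: t**2 * self.pdf(t), lo, hi, limit=200)[0]
        return MomentPair(m1, m2)


def line_from_lifetime_distribution(
    family: Callable[[float], LifetimeMixture | ContinuousLifetimeDistribution],
    lam_grid: Sequence[float],
    ctx: FretContext,
    kind: str = "custom",
    param_name: str = "lambda",
    tau_ref: float | None = None,
    metadata: dict | None = None,
) -> LineCurve:
    """Generic FRET-line engine over a parameterized lifetime distribution.

    ``family(lam)`` must return either a discrete :class:`LifetimeMixture`
    or a :class:`ContinuousLifetimeDistribution`.  Per grid point the first
    two moments are evaluated and mapped to (E, tau_F, Gamma).  Every
    specialized generator in this package is equivalent to this engine for
    the corresponding family (a tested invariant).
    """
    lam = np.asarray(lam_grid, dtype=float)
    m1 = np.empty_like(lam)
    m2 = np.empty_like(lam)
    for i, l in enumerate(lam):
        dist = family(l)
        if isinstance(dist, LifetimeMixture):
            mom = mixture_moments(dist)
        else:
            mom = dist.moments()
        m1[i], m2[i] = mom.m1, mom.m2
    return build_curve(kind, param_name, lam, m1, m2, ctx, tau_ref=tau_ref,
                       metadata=metadata)


# ---------------------------------------------------------------------------
# Three-state systems


def _state_gamma_vertex(s: FretState, ctx: FretContext) -> np.ndarray:
    """(E, Gamma) coordinates of a pure fixed-dye state."""
    E = s.efficiency(ctx)
    return np.array([E, (1.0 - E) * E])


def limiting_lines_three_state(
    states: Sequence[FretState], ctx: FretContext, n_points: int = 201
) -> dict:
    """Limiting FRET-lines of a three-state kinetic network.

    Three-state mixing spans an area (two free fractions), bounded by the
    three pairwise binary dynamic lines.  The three "special" lines vary
    one fraction ``x_i`` while the other two stay equal,
    ``x_j = x_k = (1 - x_i)/2``; they intersect at the equal mixture
    x = (1/3, 1/3, 1/3).  Returns ``{"pairwise": [...], "special": [...]}``.
    """
    if len(states) != 3:
        raise ValueError("exactly three states required")
    Es = [s.efficiency(ctx) for s in states]
    if len({round(E, 12) for E in Es}) < 3:
        warnings.warn("duplicate state efficiencies: degenerate three-state system")
    taus = np.array([s.lifetime(ctx) for s in states])
    pairwise = [
        dynamic_line_two_state(states[i], states[j], ctx, n_points)
        for i, j in ((0, 1), (1, 2), (0, 2))
    ]
    special = []
    for i in range(3):
        xi = np.linspace(0.0, 1.0, n_points)
        frac = np.zeros((n_points, 3))
        frac[:, i] = xi
        for j in range(3):
            if j != i:
                frac[:, j] = (1.0 - xi) / 2.0
        m1 = frac @ taus
        m2 = frac @ taus**2
        special.append(
            build_curve(
                "dynamic", f"x{i + 1}", xi, m1, m2, ctx,
                metadata={"varied_state": states[i].label or f"state{i + 1}",
                          "constraint": "other two fractions equal"},
            )
        )
    return {"pairwise": pairwise, "special": special}


def fractions_from_position(
    point: tuple[float, float], states: Sequence[FretState], ctx: FretContext
) -> tuple[float, float, float]:
    """Species fractions of a three-state mixture from its (E, Gamma) position.

    Implements the graphical segment-ratio construction: the line from
    vertex ``i`` through the mixed population crosses the opposite binary
    exchange line at a point Q; the fraction is the ratio of the segment
    from Q to the population over the full segment from Q to the vertex.
    Equivalent to barycentric coordinates in the Gamma plane, where mixing
    is linear.  Points outside the triangle raise, reporting the signed
    coordinates so callers can distinguish noise from model violation.
    """
    if len(states) != 3:
        raise ValueError("exactly three states required")
    P = np.asarray(point, dtype=float)
    V = [_state_gamma_vertex(s, ctx) for s in states]
    T = np.column_stack([V[0] - V[2], V[1] - V[2]])
    det = np.linalg.det(T)
    if abs(det) < 1e-14:
        raise ValueError("state vertices are collinear: fractions are not identifiable")
    lam = np.linalg.solve(T, P - V[2])
    signed = np.array([lam[0], lam[1], 1.0 - lam[0] - lam[1]])
    if np.any(signed < -1e-9):
        raise ValueError(
            "point outside the three-state triangle; signed barycentric "
            f"coordinates: {tuple(float(s) for s in signed)}"
        )
    # Segment-ratio (graphical) construction, expressed through the
    # intersection point on the opposite edge.
    x = np.empty(3)
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        # Q = intersection of line (V_i, P) with edge (V_j, V_k)
        denom = 1.0 - signed[i]
        if denom <= 1e-12:
            x[i] = 1.0
            continue
        Q = (signed[j] * V[j] + signed[k] * V[k]) / denom
        a = np.linalg.norm(P - Q)       # population -> edge point
        b = np.linalg.norm(V[i] - P)    # vertex -> population
        x[i] = a / (a + b)
    x = np.clip(x, 0.0, 1.0)
    return float(x[0]), float(x[1]), float(x[2])


def mean_variance_dynamic_line(
    s1: FretState, s2: FretState, ctx: FretContext, n_points: int = 201
) -> LineCurve:
    """Two-state dynamic line in the mean-variance representation.

    Var(tau) = (m1 - tau1)(tau2 - m1) over m1 in [tau1, tau2]: a downward
    parabola with zero variance at the pure states and maximum
    ((tau2 - tau1)/2)² at the midpoint.  The ``samples`` carry the usual
    columns; ``Var_tau_ns2`` and ``Var_E`` are added for this representation.
    """
    curve = dynamic_line_two_state(s1, s2, ctx, n_points)
    s = curve.samples
    var_tau = s["m2_ns2"] - s["m1_ns"] ** 2
    s["Var_tau_ns2"] = var_tau
    s["Var_E"] = var_tau / ctx.tauD0**2
    curve.kind = "mean_variance"
    return curve
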