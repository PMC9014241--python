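"""Förster relations and lifetime-distribution moments.

Everything in this package reduces to two observables of a single-molecule
burst: the intensity-based FRET efficiency ``E`` and the intensity-weighted
average donor lifetime ``tau_F``.  Both are determined by the first two
moments of the distribution of donor lifetimes sampled during the burst:

* ``E = 1 - m1 / tau_D0``  (the donor intensity is proportional to the
  species-averaged lifetime ``m1``),
* ``tau_F = m2 / m1``  (the mean TCSPC delay time weights each species by
  its photon yield, i.e. by its lifetime).

This module houses those transforms, the Förster distance/efficiency
relations, and the moment difference ``Gamma = (1 - E)(1 - tau_F/tau_D0)``
that linearizes kinetic mixing.  Units are fixed package-wide: lifetimes
and delay times in ns, distances in Å, rates in 1/ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FretContext",
    "LifetimeMixture",
    "MomentPair",
    "ObservablePair",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "lifetime_from_efficiency",
    "ret_rate",
    "mixture_moments",
    "intensity_weighted_lifetime",
    "observables_to_moments",
    "moments_to_observables",
    "lifetime_variance",
    "efficiency_variance",
    "moment_difference",
    "decay_from_lifetime_mixture",
]

#: Smallest lifetime (ns) treated as non-zero when dividing by tau_F.
TAU_EPS = 1e-12

#: Tolerance on species fractions summing to one.
FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class FretContext:
    """Dye-pair parameters shared by every FRET-line.

    Parameters
    ----------
    R0 : float
        Förster radius in Å (distance of 50% transfer efficiency).
        Treated as an input; its photophysical decomposition (spectral
        overlap, orientation factor) is outside the scope of this package.
    tauD0 : float
        Donor-only fluorescence lifetime in ns.
    kF_D, phiF_D, phiF_A : float, optional
        Donor radiative rate (1/ns) and donor/acceptor fluorescence
        quantum yields.  ``kF_D`` and ``phiF_D`` are informational; all
        formulas implemented here use ``tauD0`` and ratios of quantum
        yields only.  ``phiF_A``/``phiF_D`` enter the proximity-ratio
        observables for multi-state donors.
    """

    R0: float
    tauD0: float
    kF_D: float | None = None
    phiF_D: float | None = None
    phiF_A: float | None = None

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError(f"R0 must be positive, got {self.R0}")
        if not self.tauD0 > 0:
            raise ValueError(f"tauD0 must be positive, got {self.tauD0}")
        for name in ("phiF_D", "phiF_A"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class LifetimeMixture:
    """Discrete distribution of donor lifetimes (ns) with species fractions."""

    lifetimes: tuple[float, ...]
    fractions: tuple[float, ...]

    def __init__(self, lifetimes: Sequence[float], fractions: Sequence[float]):
        lifetimes = tuple(float(t) for t in lifetimes)
        fractions = tuple(float(x) for x in fractions)
        if len(lifetimes) != len(fractions):
            raise ValueError("lifetimes and fractions must have equal length")
        if any(t < 0 for t in lifetimes):
            raise ValueError("lifetimes must be non-negative")
        if any(x < 0 for x in fractions):
            raise ValueError("fractions must be non-negative")
        total = sum(fractions)
        # No silent renormalization: a fraction sum off by more than the
        # tolerance is a caller bug and must surface.
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValueError(
                f"fractions must sum to 1 within {FRACTION_TOL:g}, got {total!r}"
            )
        object.__setattr__(self, "lifetimes", lifetimes)
        object.__setattr__(self, "fractions", fractions)

    def __len__(self) -> int:
        return len(self.lifetimes)


@dataclass(frozen=True)
class MomentPair:
    """First (ns) and second (ns²) raw moments of a lifetime distribution."""

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if self.m1 < 0:
            raise ValueError(f"m1 must be non-negative, got {self.m1}")
        if self.m2 < self.m1**2 - 1e-9 * max(1.0, self.m1**2):
            raise ValueError(
                f"m2={self.m2} < m1^2={self.m1**2}: negative variance"
            )

    @property
    def variance(self) -> float:
        """Var(tau) = m2 - m1² in ns²."""
        return self.m2 - self.m1**2


@dataclass(frozen=True)
class ObservablePair:
    """The burst observables: FRET efficiency and intensity-weighted lifetime."""

    E: float
    tauF: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.E <= 1.0):
            raise ValueError(f"E must lie in [0, 1], got {self.E}")
        if self.tauF < 0:
            raise ValueError(f"tauF must be non-negative, got {self.tauF}")


# ---------------------------------------------------------------------------
# Förster relations


def efficiency_from_distance(R_DA, ctx: FretContext):
    """FRET efficiency at inter-dye distance ``R_DA`` (Å): 1/(1+(R/R0)^6)."""
    R = np.asarray(R_DA, dtype=float)
    if np.any(R < 0):
        raise ValueError("distance must be non-negative")
    out = 1.0 / (1.0 + (R / ctx.R0) ** 6)
    return out if out.ndim else float(out)


def distance_from_efficiency(E, ctx: FretContext):
    """Inter-dye distance (Å) at efficiency ``E``: R0 * ((1-E)/E)^(1/6)."""
    E = np.asarray(E, dtype=float)
    if np.any((E <= 0) | (E >= 1)):
        raise ValueError("E must lie strictly in (0, 1)")
    out = ctx.R0 * ((1.0 - E) / E) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


def lifetime_from_efficiency(E, ctx: FretContext):
    """FRET-quenched donor lifetime (ns): tau_DA = (1 - E) * tauD0."""
    E = np.asarray(E, dtype=float)
    if np.any((E < 0) | (E > 1)):
        raise ValueError("E must lie in [0, 1]")
    out = (1.0 - E) * ctx.tauD0
    return out if out.ndim else float(out)


def ret_rate(R_DA, ctx: FretContext):
    """Energy-transfer rate constant (1/ns): (1/tauD0) * (R0/R)^6."""
    R = np.asarray(R_DA, dtype=float)
    if np.any(R <= 0):
        raise ValueError("distance must be positive (rate diverges at R=0)")
    out = (ctx.R0 / R) ** 6 / ctx.tauD0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Moments and observables


def mixture_moments(mix: LifetimeMixture) -> MomentPair:
    """First and second moments of a discrete lifetime mixture."""
    taus = np.asarray(mix.lifetimes)
    x = np.asarray(mix.fractions)
    return MomentPair(float(x @ taus), float(x @ taus**2))


def intensity_weighted_lifetime(m: MomentPair) -> float:
    """tau_F = m2 / m1, the mean TCSPC delay time of the mixture.

    Exceeds the species mean ``m1`` whenever the lifetime distribution has
    non-zero variance — the mechanism behind the dynamic shift.
    """
    if m.m1 <= TAU_EPS:
        raise ValueError("m1 is zero: intensity-weighted lifetime undefined")
    return m.m2 / m.m1


def observables_to_moments(obs: ObservablePair, ctx: FretContext) -> MomentPair:
    """Invert the observable transforms: m1 = (1-E)·tauD0, m2 = tauF·m1."""
    m1 = (1.0 - obs.E) * ctx.tauD0
    return MomentPair(m1, obs.tauF * m1)


def moments_to_observables(m: MomentPair, ctx: FretContext) -> ObservablePair:
    """Map lifetime moments to the burst observables (E, tau_F)."""
    E = 1.0 - m.m1 / ctx.tauD0
    tauF = intensity_weighted_lifetime(m) if m.m1 > TAU_EPS else 0.0
    return ObservablePair(E, tauF)


def lifetime_variance(obs: ObservablePair, ctx: FretContext) -> float:
    """Var(tau_DA) in ns² from the observables: (1-E)(E-E_tau)·tauD0².

    ``E_tau = 1 - tauF/tauD0`` is the lifetime-based efficiency estimate.
    Identical to ``m2 - m1²`` of the implied moments.  Slightly negative
    values can arise from shot noise in measured observables; values below
    -1e-9·tauD0² indicate an unphysical input and raise.
    """
    E_tau = 1.0 - obs.tauF / ctx.tauD0
    var = (1.0 - obs.E) * (obs.E - E_tau) * ctx.tauD0**2
    if var < -1e-9 * ctx.tauD0**2:
        raise ValueError(
            f"negative lifetime variance {var:g} ns²: tauF < (1-E)·tauD0 "
            "is not realizable by any lifetime mixture"
        )
    return var


def efficiency_variance(obs: ObservablePair, ctx: FretContext) -> float:
    """Var(E) = Var(tau_DA)/tauD0², by linearity of E in tau."""
    return lifetime_variance(obs, ctx) / ctx.tauD0**2


def moment_difference(
    obs: ObservablePair, ctx: FretContext, tau_ref: float | None = None
) -> float:
    """Moment difference Gamma = (1-E)(1 - tauF/tau_ref) = m1/t - m2/t².

    ``tau_ref`` defaults to the donor-only lifetime; for multi-exponential
    donors the intensity-weighted donor-only lifetime is used instead (see
    :mod:`fretlines.donor`).  Gamma is quadratic in E for static species
    ((1-E)E, a parabola peaking at (1/2, 1/4)) and linear in E for kinetic
    mixing, which is what makes this representation useful.  Negative
    values are allowed (they occur for donor mixtures).
    """
    t = ctx.tauD0 if tau_ref is None else tau_ref
    return (1.0 - obs.E) * (1.0 - obs.tauF / t)


def decay_from_lifetime_mixture(mix: LifetimeMixture, t_grid) -> np.ndarray:
    """Normalized donor fluorescence decay sum_i x_i exp(-t/tau_i).

    Unit amplitude at t=0; the time integral equals the first moment m1.
    Zero-lifetime components contribute only at t=0.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be increasing")
    taus = np.asarray(mix.lifetimes)
    x = np.asarray(mix.fractions)
    out = np.zeros_like(t)
    for tau_i, x_i in zip(taus, x):
        if tau_i > 0:
            out += x_i * np.exp(-t / tau_i)
        else:
            out += x_i * (t == 0)
    return out
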