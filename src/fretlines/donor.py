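"""Multi-exponential donor decays and proximity-ratio FRET-lines.

Tethered donor dyes frequently show multi-exponential fluorescence in the
absence of the acceptor (photoinduced electron transfer, sticking, isomer
mixtures).  Under the homogeneous approximation the FRET rate does not
depend on the donor photophysical state, so the joint distribution of
donor-only lifetimes and FRET rates factorizes and a donor state ``j``
combined with a FRET state ``i`` has lifetime

    tau_ij = 1 / (1/tauD0_j + k_i).

Because the donor states have different quantum yields, no single
distance-related efficiency exists; intensity ratios instead yield the
proximity ratio ``E_PR = 1 - <tau_DA>_x / <tau'_D0>_x`` built on the
effective (yield-corrected) donor-only lifetime
``tau'_D0 = tau_DA + gamma' (tauD0 - tau_DA)`` with
``gamma' = Phi_A / Phi_D``.  Static FRET-lines in (E_PR, tau_F) become
curved; dynamic lines stay straight in the moment representation when
Gamma is normalized by the intensity-weighted donor-only lifetime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    FRACTION_TOL,
    FretContext,
    LifetimeMixture,
    MomentPair,
    mixture_moments,
    intensity_weighted_lifetime,
)
from .lines import FretState, LineCurve, build_curve

__all__ = [
    "DonorMixture",
    "FretRateSet",
    "joint_moments",
    "effective_donor_lifetime",
    "proximity_ratio",
    "static_line_fast_exchange",
    "static_line_slow_exchange",
    "dynamic_line_PR",
    "fret_rate_from_state",
]


@dataclass(frozen=True)
class DonorMixture:
    """Discrete donor photophysical states: lifetimes, fractions, yields."""

    lifetimes: tuple[float, ...]
    fractions: tuple[float, ...]
    quantum_yields: tuple[float, ...]

    def __init__(
        self,
        lifetimes: Sequence[float],
        fractions: Sequence[float],
        quantum_yields: Sequence[float],
    ):
        lifetimes = tuple(float(t) for t in lifetimes)
        fractions = tuple(float(x) for x in fractions)
        quantum_yields = tuple(float(q) for q in quantum_yields)
        if not (len(lifetimes) == len(fractions) == len(quantum_yields)):
            raise ValueError("lifetimes, fractions, quantum_yields need equal length")
        if any(t <= 0 for t in lifetimes):
            raise ValueError("donor lifetimes must be positive")
        if abs(sum(fractions) - 1.0) > FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
        if any(not (0 < q <= 1) for q in quantum_yields):
            raise ValueError("quantum yields must lie in (0, 1]")
        # With a shared radiative rate, Phi is proportional to tau; a
        # mismatch is physically unusual but not forbidden.
        ratios = [q / t for q, t in zip(quantum_yields, lifetimes)]
        if max(ratios) - min(ratios) > 1e-6 * max(ratios):
            warnings.warn(
                "quantum yields are not proportional to lifetimes: donor "
                "states imply different radiative rates"
            )
        object.__setattr__(self, "lifetimes", lifetimes)
        object.__setattr__(self, "fractions", fractions)
        object.__setattr__(self, "quantum_yields", quantum_yields)

    def __len__(self) -> int:
        return len(self.lifetimes)

    def donor_only_moments(self) -> MomentPair:
        return mixture_moments(LifetimeMixture(self.lifetimes, self.fractions))

    def intensity_weighted_lifetime(self) -> float:
        """tauD0_F of the donor-only mixture — the tau_F-axis intercept and
        the Gamma normalization for donor-mixture lines."""
        return intensity_weighted_lifetime(self.donor_only_moments())


@dataclass(frozen=True)
class FretRateSet:
    """Discrete FRET-rate states: rates (1/ns) with fractions."""

    rates: tuple[float, ...]
    fractions: tuple[float, ...]

    def __init__(self, rates: Sequence[float], fractions: Sequence[float]):
        rates = tuple(float(k) for k in rates)
        fractions = tuple(float(x) for x in fractions)
        if len(rates) != len(fractions):
            raise ValueError("rates and fractions must have equal length")
        if any(k < 0 for k in rates):
            raise ValueError("FRET rates must be non-negative")
        if abs(sum(fractions) - 1.0) > FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "fractions", fractions)


def _tau_grid(donor: DonorMixture, fret: FretRateSet) -> tuple[np.ndarray, np.ndarray]:
    """Lifetimes tau_ij and joint weights x_j*x_i over donor x FRET states."""
    tauD0 = np.asarray(donor.lifetimes)[:, None]
    k = np.asarray(fret.rates)[None, :]
    tau = 1.0 / (1.0 / tauD0 + k)
    w = np.asarray(donor.fractions)[:, None] * np.asarray(fret.fractions)[None, :]
    return tau, w


def joint_moments(donor: DonorMixture, fret: FretRateSet) -> MomentPair:
    """Lifetime moments over the factorized donor x FRET product space."""
    tau, w = _tau_grid(donor, fret)
    return MomentPair(float(np.sum(w * tau)), float(np.sum(w * tau**2)))


def effective_donor_lifetime(tauDA: float, tauD0: float, gamma_prime: float) -> float:
    """Yield-corrected donor-only lifetime tau'_D0 = tauDA + gamma'(tauD0 - tauDA).

    ``gamma_prime = Phi_A / Phi_D`` converts the donor-channel intensity
    scale to the acceptor's, so that the intensity ratio reproduces the
    proximity ratio.  gamma' = 1 recovers tauD0; gamma' -> 0 gives tauDA.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    return tauDA + gamma_prime * (tauD0 - tauDA)


def proximity_ratio(
    donor: DonorMixture, fret: FretRateSet, ctx: FretContext
) -> float:
    """Intensity-ratio observable E_PR = 1 - <tau_DA>_x / <tau'_D0>_x.

    Species averages run over all donor x FRET states; gamma' is evaluated
    per donor species from ``ctx.phiF_A`` and the species' quantum yield.
    Reduces to the ordinary efficiency for a single donor state with
    gamma' = 1.
    """
    if ctx.phiF_A is None:
        raise ValueError("ctx.phiF_A is required for the proximity ratio")
    tau, w = _tau_grid(donor, fret)
    gp = ctx.phiF_A / np.asarray(donor.quantum_yields)[:, None]
    tau_eff = tau + gp * (np.asarray(donor.lifetimes)[:, None] - tau)
    return float(1.0 - np.sum(w * tau) / np.sum(w * tau_eff))


def fret_rate_from_state(state: FretState, ctx: FretContext) -> float:
    """FRET rate (1/ns) of a conformational state.

    From the mean-position distance via the Förster relation when given,
    else from the state's efficiency using the reference donor lifetime:
    k = E / ((1-E) tauD0).
    """
    if state.R_mp is not None:
        return (ctx.R0 / state.R_mp) ** 6 / ctx.tauD0
    E = state.E
    if E >= 1.0:
        raise ValueError("E = 1 implies an infinite FRET rate")
    return E / ((1.0 - E) * ctx.tauD0)


def _k_sweep(donor: DonorMixture, n_points: int) -> np.ndarray:
    """Logarithmic FRET-rate grid covering E_PR from ~0 to ~1, plus k=0."""
    k0 = 1.0 / max(donor.lifetimes)
    grid = np.geomspace(1e-4 * k0, 1e4 * k0, n_points - 1)
    return np.concatenate([[0.0], grid])


def static_line_fast_exchange(
    donor: DonorMixture, ctx: FretContext, n_points: int = 201
) -> LineCurve:
    """Static FRET-line for fast donor-state exchange (full averaging).

    A single FRET rate is swept; at every point the lifetime moments and
    intensities average over all donor states.  The line intercepts the
    tau_F axis (k=0) at the intensity-weighted donor-only lifetime tauD0_F
    and is convex in (E_PR, tau_F).  Gamma is normalized by tauD0_F.
    """
    ks = _k_sweep(donor, n_points)
    tau_ref = donor.intensity_weighted_lifetime()
    m1 = np.empty_like(ks)
    m2 = np.empty_like(ks)
    epr = np.empty_like(ks)
    for i, k in enumerate(ks):
        fret = FretRateSet([k], [1.0])
        mom = joint_moments(donor, fret)
        m1[i], m2[i] = mom.m1, mom.m2
        epr[i] = proximity_ratio(donor, fret, ctx)
    meta = {
        "donor_lifetimes_ns": donor.lifetimes,
        "donor_fractions": donor.fractions,
        "donor_quantum_yields": donor.quantum_yields,
        "exchange": "fast",
        "gamma_normalization": "tauD0_F",
    }
    return build_curve("static_PR_fast", "k_RET", ks, m1, m2, ctx, E=epr,
                       tau_ref=tau_ref, metadata=meta)


def static_line_slow_exchange(
    donor: DonorMixture,
    species: int,
    ctx: FretContext,
    n_points: int = 201,
    tau_ref: float | None = None,
) -> LineCurve:
    """Per-species static FRET-line for slow donor-state exchange.

    Each molecule stays in donor state ``species`` for the whole burst, so
    the decay is single-exponential (tau_F = tau_DA), but the proximity
    ratio bends the line whenever gamma' = Phi_A/Phi_D differs from 1.
    Gamma is normalized by the donor mixture's tauD0_F (override with
    ``tau_ref``), which is why the long-lifetime species can reach
    negative moment differences.
    """
    if ctx.phiF_A is None:
        raise ValueError("ctx.phiF_A is required for the proximity ratio")
    tauD0_j = donor.lifetimes[species]
    gp = ctx.phiF_A / donor.quantum_yields[species]
    if tau_ref is None:
        tau_ref = donor.intensity_weighted_lifetime()
    ks = _k_sweep(donor, n_points)
    tau = 1.0 / (1.0 / tauD0_j + ks)
    tau_eff = tau + gp * (tauD0_j - tau)
    epr = 1.0 - tau / tau_eff
    meta = {
        "species": species,
        "tauD0_j_ns": tauD0_j,
        "gamma_prime": gp,
        "exchange": "slow",
        "gamma_normalization": "tauD0_F",
    }
    return build_curve("static_PR_slow", "k_RET", ks, tau, tau**2, ctx, E=epr,
                       tau_ref=tau_ref, metadata=meta)


def dynamic_line_PR(
    s1: FretState,
    s2: FretState,
    donor: DonorMixture,
    exchange: str,
    ctx: FretContext,
    n_points: int = 201,
    species: int | None = None,
) -> LineCurve:
    """Dynamic FRET-line between two conformations with a donor mixture.

    Moments mix linearly in the conformational fraction ``x1``; for
    ``exchange="fast"`` each endpoint averages over all donor states, for
    ``exchange="slow"`` a single donor ``species`` applies to the whole
    burst.  In both regimes the Gamma representation stays straight.
    """
    if exchange not in ("slow", "fast"):
        raise ValueError("exchange must be 'slow' or 'fast'")
    k1 = fret_rate_from_state(s1, ctx)
    k2 = fret_rate_from_state(s2, ctx)
    if exchange == "slow":
        if species is None:
            raise ValueError("slow exchange requires a donor species index")
        sub = DonorMixture(
            [donor.lifetimes[species]], [1.0], [donor.quantum_yields[species]]
        )
    else:
        sub = donor
    tau_ref = donor.intensity_weighted_lifetime()
    x1 = np.linspace(0.0, 1.0, n_points)
    m1 = np.empty_like(x1)
    m2 = np.empty_like(x1)
    epr = np.empty_like(x1)
    for i, x in enumerate(x1):
        fret = FretRateSet([k1, k2], [x, 1.0 - x])
        mom = joint_moments(sub, fret)
        m1[i], m2[i] = mom.m1, mom.m2
        epr[i] = proximity_ratio(sub, fret, ctx)
    meta = {
        "exchange": exchange,
        "species": species,
        "k1_per_ns": k1,
        "k2_per_ns": k2,
        "gamma_normalization": "tauD0_F",
    }
    return build_curve("dynamic_PR", "x1", x1, m1, m2, ctx, E=epr,
                       tau_ref=tau_ref, metadata=meta)
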