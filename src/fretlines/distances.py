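"""Inter-dye distance distributions and the FRET-lines they generate.

Flexible dye linkers (10–20 Å tethers) and disordered chains make the
inter-dye distance a distribution rather than a number.  Linker motion is
slow compared to the fluorescence lifetime but fast compared to the burst
duration, so each burst samples a stationary distance density p(R) whose
lifetime moments follow by the change of variables

    tau(R) = tauD0 / (1 + (R0/R)^6),
    m_nu   = ∫ tau(R)^nu p(R) dR .

Supported families:

* ``chi`` — distance between two isotropic 3-D Gaussian dye clouds
  separated by the mean-position distance R_mp, width
  sigma_DA = sqrt(sigma_D² + sigma_A²) (non-central chi with 3 degrees of
  freedom).  The physically preferred linker model.
* ``truncated_normal`` — Gaussian in R restricted to R >= 0; a common
  approximation that overweights small distances for broad widths.
* ``gaussian_chain`` — ideal-chain end-to-end distance (the central chi /
  Maxwell form), <R²> = 3 sigma².
* ``wlc`` — worm-like chain radial density in the Thirumalai–Ha mean-field
  interpolation, parameterized by contour length L and stiffness
  kappa = l_p / L; normalized numerically on [0, L).
* ``mixture`` — weighted combination of the above; moments combine
  linearly, never by re-quadrature of the summed density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.special import ndtr

from .core import (
    FRACTION_TOL,
    FretContext,
    MomentPair,
    ObservablePair,
    observables_to_moments,
)
from .lines import FretState, LineCurve, build_curve

__all__ = [
    "DistanceDistribution",
    "LinkerAveragedState",
    "chi_pdf",
    "truncated_normal_pdf",
    "gaussian_chain_pdf",
    "wlc_pdf",
    "lifetime_moments_from_distribution",
    "static_line_linker",
    "linker_averaged_state",
    "dynamic_line_with_linkers",
    "variance_decomposition",
    "polymer_lines",
    "order_disorder_line",
]

#: Floor on R (Å) inside tau(R) to avoid overflow of (R0/R)^6 at the origin;
#: every supported density is negligible there.
R_FLOOR = 1e-3

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * _SQRT2PI)


def chi_pdf(R, Rmp: float, sigma: float):
    """Non-central chi distance density (3 d.o.f.).

    p(R) = (R / Rmp) [N(R | Rmp, sigma) - N(R | -Rmp, sigma)] on R >= 0,
    exactly normalized.  The central limit Rmp -> 0 is the Gaussian-chain
    (Maxwell) density; the narrow limit sigma/Rmp -> 0 tends to a normal
    density centered at Rmp.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if Rmp < 0:
        raise ValueError("Rmp must be non-negative")
    R = np.asarray(R, dtype=float)
    out = np.zeros_like(R)
    pos = R >= 0
    r = R[pos]
    if Rmp == 0.0:
        out[pos] = gaussian_chain_pdf(r, sigma)
        return out if out.ndim else float(out)
    a = r * Rmp / sigma**2
    # sinh form is cancellation-free for small a; the direct difference of
    # normal densities is overflow-free for large a.
    small = a < 25.0
    res = np.empty_like(r)
    res[small] = (
        (r[small] / Rmp)
        * 2.0
        / (sigma * _SQRT2PI)
        * np.exp(-(r[small] ** 2 + Rmp**2) / (2.0 * sigma**2))
        * np.sinh(a[small])
    )
    big = ~small
    res[big] = (r[big] / Rmp) * (
        _normal_pdf(r[big], Rmp, sigma) - _normal_pdf(r[big], -Rmp, sigma)
    )
    out[pos] = res
    return out if out.ndim else float(out)


def truncated_normal_pdf(R, Rmp: float, sigma: float):
    """Normal density in R restricted to R >= 0 and renormalized."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    R = np.asarray(R, dtype=float)
    mass = ndtr(Rmp / sigma)  # P(X >= 0) for X ~ N(Rmp, sigma)
    out = np.where(R >= 0, _normal_pdf(R, Rmp, sigma) / mass, 0.0)
    return out if out.ndim else float(out)


def gaussian_chain_pdf(R, sigma: float):
    """Ideal-chain end-to-end distance density (central chi, 3 d.o.f.).

    p(R) = sqrt(2/pi) R²/sigma³ exp(-R²/(2 sigma²)); <R²> = 3 sigma².
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    R = np.asarray(R, dtype=float)
    out = np.where(
        R >= 0,
        np.sqrt(2.0 / np.pi) * R**2 / sigma**3 * np.exp(-(R**2) / (2.0 * sigma**2)),
        0.0,
    )
    return out if out.ndim else float(out)


def _wlc_unnormalized(x: np.ndarray, kappa: float) -> np.ndarray:
    """Mean-field WLC radial density in x = R/L, up to normalization.

    f(x) ∝ x² (1-x²)^(-9/2) exp(-3 / (4 kappa (1-x²))) on [0, 1).
    The essential singularity at x=1 is killed by the exponential for any
    finite stiffness; stiff chains concentrate near x=1, flexible chains
    reduce to the Gaussian-chain form with <R²> ≈ 2 kappa L².
    """
    u = 1.0 - x**2
    out = np.zeros_like(x)
    ok = (x >= 0) & (x < 1) & (u > 0)
    # compute in log space: the prefactor diverges while exp -> 0
    logf = (
        2.0 * np.log(np.maximum(x[ok], 1e-300))
        - 4.5 * np.log(u[ok])
        - 3.0 / (4.0 * kappa * u[ok])
    )
    out[ok] = np.exp(logf)
    return out


@lru_cache(maxsize=256)
def _wlc_norm(kappa: float) -> float:
    """Normalization of the reduced (x = R/L) WLC density; L-independent."""
    val, _ = quad(lambda x: _wlc_unnormalized(np.array([x]), kappa)[0], 0.0, 1.0,
                  limit=200)
    if not np.isfinite(val) or val <= 0:
        raise ValueError(f"WLC normalization failed for kappa={kappa}")
    return val


def wlc_pdf(R, L: float, kappa: float):
    """Worm-like-chain end-to-end distance density on [0, L).

    Thirumalai–Ha interpolation normalized numerically; zero for R >= L.
    ``kappa = l_p / L`` is the stiffness.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    R = np.asarray(R, dtype=float)
    norm = _wlc_norm(float(kappa))
    x = R / L
    out = _wlc_unnormalized(x, kappa) / (norm * L)
    return out if out.ndim else float(out)


@dataclass
class DistanceDistribution:
    """Probability density of the inter-dye distance on R >= 0.

    ``family`` is one of chi / truncated_normal / gaussian_chain / wlc /
    mixture; ``params`` holds the family parameters (Rmp and sigma in Å;
    L in Å and kappa for wlc).  Mixtures store components unexpanded with
    ``weights``.
    """

    family: str
    params: dict = field(default_factory=dict)
    components: tuple["DistanceDistribution", ...] = ()
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        fams = ("chi", "truncated_normal", "gaussian_chain", "wlc", "mixture")
        if self.family not in fams:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "mixture":
            if len(self.components) != len(self.weights) or not self.components:
                raise ValueError("mixture requires matching components and weights")
            if abs(sum(self.weights) - 1.0) > FRACTION_TOL:
                raise ValueError("mixture weights must sum to 1")
        elif self.family == "wlc":
            self.params.setdefault("kappa", None)
            if self.params.get("L") is None or self.params.get("kappa") is None:
                raise ValueError("wlc requires L and kappa")
        elif self.family == "gaussian_chain":
            if self.params.get("sigma") is None:
                raise ValueError("gaussian_chain requires sigma")
        else:
            if self.params.get("Rmp") is None or self.params.get("sigma") is None:
                raise ValueError(f"{self.family} requires Rmp and sigma")

    # -- constructors -------------------------------------------------
    @classmethod
    def chi(cls, Rmp: float, sigma: float) -> "DistanceDistribution":
        return cls("chi", {"Rmp": float(Rmp), "sigma": float(sigma)})

    @classmethod
    def truncated_normal(cls, Rmp: float, sigma: float) -> "DistanceDistribution":
        return cls("truncated_normal", {"Rmp": float(Rmp), "sigma": float(sigma)})

    @classmethod
    def gaussian_chain(cls, sigma: float) -> "DistanceDistribution":
        return cls("gaussian_chain", {"sigma": float(sigma)})

    @classmethod
    def wlc(cls, L: float, kappa: float) -> "DistanceDistribution":
        return cls("wlc", {"L": float(L), "kappa": float(kappa)})

    @classmethod
    def mixture(
        cls,
        components: Sequence["DistanceDistribution"],
        weights: Sequence[float],
    ) -> "DistanceDistribution":
        return cls("mixture", {}, tuple(components), tuple(float(w) for w in weights))

    # -- evaluation ---------------------------------------------------
    def pdf(self, R):
        if self.family == "chi":
            return chi_pdf(R, **self.params)
        if self.family == "truncated_normal":
            return truncated_normal_pdf(R, **self.params)
        if self.family == "gaussian_chain":
            return gaussian_chain_pdf(R, **self.params)
        if self.family == "wlc":
            return wlc_pdf(R, **self.params)
        R = np.asarray(R, dtype=float)
        out = np.zeros_like(R)
        for comp, w in zip(self.components, self.weights):
            out = out + w * np.asarray(comp.pdf(R))
        return out if out.ndim else float(out)

    def support(self) -> tuple[float, float]:
        """Integration range covering essentially all probability mass."""
        if self.family in ("chi", "truncated_normal"):
            Rmp, sigma = self.params["Rmp"], self.params["sigma"]
            return (max(0.0, Rmp - 10.0 * sigma), Rmp + 10.0 * sigma)
        if self.family == "gaussian_chain":
            return (0.0, 12.0 * self.params["sigma"])
        if self.family == "wlc":
            return (0.0, self.params["L"])
        los, his = zip(*(c.support() for c in self.components))
        return (min(los), max(his))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw distances; used by Monte-Carlo cross-checks."""
        if self.family == "chi":
            Rmp, sigma = self.params["Rmp"], self.params["sigma"]
            vec = rng.normal(0.0, sigma, size=(n, 3))
            vec[:, 0] += Rmp
            return np.linalg.norm(vec, axis=1)
        if self.family == "gaussian_chain":
            sigma = self.params["sigma"]
            return np.linalg.norm(rng.normal(0.0, sigma, size=(n, 3)), axis=1)
        if self.family == "truncated_normal":
            Rmp, sigma = self.params["Rmp"], self.params["sigma"]
            out = np.empty(0)
            while out.size < n:
                draw = rng.normal(Rmp, sigma, size=2 * n)
                out = np.concatenate([out, draw[draw >= 0]])
            return out[:n]
        if self.family == "mixture":
            counts = rng.multinomial(n, self.weights)
            parts = [c.sample(k, rng) for c, k in zip(self.components, counts) if k]
            return rng.permutation(np.concatenate(parts))
        # wlc: rejection sampling against a uniform envelope on [0, L)
        L, kappa = self.params["L"], self.params["kappa"]
        xg = np.linspace(0.0, 1.0 - 1e-9, 4001)
        fmax = float(np.max(_wlc_unnormalized(xg, kappa)))
        out = np.empty(0)
        while out.size < n:
            x = rng.uniform(0.0, 1.0, size=4 * n)
            y = rng.uniform(0.0, fmax, size=4 * n)
            acc = y < _wlc_unnormalized(x, kappa)
            out = np.concatenate([out, x[acc] * L])
        return out[:n]


@dataclass
class LinkerAveragedState:
    """A conformational state summarized by its linker-averaged moments."""

    label: str
    moments: MomentPair
    source: str = ""


def fret_lifetime_of_distance(R, ctx: FretContext):
    """tau(R) = tauD0 / (1 + (R0/R)^6), with a floor at R = 1e-3 Å."""
    R = np.maximum(np.asarray(R, dtype=float), R_FLOOR)
    out = ctx.tauD0 / (1.0 + (ctx.R0 / R) ** 6)
    return out if out.ndim else float(out)


def lifetime_moments_from_distribution(
    dist: DistanceDistribution, ctx: FretContext
) -> MomentPair:
    """Quadrature lifetime moments m_nu = ∫ tau(R)^nu p(R) dR.

    Mixtures combine per-component moments linearly.  Quadrature failure
    (non-convergence) raises with diagnostics rather than returning a
    silently wrong value.
    """
    if dist.family == "mixture":
        m1 = m2 = 0.0
        for comp, w in zip(dist.components, dist.weights):
            mom = lifetime_moments_from_distribution(comp, ctx)
            m1 += w * mom.m1
            m2 += w * mom.m2
        return MomentPair(m1, m2)
    lo, hi = dist.support()
    out = []
    for nu in (1, 2):
        def integrand(R, nu=nu):
            return fret_lifetime_of_distance(R, ctx) ** nu * dist.pdf(R)

        val, err = quad(integrand, lo, hi, limit=400, epsrel=1e-9, epsabs=1e-13)
        if not np.isfinite(val) or (val > 0 and err > 1e-5 * val + 1e-10):
            raise ValueError(
                f"lifetime-moment quadrature did not converge for {dist.family} "
                f"(nu={nu}, value={val!r}, abs err={err!r})"
            )
        out.append(val)
    return MomentPair(out[0], out[1])


# ---------------------------------------------------------------------------
# FRET-lines


def static_line_linker(
    family: str,
    sigma: float,
    ctx: FretContext,
    Rmp_grid: Sequence[float] | None = None,
) -> LineCurve:
    """Linker-corrected static FRET-line: sweep the mean-position distance.

    For sigma > 0 every point is right-shifted (larger tau_F at equal E)
    from the ideal static line, increasingly so for broader linkers;
    sigma = 0 reproduces the ideal line.  ``family`` selects chi (default
    physical model) or truncated_normal.  The field-standard default width
    is ~6 Å, calibrated on rigid DNA rulers; always user-set here.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if Rmp_grid is None:
        Rmp_grid = np.linspace(0.2 * ctx.R0, 2.5 * ctx.R0, 201)
    Rmp_grid = np.asarray(Rmp_grid, dtype=float)
    if sigma == 0.0:
        tau = fret_lifetime_of_distance(Rmp_grid, ctx)
        return build_curve(
            "static_linker", "Rmp", Rmp_grid, tau, tau**2, ctx,
            metadata={"family": family, "sigma_A": 0.0},
        )
    maker = {
        "chi": DistanceDistribution.chi,
        "truncated_normal": DistanceDistribution.truncated_normal,
    }
    if family not in maker:
        raise ValueError("family must be 'chi' or 'truncated_normal'")
    m1 = np.empty_like(Rmp_grid)
    m2 = np.empty_like(Rmp_grid)
    for i, Rmp in enumerate(Rmp_grid):
        mom = lifetime_moments_from_distribution(maker[family](Rmp, sigma), ctx)
        m1[i], m2[i] = mom.m1, mom.m2
    return build_curve(
        "static_linker", "Rmp", Rmp_grid, m1, m2, ctx,
        metadata={"family": family, "sigma_A": sigma},
    )


def linker_averaged_state(
    state: FretState,
    ctx: FretContext,
    observed: ObservablePair | None = None,
) -> LinkerAveragedState:
    """Linker-averaged lifetime moments of one conformational state.

    Sources, in order of precedence: an explicit pair of observed (E,
    tau_F) values of the pure state (the model-free route), the state's
    distance-distribution model (quadrature), precomputed moments, or a
    fixed dye position (moments (tau, tau²)).
    """
    if observed is not None:
        return LinkerAveragedState(
            state.label, observables_to_moments(observed, ctx), source="observables"
        )
    if state.distance_model is not None:
        mom = lifetime_moments_from_distribution(state.distance_model, ctx)
        return LinkerAveragedState(state.label, mom, source="distance_model")
    if state.linker_moments is not None:
        return LinkerAveragedState(state.label, state.linker_moments, source="moments")
    tau = state.lifetime(ctx)
    return LinkerAveragedState(state.label, MomentPair(tau, tau**2), source="fixed_dye")


def dynamic_line_with_linkers(
    s1: LinkerAveragedState,
    s2: LinkerAveragedState,
    ctx: FretContext,
    n_points: int = 201,
) -> LineCurve:
    """Two-state dynamic line with linker-broadened endpoints.

    Because linker motion is fast against conformational exchange, the
    mixture moments are the linear combination of the linker-averaged
    per-state moments; the Gamma representation therefore stays straight,
    connecting the linker-shifted pure-state coordinates.
    """
    x1 = np.linspace(0.0, 1.0, n_points)
    m1 = x1 * s1.moments.m1 + (1 - x1) * s2.moments.m1
    m2 = x1 * s1.moments.m2 + (1 - x1) * s2.moments.m2
    meta = {"labels": (s1.label, s2.label),
            "endpoint_moments": ((s1.moments.m1, s1.moments.m2),
                                 (s2.moments.m1, s2.moments.m2))}
    return build_curve("dynamic", "x1", x1, m1, m2, ctx, metadata=meta)


def variance_decomposition(
    states: Sequence[LinkerAveragedState], fractions: Sequence[float]
) -> tuple[float, float, float]:
    """Split Var(tau) into conformational and linker contributions.

    Returns ``(total, conformational, linker)`` in ns²: the variance of
    the combined lifetime distribution equals the between-state variance
    of the linker-averaged mean lifetimes plus the fraction-weighted mean
    of the within-state linker variances.  The decomposition is exact.
    """
    x = np.asarray(fractions, dtype=float)
    if abs(x.sum() - 1.0) > FRACTION_TOL:
        raise ValueError("fractions must sum to 1")
    m1 = np.array([s.moments.m1 for s in states])
    m2 = np.array([s.moments.m2 for s in states])
    tot_m1 = float(x @ m1)
    tot_m2 = float(x @ m2)
    total = tot_m2 - tot_m1**2
    conformational = float(x @ m1**2) - tot_m1**2
    linker = float(x @ (m2 - m1**2))
    return total, conformational, linker


def polymer_lines(
    ctx: FretContext,
    mode: str,
    grid: Sequence[float],
    L: float | None = None,
    kappa: float | None = None,
) -> LineCurve:
    """FRET-lines of flexible polymers.

    * ``gc_sweep_sigma`` — the single Gaussian-chain line, swept over the
      width sigma (Å).  One line describes every ideal chain.
    * ``wlc_sweep_kappa_fixed_L`` — worm-like chain at contour length
      ``L`` (Å), swept over stiffness kappa.
    * ``wlc_sweep_L_fixed_kappa`` — swept over contour length at fixed
      ``kappa``.

    Combinations of (kappa, L) can share a FRET efficiency yet differ in
    tau_F, which is what makes the two-observable plane resolve them.
    """
    grid = np.asarray(grid, dtype=float)
    m1 = np.empty_like(grid)
    m2 = np.empty_like(grid)
    if mode == "gc_sweep_sigma":
        for i, sig in enumerate(grid):
            mom = lifetime_moments_from_distribution(
                DistanceDistribution.gaussian_chain(sig), ctx
            )
            m1[i], m2[i] = mom.m1, mom.m2
        return build_curve("gaussian_chain", "sigma", grid, m1, m2, ctx)
    if mode == "wlc_sweep_kappa_fixed_L":
        if L is None:
            raise ValueError("L is required for wlc_sweep_kappa_fixed_L")
        for i, k in enumerate(grid):
            mom = lifetime_moments_from_distribution(
                DistanceDistribution.wlc(L, k), ctx
            )
            m1[i], m2[i] = mom.m1, mom.m2
        return build_curve("wlc", "kappa", grid, m1, m2, ctx, metadata={"L_A": L})
    if mode == "wlc_sweep_L_fixed_kappa":
        if kappa is None:
            raise ValueError("kappa is required for wlc_sweep_L_fixed_kappa")
        for i, Li in enumerate(grid):
            mom = lifetime_moments_from_distribution(
                DistanceDistribution.wlc(Li, kappa), ctx
            )
            m1[i], m2[i] = mom.m1, mom.m2
        return build_curve("wlc", "L", grid, m1, m2, ctx, metadata={"kappa": kappa})
    raise ValueError(f"unknown polymer line mode {mode!r}")


def order_disorder_line(
    folded: DistanceDistribution,
    unfolded: DistanceDistribution,
    ctx: FretContext,
    n_points: int = 201,
) -> LineCurve:
    """Folding FRET-line: mix a compact (folded) and a polymer (unfolded)
    distance distribution over the folded fraction x_f.

    Endpoints are the linker-averaged folded point and the polymer point;
    the moments mix linearly in x_f, so the line is straight in the Gamma
    representation even though both endpoints are themselves broadened.
    """
    mf = lifetime_moments_from_distribution(folded, ctx)
    mu = lifetime_moments_from_distribution(unfolded, ctx)
    xf = np.linspace(0.0, 1.0, n_points)
    m1 = xf * mf.m1 + (1 - xf) * mu.m1
    m2 = xf * mf.m2 + (1 - xf) * mu.m2
    meta = {
        "folded": {"family": folded.family, **folded.params},
        "unfolded": {"family": unfolded.family, **unfolded.params},
    }
    return build_curve("order_disorder", "xf", xf, m1, m2, ctx, metadata=meta)
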