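"""Per-burst observables and dynamics indicators.

From each burst's photon record this module estimates the intensity FRET
efficiency (acceptor fraction), the intensity-weighted donor lifetime (the
mean TCSPC delay, which converges to m2/m1 of the burst's lifetime
mixture, not to the species mean), the burst-variance-analysis (BVA)
standard deviation with its binomial shot-noise reference, and the
variance of the efficiency distribution inferred from the observables
alone — the lifetime-based dynamics indicator that, unlike BVA, does not
degrade for fast exchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FretContext, ObservablePair, moment_difference
from .simulate import BurstTable

logger = logging.getLogger(__name__)

__all__ = [
    "burst_efficiency",
    "burst_mean_delay",
    "bva_sigma",
    "bva_shot_noise",
    "dynamic_variance_estimate",
    "bva_shot_noise_subtraction",
    "analyze_bursts",
    "histogram2d",
]


def burst_efficiency(n_acceptor: int, n_donor: int) -> float:
    """Intensity FRET efficiency n_A / (n_A + n_D) (ideal, corrected counts)."""
    total = n_acceptor + n_donor
    if total <= 0:
        raise ValueError("burst has no photons: efficiency undefined")
    return n_acceptor / total


def burst_mean_delay(donor_delays) -> float:
    """Mean donor delay time (ns): the per-burst tau_F estimate.

    The arithmetic mean of exponential delay times is the maximum-
    likelihood lifetime in the ideal (delta-IRF, zero background) regime
    and converges to m2/m1 of the burst's lifetime mixture.
    """
    d = np.asarray(donor_delays, dtype=float)
    if d.size == 0:
        raise ValueError("no donor photons: mean delay undefined")
    return float(d.mean())


def bva_sigma(photon_colors, N: int, overlapping: bool = False) -> float:
    """BVA standard deviation of the FRET efficiency within a burst.

    ``photon_colors`` is the ordered sequence of channel flags (True/1 for
    acceptor).  The trace is cut into consecutive windows of N photons
    (non-overlapping by default, trailing partial window discarded); the
    per-window efficiencies E_i are compared against the burst efficiency
    E, returning sqrt(mean((E_i - E)^2)).
    """
    colors = np.asarray(photon_colors).astype(float)
    n = colors.size
    if N < 1:
        raise ValueError("window must be at least 1 photon")
    if n < N:
        raise ValueError(f"burst has {n} photons, fewer than the window N={N}")
    E_burst = colors.mean()
    if overlapping:
        csum = np.concatenate([[0.0], np.cumsum(colors)])
        Ei = (csum[N:] - csum[:-N]) / N
    else:
        M = n // N
        Ei = colors[: M * N].reshape(M, N).mean(axis=1)
    return float(np.sqrt(np.mean((Ei - E_burst) ** 2)))


def bva_shot_noise(E: float, N: int) -> float:
    """Binomial shot-noise limit sqrt(E(1-E)/N): the static BVA reference."""
    if N < 1:
        raise ValueError("window must be at least 1 photon")
    return float(np.sqrt(E * (1.0 - E) / N))


def dynamic_variance_estimate(obs: ObservablePair, ctx: FretContext) -> float:
    """Conformational variance of E from the observables: (1-E)(E-E_tau).

    E_tau = 1 - tauF/tauD0.  This is Var(tau)/tauD0² expressed through the
    observables; it contains no shot-noise term, so for two-state exchange
    its burst average traces the parabola (E - E1)(E2 - E).  Unlike the
    BVA estimate it does not decay for exchange faster than the
    inter-photon time.
    """
    E_tau = 1.0 - obs.tauF / ctx.tauD0
    return (1.0 - obs.E) * (obs.E - E_tau)


def bva_shot_noise_subtraction(sigmaE_bva: float, E: float, N: int) -> float:
    """Approximate conformational variance: sigma_BVA² - E(1-E)/N, floored at 0.

    Shot noise and dynamics are not strictly additive and windowed
    sampling averages over dynamics faster than N inter-photon times, so
    this subtraction underestimates the true conformational variance; it
    is provided as the standard quick correction.  Degenerate for N = 1
    (single-photon windows have E_i in {0, 1}).
    """
    if N == 1:
        logger.warning("BVA with N=1 is degenerate: windows carry no variance "
                       "information beyond shot noise")
    return max(sigmaE_bva**2 - E * (1.0 - E) / N, 0.0)


def analyze_bursts(
    table: BurstTable,
    ctx: FretContext,
    bva_window: int = 5,
    bva_overlapping: bool = False,
    tau_ref: float | None = None,
) -> pd.DataFrame:
    """Per-burst observables for every burst in a table.

    Columns: burst_id, n_photons, E_hat, tauF_hat (NaN when the burst has
    no donor photons — those bursts are excluded from lifetime-based
    columns with a logged count), sigmaE_bva (NaN below the window size),
    var_dyn, Gamma_hat, m1_hat, m2_hat.
    """
    rows = []
    n_no_donor = 0
    n_below_window = 0
    photons = table.photons
    grouped = dict(iter(photons.groupby("burst_id", sort=True)))
    for _, b in table.bursts.iterrows():
        bid = int(b["burst_id"])
        ph = grouped[bid]
        colors = (ph["channel"] == "A").to_numpy()
        n_a = int(colors.sum())
        n_d = int(colors.size - n_a)
        E = burst_efficiency(n_a, n_d)
        if n_d > 0:
            tauF = burst_mean_delay(ph.loc[ph["channel"] == "D", "delay_ns"])
            obs = ObservablePair(E, tauF)
            var_dyn = dynamic_variance_estimate(obs, ctx)
            gamma = moment_difference(obs, ctx, tau_ref=tau_ref)
            m1 = (1.0 - E) * ctx.tauD0
            m2 = tauF * m1
        else:
            n_no_donor += 1
            tauF = var_dyn = gamma = m1 = m2 = np.nan
        if colors.size >= bva_window:
            sig = bva_sigma(colors, bva_window, overlapping=bva_overlapping)
        else:
            n_below_window += 1
            sig = np.nan
        rows.append(
            {
                "burst_id": bid,
                "n_photons": colors.size,
                "n_donor": n_d,
                "n_acceptor": n_a,
                "E_hat": E,
                "tauF_hat": tauF,
                "sigmaE_bva": sig,
                "var_dyn": var_dyn,
                "Gamma_hat": gamma,
                "m1_hat": m1,
                "m2_hat": m2,
            }
        )
    if n_no_donor:
        logger.info("%d bursts without donor photons: lifetime observables NaN",
                    n_no_donor)
    if n_below_window:
        logger.warning("%d bursts below the BVA window of %d photons",
                       n_below_window, bva_window)
    return pd.DataFrame(rows)


def histogram2d(
    observables: pd.DataFrame,
    representation: str = "E_tauF",
    bins: int | tuple = 41,
    ctx: FretContext | None = None,
    ranges: tuple | None = None,
) -> dict:
    """2-D burst frequency histogram in one of the three representations.

    ``representation``: ``E_tauF`` (tauF_hat vs E_hat), ``moment``
    (E_hat vs Gamma_hat) or ``mean_variance`` (E_hat vs var_dyn).  Bursts
    with undefined coordinates (no donor photons) are dropped; the counts
    of the remaining bursts are conserved.  Returns a dict with ``counts``,
    bin ``x_edges``/``y_edges``, the axis names, and the marginals.
    """
    axes = {
        "E_tauF": ("tauF_hat", "E_hat"),
        "moment": ("E_hat", "Gamma_hat"),
        "mean_variance": ("E_hat", "var_dyn"),
    }
    if representation not in axes:
        raise ValueError(f"unknown representation {representation!r}")
    if len(observables) == 0:
        raise ValueError("no bursts to histogram")
    xcol, ycol = axes[representation]
    data = observables[[xcol, ycol]].dropna()
    counts, xe, ye = np.histogram2d(
        data[xcol], data[ycol], bins=bins, range=ranges
    )
    return {
        "counts": counts,
        "x_edges": xe,
        "y_edges": ye,
        "x_name": xcol,
        "y_name": ycol,
        "marginal_x": counts.sum(axis=1),
        "marginal_y": counts.sum(axis=0),
        "n_bursts": int(counts.sum()),
        "n_dropped": int(len(observables) - len(data)),
    }
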