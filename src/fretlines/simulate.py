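"""Photon-level simulation of confocal smFRET bursts.

The model is the idealized experiment the FRET-line theory describes: a
molecule switches between conformational states as a continuous-time
Markov chain (Gillespie dynamics), emits photons as a homogeneous Poisson
process at a fixed per-molecule count rate while in the confocal volume,
each photon is routed to the acceptor channel with probability equal to
the instantaneous state's FRET efficiency, and donor photons carry a TCSPC
delay time drawn from the state's exponential decay with mean tau_DA.

Deliberately not modeled: diffusion-path brightness variation, background,
IRF, and acceptor photophysics — the theory's ideal-experiment scope.
Acceptor delay times are not generated because every lifetime estimator in
scope uses donor photons only.  Burst durations default to an exponential
law with mean equal to the diffusion time (0.5 ms), truncated at ten times
the mean; a fixed-duration mode exists for clean oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .core import FretContext
from .lines import FretState

__all__ = [
    "KineticModel",
    "SimulationConfig",
    "BurstTable",
    "StatePath",
    "equilibrium_distribution",
    "simulate_state_trajectory",
    "simulate_burst",
    "simulate_experiment",
    "two_state_model",
]


@dataclass
class KineticModel:
    """Conformational states plus transition rates.

    ``rate_matrix[i, j]`` is the rate (1/ms) of the transition from state
    j to state i; the diagonal is defined internally as the negative
    column sums, so only off-diagonal entries are read.
    """

    states: Sequence[FretState]
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.states)
        if K.shape != (n, n):
            raise ValueError(f"rate matrix must be {n}x{n}, got {K.shape}")
        off = K[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        K = K.copy()
        np.fill_diagonal(K, 0.0)
        np.fill_diagonal(K, -K.sum(axis=0))
        self.rate_matrix = K

    @property
    def n_states(self) -> int:
        return len(self.states)

    def efficiencies(self, ctx: FretContext) -> np.ndarray:
        return np.array([s.efficiency(ctx) for s in self.states])

    def lifetimes(self, ctx: FretContext) -> np.ndarray:
        return np.array([s.lifetime(ctx) for s in self.states])


def two_state_model(E1: float, E2: float, k12: float, k21: float) -> KineticModel:
    """Convenience two-state model; rates in 1/ms, k12 leaves state 1."""
    K = np.array([[0.0, k21], [k12, 0.0]])
    return KineticModel([FretState("state1", E=E1), FretState("state2", E=E2)], K)


@dataclass
class SimulationConfig:
    """Simulation settings.

    ``count_rate`` in photons/ms (100 kHz = 100/ms, the typical confocal
    per-molecule rate); ``burst_mean_ms`` is the diffusion time setting
    the mean burst duration.  The seed is mandatory: every burst gets its
    own child RNG stream, so burst k is reproducible regardless of
    n_bursts.
    """

    count_rate: float = 100.0
    burst_duration_model: str = "exponential"
    burst_mean_ms: float = 0.5
    n_bursts: int = 1000
    min_photons: int = 50
    seed: int = 0
    max_duration_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.count_rate <= 0 or self.burst_mean_ms <= 0:
            raise ValueError("count rate and burst duration must be positive")
        if self.burst_duration_model not in ("fixed", "exponential"):
            raise ValueError("burst_duration_model must be 'fixed' or 'exponential'")
        if self.n_bursts < 1 or self.min_photons < 1:
            raise ValueError("n_bursts and min_photons must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class StatePath:
    """Piecewise-constant state trajectory on [0, duration] (ms).

    ``switch_times`` are the entry times of each segment (first is 0);
    ``states`` the corresponding state indices.
    """

    switch_times: np.ndarray
    states: np.ndarray
    duration: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.switch_times, t, side="right") - 1
        return self.states[idx]

    def occupancy(self, n_states: int) -> np.ndarray:
        """Time fraction spent in each state."""
        edges = np.concatenate([self.switch_times, [self.duration]])
        dwell = np.diff(edges)
        occ = np.zeros(n_states)
        np.add.at(occ, self.states, dwell)
        return occ / self.duration


@dataclass
class BurstTable:
    """Per-burst photon summaries plus the raw photon records.

    ``bursts`` columns: burst_id, n_donor, n_acceptor, duration_ms, and
    occ_<i> true state occupancies.  ``photons`` columns: burst_id,
    channel ('D'/'A'), delay_ns (NaN for acceptor photons), macrotime_ms.
    """

    bursts: pd.DataFrame
    photons: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def donor_delays(self, burst_id: int) -> np.ndarray:
        p = self.photons
        sel = (p["burst_id"] == burst_id) & (p["channel"] == "D")
        return p.loc[sel, "delay_ns"].to_numpy()

    def __len__(self) -> int:
        return len(self.bursts)


def equilibrium_distribution(model: KineticModel) -> np.ndarray:
    """Stationary distribution pi with K pi = 0, sum(pi) = 1."""
    if model.n_states == 1:
        return np.array([1.0])
    ns = null_space(model.rate_matrix)
    if ns.shape[1] != 1:
        raise ValueError(
            "rate matrix is reducible: stationary distribution is not unique"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValueError("rate matrix has no non-negative stationary distribution")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def simulate_state_trajectory(
    model: KineticModel,
    duration: float,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> StatePath:
    """Gillespie path: exponential dwells, jump probabilities by rate.

    The initial state is drawn from the equilibrium distribution unless
    given explicitly.
    """
    K = model.rate_matrix
    n = model.n_states
    exit_rates = -np.diag(K)
    if initial_state is None:
        pi = equilibrium_distribution(model)
        state = int(rng.choice(n, p=pi))
    else:
        state = int(initial_state)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        r = exit_rates[state]
        if r <= 0.0:
            break
        t += rng.exponential(1.0 / r)
        if t >= duration:
            break
        probs = K[:, state].copy()
        probs[state] = 0.0
        probs = np.clip(probs, 0.0, None) / r
        state = int(rng.choice(n, p=probs))
        times.append(t)
        states.append(state)
    return StatePath(np.array(times), np.array(states), duration)


def simulate_burst(
    path: StatePath,
    config: SimulationConfig,
    ctx: FretContext,
    rng: np.random.Generator,
    efficiencies: np.ndarray | None = None,
    lifetimes: np.ndarray | None = None,
    model: KineticModel | None = None,
) -> dict:
    """Photons of one burst given a state path.

    Returns a dict with macrotimes (ms), channels, donor delay times (ns)
    and per-photon state indices.  Photon arrivals are Poisson at the
    configured count rate; the color split is Bernoulli with the
    instantaneous state's efficiency; donor delays are exponential with
    the state's FRET-quenched lifetime.
    """
    if efficiencies is None or lifetimes is None:
        if model is None:
            raise ValueError("provide efficiencies+lifetimes or a model")
        efficiencies = model.efficiencies(ctx)
        lifetimes = model.lifetimes(ctx)
    n_photons = rng.poisson(config.count_rate * path.duration)
    t = np.sort(rng.uniform(0.0, path.duration, size=n_photons))
    states = path.state_at(t)
    E = efficiencies[states]
    is_acceptor = rng.random(n_photons) < E
    delays = np.full(n_photons, np.nan)
    donor = ~is_acceptor
    tau = lifetimes[states[donor]]
    delays[donor] = rng.exponential(np.where(tau > 0, tau, 1e-300))
    if np.any(tau == 0):
        delays[donor] = np.where(tau > 0, delays[donor], 0.0)
    return {
        "macrotime_ms": t,
        "is_acceptor": is_acceptor,
        "delay_ns": delays,
        "state": states,
    }


def simulate_experiment(
    model: KineticModel, config: SimulationConfig, ctx: FretContext
) -> BurstTable:
    """Simulate a burst experiment: n_bursts bursts passing the
    min_photons selection.

    One root seed spawns an independent child RNG stream per candidate
    burst, so any burst is bit-reproducible independently of how many
    bursts are requested.  The true state occupancies of every burst are
    recorded for oracle tests.
    """
    eff = model.efficiencies(ctx)
    taus = model.lifetimes(ctx)
    root = np.random.SeedSequence(config.seed)
    burst_rows = []
    photon_frames = []
    kept = 0
    generated = 0
    candidate = 0
    while kept < config.n_bursts:
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(candidate,))
        rng = np.random.default_rng(child)
        candidate += 1
        generated += 1
        if config.burst_duration_model == "fixed":
            duration = config.burst_mean_ms
        else:
            duration = rng.exponential(config.burst_mean_ms)
            duration = min(duration, config.max_duration_factor * config.burst_mean_ms)
        path = simulate_state_trajectory(model, duration, rng)
        ph = simulate_burst(path, config, ctx, rng, efficiencies=eff, lifetimes=taus)
        n = ph["macrotime_ms"].size
        if n < config.min_photons:
            continue
        occ = path.occupancy(model.n_states)
        n_acc = int(ph["is_acceptor"].sum())
        row = {
            "burst_id": kept,
            "n_donor": n - n_acc,
            "n_acceptor": n_acc,
            "duration_ms": duration,
        }
        for i, o in enumerate(occ):
            row[f"occ_{i}"] = o
        burst_rows.append(row)
        photon_frames.append(
            pd.DataFrame(
                {
                    "burst_id": kept,
                    "channel": np.where(ph["is_acceptor"], "A", "D"),
                    "delay_ns": ph["delay_ns"],
                    "macrotime_ms": ph["macrotime_ms"],
                }
            )
        )
        kept += 1
    bursts = pd.DataFrame(burst_rows)
    photons = pd.concat(photon_frames, ignore_index=True)
    meta = {
        "seed": config.seed,
        "count_rate_per_ms": config.count_rate,
        "burst_duration_model": config.burst_duration_model,
        "burst_mean_ms": config.burst_mean_ms,
        "min_photons": config.min_photons,
        "n_generated": generated,
        "n_kept": kept,
        "state_efficiencies": [float(e) for e in eff],
        "state_lifetimes_ns": [float(t) for t in taus],
        "tauD0_ns": ctx.tauD0,
        "R0_A": ctx.R0,
    }
    return BurstTable(bursts=bursts, photons=photons, metadata=meta)
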