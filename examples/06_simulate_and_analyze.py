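"""Simulate a two-state smFRET experiment and verify the dynamic line.

Photon-level simulation: Markov switching between E = 0.25 and E = 0.80 at
1/ms, 0.5 ms mean bursts, 100 photons/ms.  The per-burst estimators place
the population centroid on the two-state dynamic line, displaced from the
static line — the lifetime-based dynamics fingerprint.
"""

import numpy as np

import fretlines as fl

ctx = fl.FretContext(R0=50.0, tauD0=4.0)
model = fl.two_state_model(E1=0.25, E2=0.8, k12=1.0, k21=1.0)
config = fl.SimulationConfig(count_rate=100.0, burst_mean_ms=0.5,
                             n_bursts=1000, min_photons=50, seed=7)

table = fl.simulate_experiment(model, config, ctx)
obs = fl.analyze_bursts(table, ctx, bva_window=5)
print(f"{len(table)} bursts, {len(table.photons)} photons "
      f"({table.metadata['n_generated'] - len(table)} rejected below "
      f"{config.min_photons} photons)")

E, tauF = obs["E_hat"].mean(), obs["tauF_hat"].mean()
print(f"population centroid: E = {E:.3f}, tauF = {tauF:.2f} ns")
print(f"static line at that E would give tauF = {(1 - E) * 4:.2f} ns")

# centroid on the dynamic chord in moment space (m2 = (t1+t2) m1 - t1 t2)
t1, t2 = 3.0, 0.8
resid = obs["m2_hat"] - ((t1 + t2) * obs["m1_hat"] - t1 * t2)
se = resid.std() / np.sqrt(len(resid))
print(f"moment-space residual from the dynamic line: "
      f"{resid.mean():+.4f} ± {se:.4f} ns² (consistent with zero)")

bva_excess = (obs["sigmaE_bva"]
              - np.sqrt(obs["E_hat"] * (1 - obs["E_hat"]) / 5)).mean()
print(f"mean BVA sigma_E above shot noise: {bva_excess:+.4f} "
      "(positive: dynamics slower than the photon window)")
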