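# fretlines

Reference curves ("FRET-lines") for single-molecule FRET burst analysis,
plus a photon-level burst simulator and per-burst estimators to validate
them against synthetic data.

## The problem

In confocal single-molecule FRET (smFRET) with multiparameter detection,
every burst yields two observables for the donor dye:

* the intensity-based FRET efficiency **E** = F_A / (F_A + F_D), and
* the intensity-weighted average fluorescence lifetime **τ_F**, estimated
  as the mean TCSPC delay time of the donor photons.

Both are set by the first two moments of the distribution of donor
lifetimes sampled during the burst:

```
E = 1 − ⟨τ⟩/τ_D0          (donor intensity ∝ first moment ⟨τ⟩)
τ_F = ⟨τ²⟩/⟨τ⟩            (delay-time average ∝ second/first moment)
```

A molecule with a single inter-dye distance sits on the **static
FRET-line** E = 1 − τ_F/τ_D0.  Any heterogeneity — conformational
exchange, flexible dye linkers, chain disorder — makes ⟨τ²⟩ > ⟨τ⟩² and
displaces the population toward longer τ_F.  Parametric model curves in
the (E, τ_F) plane, the FRET-lines, turn that displacement into a
quantitative, model-selective readout.  The **moment difference**

```
Γ = (1 − E)(1 − τ_F/τ_D0) = ⟨τ⟩/τ_D0 − ⟨τ²⟩/τ_D0²
```

linearizes kinetic mixing: dynamic exchange between any set of states is a
straight line (or simplex) in the (E, Γ) plane, which enables graphical
recovery of species fractions.

The package is aimed at people analyzing (or simulating) burstwise smFRET
data who need reference lines for two- and multi-state exchange, donor
photophysics (multi-exponential donors, proximity ratio E_PR), dye-linker
broadening (non-central χ / truncated-normal distance models), polymer
models of disordered chains (Gaussian chain, worm-like chain), and
order–disorder transitions.

## Worked example

```python
import fretlines as fl

ctx = fl.FretContext(R0=50.0, tauD0=4.0)    # Förster radius Å, lifetime ns

# a molecule switching between two states
s1, s2 = fl.FretState("high", E=0.8), fl.FretState("low", E=0.2)
dyn = fl.dynamic_line_two_state(s1, s2, ctx)
mid = dyn.samples.iloc[100]                  # occupancy x1 = 0.5
print(mid["E"], mid["tauF_ns"])              # 0.500  2.72

print(fl.dynamic_shift(0.1, 0.9))            # 0.2828...
```

The equal mixture appears at E = 0.500 but τ_F = 2.72 ns, not the 2.00 ns
the static line predicts — long-lived (low-FRET) species contribute more
photons to the delay-time average.  The dynamic shift `ds` is the maximal
orthogonal distance of such a line from the static line in normalized
coordinates: 0.28 for limiting efficiencies 0.1/0.9, well above the
typical ~0.05 detectability threshold.

The same check end-to-end through the simulator
(`examples/06_simulate_and_analyze.py`, 1000 bursts at 100 photons/ms,
exchange at 1/ms):

```
population centroid: E = 0.535, tauF = 2.14 ns
static line at that E would give tauF = 1.86 ns
moment-space residual from the dynamic line: -0.0027 ± 0.0288 ns²
```

The simulated population is displaced from the static line and its
centroid is statistically on the two-state dynamic line.

Each script in `examples/` is a short narrative of one capability:
Förster relations, static/dynamic lines, three-state fraction recovery,
donor mixtures, linker/polymer/folding lines, and simulation + analysis.

## Command line

```
fretline line --kind dynamic --config line.yaml --out dyn.csv
fretline simulate --config sim.yaml --out-prefix run
fretline analyze run.photons.csv --out-prefix ana
```

All outputs are plain CSV with JSON metadata sidecars recording the
resolved parameters, so every run is reproducible from its outputs.

## See also

`docs/methods.md` describes the models, their assumptions, the numerical
choices and the limits of what the synthetic-data validation shows.
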