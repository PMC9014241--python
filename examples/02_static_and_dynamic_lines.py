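"""Static and two-state dynamic FRET-lines, and the dynamic shift.

Pure (single-lifetime) states fall on the diagonal static line
E = 1 - tauF/tauD0.  A molecule exchanging between two states traces a
curved line whose maximal orthogonal distance from the static line — the
dynamic shift ds — depends only on the two limiting efficiencies.
"""

import fretlines as fl

ctx = fl.FretContext(R0=50.0, tauD0=4.0)

static = fl.static_line_ideal(ctx)
print("Static line endpoints:",
      static.samples.iloc[0][["E", "tauF_ns"]].tolist(), "->",
      static.samples.iloc[-1][["E", "tauF_ns"]].tolist())

s1, s2 = fl.FretState("high", E=0.8), fl.FretState("low", E=0.2)
dyn = fl.dynamic_line_two_state(s1, s2, ctx)
mid = dyn.samples.iloc[100]  # x1 = 0.5
print(f"Equal mixture of E=0.8/0.2: E = {mid['E']:.3f}, "
      f"tauF = {mid['tauF_ns']:.2f} ns (static line would give "
      f"{(1 - mid['E']) * 4:.2f} ns)")
print("The excess tauF is the fingerprint of dynamics: long-lived species "
      "contribute more photons to the delay-time average.")

print()
for E1, E2 in ((0.1, 0.9), (0.3, 0.7), (0.5, 0.95)):
    print(f"dynamic shift ds(E1={E1}, E2={E2}) = "
          f"{fl.dynamic_shift(E1, E2):.2f}")
print("Shifts above ~0.05 are typically detectable in calibrated "
      "measurements.")
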