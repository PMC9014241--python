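"""Förster relations: distance, efficiency, lifetime and transfer rate.

A donor-acceptor pair with Förster radius 50 Å and donor-only lifetime
4 ns.  The printed values show the 1/(1+(R/R0)^6) distance dependence and
how FRET quenches the donor lifetime to (1-E)·tauD0.
"""

import fretlines as fl

ctx = fl.FretContext(R0=50.0, tauD0=4.0)

for R in (40.0, 50.0, 60.0):
    E = fl.efficiency_from_distance(R, ctx)
    tau = fl.lifetime_from_efficiency(E, ctx)
    k = fl.ret_rate(R, ctx)
    print(f"R = {R:5.1f} Å  ->  E = {E:.3f},  tau_DA = {tau:.2f} ns, "
          f"k_RET = {k:.3f} /ns")

print()
print("Inverse: E = 0.25  ->  R =", f"{fl.distance_from_efficiency(0.25, ctx):.1f} Å")
print("At R = R0 the efficiency is 1/2 and the transfer rate equals 1/tauD0.")
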