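"""Equilibrium operational sex ratio along single parameter axes.

Reproduces the two characteristic responses of the OSR: it rises with
the interbirth interval at fixed lifespan (each dependant keeps its
mother out of the mating pool for longer) and with lifespan at fixed
interbirth interval (male fertile years grow while female fertility
still ends at 45).
"""
from pairbond import AxisSpec, ParameterSet, osr_curve

print("OSR vs interbirth interval (years), by lifespan:")
for L in (25, 30, 38):
    df = osr_curve(ParameterSet(L=float(L)),
                   AxisSpec("interbirth_interval", [2, 3, 4, 5, 6]))
    osr = "  ".join(f"{v:6.2f}" for v in df.osr)
    print(f"  L={L}:  {osr}")

print("\nOSR vs lifespan (years), by interbirth interval:")
for ib in (3, 4, 5):
    df = osr_curve(ParameterSet(beta=1.0 / ib),
                   AxisSpec("L", [20, 25, 30, 35, 40, 45]))
    osr = "  ".join(f"{v:6.2f}" for v in df.osr)
    print(f"  interbirth={ib}:  {osr}")

print("""
Every row increases monotonically: longer interbirth intervals and
longer lifespans both inflate the number of fertile males competing for
each free fertile female.""")
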