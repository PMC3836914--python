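"""Compare the four annealing-temperature methods on primers of
increasing length.

The Wallace rule (2(A+T) + 4(G+C)) climbs linearly with length, which is
why it is only a rule of thumb beyond ~14 bases; the nearest-neighbor
methods flatten out because duplex stability per added stack saturates.
Method choice is a single parameter — all methods share one contract.
"""

import random

from primerforge.thermo import METHODS, TmParams, melting_temperature

rng = random.Random(7)
oligo = "".join(rng.choice("ACGT") for _ in range(100))

print(f"{'length':>6}  " + "  ".join(f"{name:>14}" for name in sorted(METHODS)))
for length in (12, 20, 32, 60, 100):
    s = oligo[:length]
    tms = [melting_temperature(s, TmParams(method=m)) for m in sorted(METHODS)]
    print(f"{length:>6}  " + "  ".join(f"{t:>14.2f}" for t in tms))

print()
print("Values are Tm in degrees C at 50 nM total oligo, 50 mM Na+.")
print("santalucia_nn (the oligoTm-style default) is the one used for")
print("primer evaluation unless another method is selected.")
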