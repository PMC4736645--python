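"""Invasion-front speeds on a mutation-free strip.

Measures how fast (i) cooperators expand into empty space and (ii)
selfish individuals sweep through a resident cooperator population, on
a 512x32 strip with absorbing boundaries.  Cooperator expansion runs
near one node per step and slows as costs rise; the selfish sweep is an
order of magnitude slower, speeds up sharply with cost, and does not
care how much the residents produce — the two opposite cost trends are
what segregate selection pressures between the front and the back of a
travelling wave.
"""

import numpy as np

from pglattice import InvasionScenario, SimulationParams, invasion_assay

base = SimulationParams(seed=3)

print("cooperators (p = 6) into empty space:")
for c in (3.0, 4.0, 5.0):
    sc = InvasionScenario("cooperators_into_empty", invader_p=6.0, c=c)
    m = invasion_assay(sc, base, np.random.default_rng(30 + int(c)))
    print(f"  c = {c}: rate = {m.invasion_rate:.3f} nodes/step")

print("selfish (p = 0.2) into resident cooperators (p = 6):")
for c in (3.0, 4.0, 5.0):
    sc = InvasionScenario(
        "selfish_into_cooperators", invader_p=0.2, resident_p=6.0, c=c
    )
    m = invasion_assay(sc, base, np.random.default_rng(50 + int(c)))
    print(f"  c = {c}: rate = {m.invasion_rate:.3f} nodes/step")

print("\nRates are invaded length / arrival time (nodes per Monte-Carlo step).")
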