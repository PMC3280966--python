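"""Sensitivity scan and mutant scenarios.

Perturbs every kinetic parameter one at a time around the calibrated
reference and classifies the resulting steady patterns, then runs the
mutant scenarios: reduced FGF10 expression, enhanced SHH diffusion,
scaled-up Ptc production, and the SHH-expression series with its Ptc
emergence times.  Directions, not magnitudes, are the readout: reduced
FGF10 expression spaces branch points further apart; more Ptc production
lowers peak SHH; weaker SHH expression delays Ptc emergence.
"""

import numpy as np

from lungbud import REFERENCE
from lungbud.experiments import mutant_suite, sensitivity_scan

np.seterr(over="ignore", invalid="ignore")

scan = sensitivity_scan(REFERENCE, factors=(0.8, 1.2), t_end=200.0)
print(f"reference class: {scan.reference_class}")
preserved = scan.preserved_at(0.2)
print("class preserved at +-20%:")
for name, ok in preserved.items():
    print(f"  {name:8s} {'yes' if ok else 'no '}   "
          f"({scan.classes(name)})")

print("\nmutant scenarios:")
table = mutant_suite(REFERENCE, seed=1)
for scenario in table.scenario.unique():
    sub = table[table.scenario == scenario]
    desc = ", ".join(f"{m}={v if not isinstance(v, float) else round(v, 3)}"
                     for m, v in zip(sub.metric, sub.value))
    print(f"  {scenario:12s} {desc}")
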