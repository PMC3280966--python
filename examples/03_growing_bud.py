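"""Branching-mode selection on a growing lung bud.

Grows the stalk by tip-localised insertion at the fast reference speed
(14 um/h) for one simulated day, tracks where and when new FGF10 maxima
appear, and contrasts the resulting branching mode with a slower
protocol.  Fast growth keeps an FGF10 maximum locked at the advancing
tip while new flank maxima are inserted along the stalk (lateral
branching); sufficiently slow growth loses the tip maximum (bifurcation
mode).
"""

from lungbud import REFERENCE, Scales
from lungbud.experiments import (FAST_GROWTH_UM_H, classify_growth_run,
                                 growth_protocol)
from lungbud.growth import establishment_time
from lungbud.patterns import branch_events

scales = Scales()
day = 86400.0 / scales.T                      # one day, dimensionless
growth = growth_protocol(FAST_GROWTH_UM_H, t_end=day)
print(f"fast protocol: tip speed {growth.v:.4f} (= {FAST_GROWTH_UM_H} um/h), "
      f"one day = {day:.1f} time units")

report, trajectory = classify_growth_run(REFERENCE, growth, seed=2)
final = trajectory[-1]
print(f"final stalk length: {final.mesh.h:.1f} lumen radii")
print(f"pattern class: {report.pattern_class}")
if report.mean_spacing:
    print(f"mean inter-branch spacing: {report.mean_spacing:.2f} "
          f"(= {scales.L * report.mean_spacing:.0f} um)")

events = branch_events(trajectory)
t_est = establishment_time(trajectory)
print(f"pattern established at t = {t_est:.0f}")
for e in events:
    if e.t > t_est + 5.0:
        print(f"  new branch site at t={e.t:5.1f}, axial y={e.y:.2f} "
              f"({e.distance_behind_tip:.1f} behind the tip)")
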