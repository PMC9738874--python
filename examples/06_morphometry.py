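"""Kidney volumetry, growth rates and the reference growth curve.

Shows the ellipsoid volume estimate from MRI axis lengths, the exponential
growth-rate of a body-weight series, the 5-anchor logistic reference curve,
and the cumulative dose of the cardiotoxic regimen.
"""

import numpy as np

from renalpet import (
    GrowthSeries,
    KidneyAxes,
    cumulative_dose,
    ellipsoid_volume,
    growth_rate,
    sigmoid_reference,
)

axes = KidneyAxes(length=19.5, width=12.6, depth=13.0)
print(f"kidney axes {axes.length} x {axes.width} x {axes.depth} mm "
      f"-> volume {ellipsoid_volume(axes):.0f} mm^3")

days = np.arange(56.0, 120.0, 7.0)
weights = 290.0 * np.exp(0.009 * (days - 56.0))
rate = growth_rate(GrowthSeries(days, weights))
print(f"growth rate {rate:.4f} per day (doubling time {np.log(2) / rate:.0f} days)")

anchors_d = [28.0, 56.0, 84.0, 112.0, 140.0]
anchors_w = [95.0, 290.0, 420.0, 480.0, 515.0]
sig = sigmoid_reference(anchors_d, anchors_w)
print("reference curve at days 60/90/120:",
      [f"{float(sig(d)):.0f} g" for d in (60, 90, 120)])

print(f"cumulative doxorubicin dose: {cumulative_dose(1.0, 2, 6):.0f} mg/kg "
      "(1 mg/kg twice weekly for 6 weeks)")
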