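"""Early-Patlak slope markers for one healthy subject.

Computes the Patlak transform of each renal/hepatic curve against the aorta
curve and regresses the region-specific early windows: cortex/medulla over
the first 9 s of tracer activity (vascular transit analog), pelvis over
60-120 s after arrival (urinary extraction ramp), liver over its long early
linear rise (method control).
"""

from renalpet import (
    default_group_params,
    first_nonzero_frame,
    fit_slope,
    patlak_transform,
    prescribed_window,
    simulate_subject,
)

rec = simulate_subject(default_group_params("L1", rng_seed=7))
aorta = rec.tacs["aorta"]
t0 = aorta.schedule.start[first_nonzero_frame(aorta)]
print(f"tracer arrival t0 = {t0:.0f} s after scan start\n")

print(f"{'region':<8} {'window (s)':<16} {'slope/min':>10} {'R^2':>7}")
for region in ("cortex", "medulla", "pelvis", "liver"):
    points = patlak_transform(rec.tacs[region], aorta)
    window = prescribed_window(region, t0, aorta.schedule.end[-1])
    m = fit_slope(points, window, region=region)
    span = f"[{window.t_start:.0f}, {window.t_end:.0f}]"
    print(f"{region:<8} {span:<16} {m.slope_per_min:>10.3f} {m.r_squared:>7.3f}")

# Higher cortical/medullary slopes mean better early tracer delivery; the
# pelvic slope tracks how fast filtered tracer reaches the collecting system.
# In diseased groups all three fall below their age-control values.
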