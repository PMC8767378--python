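"""Render one synthetic subject, calibrate from the ruler, and measure the nose.

Builds a three-view scene with known ground truth, recovers the mm-per-pixel
scale from the rendered ruler ticks, and converts landmark pixel geometry
into calibrated measurements.  The printed pairs show that the measurement
pipeline reproduces the generator's values.
"""

from nasoform.anthropometry import calibrate_scale, measure_subject
from nasoform.synthetic import (PopulationParams, RenderConfig,
                                render_subject_views, sample_population)

rec = sample_population(PopulationParams(n=1, seed=7))[0]
views = render_subject_views(rec, RenderConfig(), seed=7)

calibrations = {}
for view, rv in views.items():
    cal = calibrate_scale(rv.ruler_ticks_px, rv.tick_spacing_mm, view=view)
    calibrations[view] = cal
    print(f"{view:8s} scale {cal.mm_per_px:.4f} mm/px "
          f"(ruler ticks every {rv.tick_spacing_mm:g} mm)")

table = measure_subject({v: rv.landmarks for v, rv in views.items()},
                        calibrations, provenance="ground_truth")

print("\nmeasurement        measured   generator   units")
for code in ("n-prn", "n-sn", "n-r", "al-al", "ac-ac", "en-en", "g-n-prn"):
    value, units = table.values[code]
    print(f"{code:16s} {value:9.3f} {rec.surface[code]:11.3f}   {units}")
print("\nMeasured values equal the generator's surface traits: pixel geometry")
print("plus ruler calibration is lossless at sub-pixel landmark precision.")
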