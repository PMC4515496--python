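"""Quantify one synthetic scan end to end.

Builds a moderate-fatty-liver phantom (liver parenchyma brighter than the
renal cortex by 22.0 intensity units), runs the full pipeline, and prints
the hepatorenal report.
"""

from hriq import PhantomSpec, RunConfig, SOMConfig, analyze_image, generate_phantom
from hriq.phantom import REFERENCE_CLASS_MEANS

liver_mean, kidney_mean = REFERENCE_CLASS_MEANS["moderate"]
phantom = generate_phantom(
    PhantomSpec(liver_mean=liver_mean, kidney_mean=kidney_mean, noise_cv=0.1, seed=7)
)
report = analyze_image(phantom.image, RunConfig(som=SOMConfig(seed=7)))

print(f"true liver-kidney difference : {phantom.true_hri_diff:.3f}")
print(f"liver representative         : {report.liver_rep:.3f}")
print(f"kidney representative        : {report.kidney_rep:.3f}")
print(f"recovered HRI-diff           : {report.hri_diff:.3f}")
print(f"severity grade               : {report.severity}")
# The representatives are the mean intensities of each ROI's largest
# SOM cluster; their difference tracks the known 22.0-unit contrast and
# lands in the "moderate" severity band (>= 15.23).
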