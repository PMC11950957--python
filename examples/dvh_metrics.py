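"""Compute the standard DVH plan-quality metrics for one synthetic plan.

Prints the full 23-metric table (PTV coverage/homogeneity, organ-at-risk
dose-volume points) the way treatment-plan reports tabulate them.
"""

import numpy as np

from phandose.dvh import GY_METRICS, metric_suite
from phandose.phantom import PhantomConfig, generate_plan_sample
from phandose.preprocess import rescale_to_coverage

sample, _ = generate_plan_sample(PhantomConfig(), "demo", np.random.SeedSequence(7))
dose, factor = rescale_to_coverage(sample.dose, sample.masks["PTV"])
print(f"coverage rescale factor: {factor:.4f} "
      f"(so 95% of the PTV receives 95% of {dose.prescription} Gy)\n")

table = metric_suite(dose, sample.masks)
for (structure, metric), value in table.items():
    unit = "Gy" if metric in GY_METRICS else "%"
    print(f"{structure:16s} {metric:6s} {value:8.2f} {unit}")

print(
    "\nD_x% is the minimum dose to the hottest x% of a structure; V_xGy the"
    "\npercentage of it receiving at least x Gy.  HI is the PTV homogeneity"
    "\nindex 100*(D2%-D98%)/D50%; R50% measures how far the half-prescription"
    "\nisodose spills beyond the target."
)
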