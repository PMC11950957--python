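"""Generate a small synthetic pelvic cohort and summarise its rectal dosimetry.

Each phantom is one patient-equivalent VMAT plan: CT-like image, six
structures and an analytic dose with concave rectal sparing.  The printed
table shows how the sampled PTV-rectum gap drives the rectum's high-dose
volume (V70Gy) and hence the modelled grade >= 2 late-rectal-bleeding risk.
"""

from phandose import PhantomConfig, generate_cohort, ntcp_suite, rescale_to_coverage
from phandose.dvh import compute_dvh, volume_at_dose

cfg = PhantomConfig(cohort_size=10, seed=42)
samples, records = generate_cohort(cfg)

print(f"{'id':12s} {'gap mm':>7s} {'rectum V70Gy %':>14s} {'G2-LRB LKB NTCP %':>18s}")
for sample, rec in zip(samples, records):
    dose, _ = rescale_to_coverage(sample.dose, sample.masks["PTV"])
    curve = compute_dvh(dose, sample.masks["rectum"])
    v70 = volume_at_dose(curve, 70.0)
    ntcp = ntcp_suite(dose, sample.masks["rectum"])["G2-LRB-LKB-NTCP"]
    print(f"{sample.id:12s} {rec['gap']:7.1f} {v70:14.2f} {ntcp:18.2f}")

print(
    "\nA smaller (more negative) gap means the PTV margin reaches further into"
    "\nthe anterior rectal wall, so more rectum sits in the high-dose region"
    "\nand the bleeding risk rises - the anatomical signal the dose-prediction"
    "\nmodel has to learn."
)
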