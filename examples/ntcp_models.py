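"""Rectal NTCP from a dose-volume histogram: LKB and relative seriality.

Builds a toy rectum DVH, converts each bin to its equivalent dose in 2-Gy
fractions (EQD2, linear-quadratic model, alpha/beta = 3 Gy), and evaluates
both complication-probability models across the packaged endpoint registry.
"""

import numpy as np

from phandose.radiobio import (
    REGISTRY,
    effective_dose,
    eqd2,
    lkb_ntcp_from_bins,
    rs_ntcp_from_bins,
)

# toy differential DVH of a rectum: most volume at low dose, a hot anterior wall
dose_bins = np.array([10.0, 30.0, 50.0, 65.0, 72.0])   # physical Gy over 34 fractions
rel_volume = np.array([0.45, 0.25, 0.15, 0.10, 0.05])

eqd2_bins = eqd2(dose_bins, n_fractions=34, alpha_beta=3.0)
print("physical Gy :", dose_bins)
print("EQD2 Gy     :", np.round(eqd2_bins, 2))
print("(doses above 2 Gy/fraction are inflated, below are deflated)\n")

print(f"{'endpoint':24s} {'model':5s} {'NTCP %':>8s}")
for name, p in REGISTRY["lkb"].items():
    ntcp = 100 * lkb_ntcp_from_bins(eqd2_bins, rel_volume, p)
    print(f"{name:24s} {'LKB':5s} {ntcp:8.2f}")
for name, p in REGISTRY["rs"].items():
    ntcp = 100 * rs_ntcp_from_bins(eqd2_bins, rel_volume, p)
    print(f"{name:24s} {'RS':5s} {ntcp:8.2f}")

g2 = REGISTRY["lkb"]["G2-LRB"]
deff = effective_dose(eqd2_bins, rel_volume, g2)
print(
    f"\nFor grade >= 2 bleeding (LKB), the generalised-mean effective dose is"
    f"\nDeff = {deff:.1f} Gy with volume exponent n = {g2.n}: the small n makes the"
    f"\nrectum behave serially, so the hottest subvolume dominates the risk."
)
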