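# NTCP endpoint parameter registry, version 1.
#
# LKB entries: n (volume effect, -> 0 means more serial), m (slope),
# td50 (Gy, tolerance dose for 50% complication), alpha_beta (Gy).
# RS entries: d50 (Gy), gamma (normalised slope at D50), s (seriality),
# alpha_beta (Gy).
#
# All endpoints describe late rectal toxicity after prostate radiotherapy.
# Grading: in the LKB set, grade 1 = toxicity not requiring intervention,
# grade >= 2 = toxicity requiring any intervention.  In the RS set, grade 1 =
# bleeding up to twice a week, grade 2 = more than twice a week.
version: 1
lkb:
  G1-LRB:              {n: 0.23, m: 0.37, td50: 57.3,  alpha_beta: 3.0}
  G2-LRB:              {n: 0.19, m: 0.32, td50: 75.8,  alpha_beta: 3.0}
  G1-stool-frequency:  {n: 0.27, m: 0.56, td50: 55.7,  alpha_beta: 3.0}
  G2-stool-frequency:  {n: 0.31, m: 0.36, td50: 75.8,  alpha_beta: 3.0}
  G1-bowel-pain:       {n: 0.17, m: 0.49, td50: 142.6, alpha_beta: 3.0}
  G1-sphincter-control: {n: 0.24, m: 0.32, td50: 79.1, alpha_beta: 3.0}
  G1-stricture-ulcer:  {n: 0.32, m: 0.25, td50: 84.4,  alpha_beta: 3.0}
rs:
  G2-LRB:              {d50: 83.6, gamma: 1.42, s: 0.50, alpha_beta: 3.0}
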