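# Default selection/elimination score configuration (schema v1).
#
# Each term maps a property through a piecewise-linear desirability in
# [0, 1] (knots: [property value, desirability]) and multiplies it by a
# weight.  The eight physicochemical desirabilities plateau at 1 across the
# drug-likeness rule windows (Lipinski / Ghose / Veber and the unified
# 160 <= MW <= 480, -0.4 <= logP <= 5 windows) and fall off linearly
# outside; mutagenicity and synthetic-difficulty desirabilities decrease,
# the LD50 desirability increases.  Maximum attainable S_S: 3.9.
schema: aoxdesign-score-config/1
terms:
  MW:            {weight: 0.3, desirability: [[100, 0.0], [160, 1.0], [480, 1.0], [600, 0.0]]}
  logP:          {weight: 0.3, desirability: [[-2.4, 0.0], [-0.4, 1.0], [5.0, 1.0], [7.0, 0.0]]}
  HBA:           {weight: 0.3, desirability: [[0, 1.0], [10, 1.0], [15, 0.0]]}
  HBD:           {weight: 0.3, desirability: [[0, 1.0], [5, 1.0], [10, 0.0]]}
  rotatable_bonds: {weight: 0.3, desirability: [[0, 1.0], [10, 1.0], [15, 0.0]]}
  TPSA:          {weight: 0.3, desirability: [[0, 1.0], [140, 1.0], [200, 0.0]]}
  heavy_atoms:   {weight: 0.3, desirability: [[10, 0.0], [20, 1.0], [70, 1.0], [90, 0.0]]}
  molar_refractivity: {weight: 0.3, desirability: [[20, 0.0], [40, 1.0], [130, 1.0], [160, 0.0]]}
  # Ames mutagenicity as probability of a positive call (booleans map to 0/1).
  ames:          {weight: 0.5, desirability: [[0.0, 1.0], [1.0, 0.0]]}
  # Rat oral LD50 in mg/kg: higher (less acutely toxic) is better.
  LD50:          {weight: 0.5, desirability: [[0, 0.0], [5000, 1.0]]}
  # Synthetic-accessibility score on the common 1 (easy) .. 10 (hard) scale.
  SA:            {weight: 0.5, desirability: [[1.0, 1.0], [10.0, 0.0]]}
elimination:
  aggregate: sum
  # standardized deviations above this are flagged (direction-aware)
  flag_threshold: 2.0
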