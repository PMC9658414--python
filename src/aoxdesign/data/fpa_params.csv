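# SYNTHETIC calibration table for the fitted-parameters approach (FPA),
# pKa = m * dG_BA + C0, one row per acidic-site family.  These slopes and
# intercepts are plausible placeholder fits for a generic solvation-corrected
# DFT level; replace with a published calibration for production use.
# units: m in 1/(kcal/mol); C0 in pKa units; dG_BA in kcal/mol.
family,m,C0,level_of_theory
phenol,0.25,-62.0,synthetic-calibration
amine,0.28,-70.0,synthetic-calibration
carboxylic acid,0.22,-55.0,synthetic-calibration
thiol,0.23,-57.0,synthetic-calibration
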