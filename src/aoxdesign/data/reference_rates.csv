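# Apparent rate coefficients of reference antioxidants with the peroxyl
# radical (HOO•), per medium, M^-1 s^-1.  Aqueous values are pH-conditioned
# apparent coefficients at physiological pH.
antioxidant,medium,k
Trolox,lipid,3.40e3
ascorbic_acid,lipid,5.71e3
alpha-tocopherol,lipid,3.0e6
Trolox,aqueous,8.96e4
ascorbic_acid,aqueous,3.07e5
alpha-tocopherol,aqueous,2.0e5
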