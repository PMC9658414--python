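# aoxdesign

Computer-assisted design and screening of **multifunctional antioxidants** —
candidate molecules that combine oral-drug-like behavior with several,
complementary modes of antioxidant protection (direct radical scavenging,
metal chelation that suppresses Fenton-type •OH production, repair of
oxidatively damaged biomolecules) and multi-target neuroprotection
(inhibition of COMT, AChE and MAOB). The package is aimed at computational
chemists who already produce the underlying electronic-structure and docking
numbers and need the protocol around them: enumeration, triage, speciation,
kinetics, thermodynamics and reporting. It does **not** run quantum
chemistry or docking; those results enter as tables.

## What it computes

**Candidate building.** Derivatives of a parent scaffold are enumerated by
adding up to *m* small functional groups (−OH, −NH₂, −SH, −COOH) at
designated sites, one group per site, with canonical-SMILES deduplication.
On a symmetry-free scaffold the count is `Σ_{k=1..m} C(s,k)·gᵏ`.

**Triage scores.** Each candidate gets a *selection score*
`S_S = Σ_i w_i·d_i(x_i)` over eleven terms — eight ADME descriptors (MW,
logP, HBA, HBD, rotatable bonds, TPSA, heavy atoms, molar refractivity,
checked against Lipinski/Ghose/Veber and the unified windows
160 ≤ MW ≤ 480, −0.4 ≤ logP ≤ 5) plus Ames mutagenicity, rat oral LD50 and
synthetic accessibility. Per-property *elimination scores*
`S_E = |x − μ_ref|/σ_ref` flag outliers against a reference set, with
desirable-direction deviations (e.g., unusually low toxicity) reported but
never auto-eliminating. The term shapes live in a versioned YAML config.

**Reactivity triage (eH-DAMA).** Species are placed at (ionization energy,
minimum bond-dissociation energy); the bottom-left corner marks the best
scavengers via single electron transfer (SET) and formal H-atom transfer
(f-HAT). Ranking is Pareto dominance with normalized-distance tie-breaks,
and up to six candidates continue.

**Speciation.** Site pKa values come from the fitted-parameters approach,
`pKa = m·ΔG_BA + C₀` per acidic-site family; microspecies fractions follow
the closed-form sequential-deprotonation equilibrium, and candidates whose
neutral fraction at pH 7.4 falls below 1% are discarded (no passive membrane
crossing).

**Kinetics.** Per-channel rate coefficients use conventional TST,
`k = σ·κ·(k_B T/h)·e^{−ΔG‡/RT}`, with asymmetric-Eckart tunneling κ for
f-HAT, Marcus theory `ΔG‡ = (λ/4)(1 + ΔG°/λ)²` for SET,
Smoluchowski/Stokes–Einstein diffusion limits with Collins–Kimball
correction `k_app = k_D·k_act/(k_D + k_act)`, and molar-fraction weighting
`k_total = Σ_s f_s Σ_c k_app` at the working pH. The same engine powers the
biomolecule-repair routes (lipid, Cys/His/Leu/Met/Trp/Tyr residues, and the
three DNA-repair routes including the two-step SHATD).

**Chelation/OIL.** Conditional Gibbs energies
`ΔG′ = ΔG° − n·RT·ln10·pH` for coupled deprotonation–chelation, Boltzmann
populations of competing complexes, and classification of whether chelation
fully inhibits or strongly lowers metal reduction (OIL-1).

**Binding post-processing.** Docking energies convert to inhibition
constants `K_i = e^{−G_U/RT}`, and a polygenic score aggregates binding
across the three target enzymes relative to their natural substrates.

## Worked example

Closed-form speciation of a diprotic candidate (thiol pKa 5.90, phenol pKa
12.12) at physiological pH:

```console
$ aoxdesign speciate --pkas 5.90,12.12 --pH 7.4
H2A     0.0306529
HA-     0.969329
A-2     1.84702e-05
```

About 3.1% of the population stays neutral (enough for passive membrane
crossing) while the mono-anion dominates at 96.9%; the di-anion is
negligible.

Comparing a candidate's overall rate coefficients against reference
antioxidants (aqueous comparisons are first weighted by the peroxyl
radical's neutral fraction, 0.0025 at pH 7.4 for pKa 4.8):

```python
>>> from aoxdesign import compare_to_references
>>> compare_to_references(5.17e6, "lipid", {"Trolox": 3.40e3, "ascorbic_acid": 5.71e3})
{'Trolox': 1520.0, 'ascorbic_acid': 905.0}
>>> compare_to_references(9.96e9, "aqueous", {"Trolox": 8.96e4}, target_fraction=0.0025)
{'Trolox': 278.0}
```

So this candidate out-scavenges Trolox 1520-fold in lipid media and
278-fold in water.

The full protocol runs end to end on the bundled, internally consistent
study-case fixture (see `docs/methods.md` for what is synthetic about it):

```console
$ aoxdesign run --study-case --out report.json
report -> report.json
```

The report carries, per stage: selection scores (derivative 3.61, parent
3.75), the eH-DAMA ranking (the mono-anion leads), speciation, overall rate
coefficients (9.96 × 10⁹ M⁻¹s⁻¹ aqueous, 5.17 × 10⁶ lipid, with 74.6/25.4%
SET/f-HAT branching in water), the dominant chelation complex (99.993% of
the population, ascorbate reduction fully inhibited), per-target repair
rates, the polygenic ranking, and a provenance trail of every pass/fail
decision.

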