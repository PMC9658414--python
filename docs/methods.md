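# Methods

This note documents the models implemented in `aoxdesign`, the choices made
where the protocol leaves the design open, what the synthetic fixtures do
and do not emulate, and the numerical details that matter for
reproducibility.

## Scope and division of labor

The package implements the *protocol* around electronic-structure and
docking calculations, not the calculations themselves. Reaction Gibbs
energies, activation barriers, imaginary frequencies, reorganization
energies, deprotonation energies ΔG_BA, complexation energies, ionization
and bond-dissociation energies, docking binding energies, and externally
predicted Ames/LD50/synthetic-accessibility values are all **inputs**,
supplied as headered CSV tables. Everything downstream of those inputs —
scores, maps, speciation, rate coefficients, populations, classifications,
reports — is computed here.

## Selection and elimination scores

The multi-objective triage is a weighted desirability sum,

    S_S = Σ_i w_i · d_i(x_i),   d_i : property → [0, 1],

with eleven terms: eight physicochemical descriptors and three
negative-design terms (Ames mutagenicity probability, rat oral LD50,
synthetic accessibility on the common 1–10 scale). The desirability shapes
are piecewise-linear and live in `data/scores_default.yaml`
(`aoxdesign-score-config/1`): the physicochemical terms plateau at 1 across
the drug-likeness rule windows and fall off linearly outside; the Ames and
SA terms decrease; the LD50 term increases. Weights are 0.3 per
physicochemical term and 0.5 per negative-design term (maximum S_S 3.9).
The engine guarantees only the structural contracts — the total is the sum
of its terms, is non-increasing in mutagenicity and non-decreasing in
ease-of-synthesis and rule compliance — so the algebra can be revised as
data without touching code. Descriptors are computed with RDKit on the
canonical atom ordering (Wildman–Crippen logP and MR, Ertl TPSA); the
backend is recorded in `profiles.DESCRIPTOR_BACKEND` because rule outcomes,
not exact descriptor values, are the reproducible quantity.

Per-property elimination scores are standardized deviations
`|x − μ_ref|/σ_ref` against a reference set of molecules already in use for
the indication; the ADMETSA aggregate is their plain sum. A deviation
larger than the flag threshold (default 2.0) is marked *desirable* when the
desirability at x is at least that at the reference mean — e.g., a
candidate far less mutagenic than the reference average. Desirable
deviations are reported, never auto-eliminating; elimination is a
human-reviewed decision.

## eH-DAMA ranking rule

"Bottom-left is best" fixes no numeric ordering, so the package makes one
explicit: non-dominated sorting on (IE, min-site BDE) with both axes
lower-is-better, ties within a Pareto front broken by Euclidean distance to
the candidate set's component-wise minimum after range normalization. The
rule is invariant under per-axis affine rescaling, which is the natural
requirement for a map whose axes carry different units (eV vs kcal/mol).
Per-protonation-state entries rank separately and carry their molar
fractions into the report. Candidates whose SET against the target radical
is more exergonic than −40 kcal/mol get a Marcus-inverted-region warning
(the map may overstate their SET rate); the map itself is unchanged.

## Speciation

Site pKa values use the fitted-parameters approach (FPA), a per-family
linear map pKa = m·ΔG_BA + C₀. The shipped `data/fpa_params.csv` is a
**synthetic calibration** with plausible slopes/intercepts — the point of
the FPA table being runtime data is precisely that users substitute their
published calibration for their level of theory. When a molecule has
several acidic sites the deprotonation route orders them by ascending site
pKa (most acidic leaves first) and collapses branching microstates onto
that dominant route. Fractions follow the closed form

    f_j ∝ 10^(j·pH − Σ_{i≤j} pKa_i),

shift-stabilized and normalized; temperature is fixed at 298.15 K and the
default pH is 7.4. Candidates with neutral fraction strictly below 1% are
discarded (passive membrane permeation requires a non-negligible neutral
population); exactly 1% is kept. The hydroperoxyl radical's pKa (4.8) is a
configurable literature constant.

## Kinetics

Conventional TST on a 1 M standard state with reaction-path degeneracy σ
(an input integer, not perceived from structure). Eckart tunneling for
f-HAT channels uses the asymmetric barrier fixed by the forward/reverse
Gibbs barriers and the transition state's imaginary frequency; the
transmission coefficient is

    κ = e^{ΔG‡/RT} ∫₀^∞ P(E)·e^{−E/RT} dE/RT,

with P(E) evaluated in log space (the hyperbolic cosines overflow double
precision long before chemically relevant barriers are reached) and the
integral done by adaptive quadrature at relative tolerance 1e-8 plus an
explicit tail segment; non-convergence raises with diagnostics rather than
returning a number. SET channels take their barrier from Marcus theory with
λ supplied (or derived as λ = ΔE_vert − ΔG° when only vertical energies are
available) and get no tunneling; RAF and SHATD hydrogen-transfer steps are
treated like f-HAT, with κ = 1 unless an imaginary frequency is supplied.

Diffusion limits use Smoluchowski with Stokes–Einstein radii
(k_D = 4π·R_AB·D_AB·N_A; ~7.4 × 10⁹ M⁻¹s⁻¹ for equal radii in water at
298.15 K, and radius-independent in that case); default viscosities are
8.91 × 10⁻⁴ Pa·s (water) and 8.62 × 10⁻⁴ Pa·s (pentyl ethanoate as lipid
mimic). Apparent rates are Collins–Kimball interpolations, so k_app ≤ k_D
per channel while the *sum* over channels and species may exceed any single
k_D. Overall coefficients weight per-state channel sums by microspecies
molar fractions at the working pH; branching ratios are the weighted
shares. Fold comparisons against reference antioxidants multiply the
candidate's aqueous coefficient by the target radical's neutral fraction
first (the tabulated reference values are pH-conditioned apparent
coefficients) and round to three significant figures.

Repair routes reuse the same engine per target: lipid model (f-HAT from the
thiol, neutral species, lipid medium), six oxidizable residues (f-HAT and,
where exergonic, SET), and three DNA routes — SET repair of
guanine-centered radical cations, f-HAT at the deoxyribose C4 radical, and
SHATD for 8-OH-dG lesions, where the hydrogen-transfer step is
rate-limiting and the dehydration step is checked for exergonicity only
(endergonic dehydration voids the route). Endergonic SET channels are
excluded from kinetics; targets without a viable channel are reported "not
repaired".

## Chelation and OIL-1

Coupled deprotonation–chelation viability is pH-dependent through
ΔG′ = ΔG° − n·RT·ln10·pH (−1.364 kcal/mol per proton per pH unit at
298.15 K), using proton activity 10^(−pH) at unit reference concentration;
coupling to the ligand's own speciation is reported separately (the
reacting microspecies' fraction multiplies the population, not ΔG′).
Competing complexes of equal stoichiometry are populated by the
Maxwell–Boltzmann distribution of their conditional Gibbs energies,
computed shift-stabilized. ΔG° inputs are assumed to already contain the
supplier's metal-solvation bookkeeping (explicit waters around Cu(II)/Cu(I));
the module documents but does not alter that convention. OIL-1
classification: *fully inhibited* when chelation turns an exergonic
reduction endergonic; *strongly lowered* when both remain exergonic but the
chelated reaction is ≥ 10⁴-fold slower (rate ratio if rates are given,
equilibrium ratio e^{ΔΔG/RT} otherwise); *unchanged* else. OIL-2
(scavenging •OH right after Fenton-type production) is covered by the
kinetics module on •OH channels together with the inverted-region warning,
not by a separate simulator.

## Binding post-processing

Binding strengths are stored as positive magnitudes G_U (kcal/mol);
K_i = e^{−G_U/RT} with R = 1.9872 × 10⁻³ kcal/(mol·K), T = 298.15 K. The
polygenic score is the mean over the three target enzymes of the ligand's
G_U relative to that enzyme's natural substrate; a ligand stronger than the
substrate at all three targets is flagged as a possible panel inhibitor.
Single-target reference inhibitors are kept in the tables for comparison
but only ligands with a complete panel enter the ranking.

## Pipeline

Stages run in protocol order (profile/score → subset 1 → eH-DAMA →
subset 2 → speciation → scavenging kinetics → chelation → repair →
binding). Subset 1 ranks by S_S and drops candidates exceeding a
configurable count of large *undesirable* elimination-score deviations
(default 3) — a concrete rule standing in for a triage the protocol leaves
qualitative. Every candidate carries a provenance trail of stage decisions.
A stage whose inputs are absent is skipped with a logged reason; in a
default full run its dependents skip in chain, while explicitly requested
stages fail fast instead. Reports serialize with sorted keys and no
timestamps, so re-runs are byte-identical.

## Synthetic fixtures

`generate_fixtures(seed, size)` fabricates every input table the pipeline
consumes — profiles spanning rule pass/fail cases, ΔG_BA values inverted
from prescribed pKas through the loaded FPA calibration, channel tables
with known analytic outcomes, chelation ΔG sets realizing prescribed
Boltzmann populations, binding records realizing prescribed K_i — keyed to
a single seed.

`study_case_bundle()` is the deterministic counterpart for the melatonin-
derivative study case. Its structures are real (melatonin, and a synthetic
stand-in for the derivative: the melatonin scaffold plus one thiol and one
phenol, 19 heavy atoms); its descriptor values are genuinely computed by
RDKit. Everything a quantum-chemistry or docking code would supply is
*engineered by inverting this package's own forward engines* so that
recomputation lands on the study case's published totals: annotation values
solved so the score engine yields 3.61/3.75/3.0, ΔG_BA values inverted from
pKa 5.90/12.12, channel barriers solved (bracketed root-finding through the
TST/Eckart/Collins–Kimball chain, which is strictly decreasing in the
barrier) so the weighted totals equal 9.96 × 10⁹ and 5.17 × 10⁶ M⁻¹s⁻¹ with
the published mechanism branching, complexation energies inverted from the
99.993% dominant population, and binding magnitudes chosen to reproduce the
published qualitative ordering.

What passing these tests shows: the protocol machinery — every formula
above and the bookkeeping between stages — is self-consistent and correctly
composed, to round-trip precision. What it does **not** show: that any
real molecule has these properties. The fixtures contain no real
electronic-structure data; reproducing the published totals demonstrates
the computation, not the chemistry. Results that depend on external QM
inputs are therefore additionally guarded by property-based tests
(closed-form speciation vs an independent linear-system equilibrium solver;
Eckart κ vs a fine-grid trapezoid oracle on the direct formula; Marcus
symmetry; diffusion capping; branching normalization; Boltzmann shift
invariance; rule flags vs literal inequality recoding; enumeration counts
vs closed-form combinatorics).

## Numerical choices

- Constants: CODATA 2018; R = 1.987204 × 10⁻³ kcal/(mol·K) everywhere
  except the K_i convention above; k_BT/h = 6.21 × 10¹² s⁻¹ at 298.15 K.
- Eckart quadrature: relative tolerance 1e-8, integration variable E/RT,
  upper segment split at ΔG‡/RT + 60; log-space transmission with
  `log1p`/`logaddexp` guards; the d-parameter switches cosh→cos when
  4·α₁α₂ < π².
- Speciation exponents are shifted by their maximum before exponentiation;
  Boltzmann weights by their minimum ΔG.
- Rule bounds are inclusive at both ends (the criteria are stated with ≤).
- Ames inputs may be boolean or probability; the 0.5 threshold for calling
  a probability "positive" is exported as a named constant.
- Degenerate inputs fail loudly: non-ascending pKa routes, zero reference
  dispersions, missing score terms, unknown mechanisms/media, empty
  complex lists and mismatched reductants all raise typed errors.
- Test problem sizes: 1000-case speciation and rule-flag sweeps, 200-case
  Eckart oracle comparison at grid 250001 — sizes chosen so the whole suite
  exercises the randomized contracts well inside a coffee break.

## Known limitations

- No variational TST, small-curvature tunneling, or anharmonicity; Eckart κ
  with Gibbs barriers is the standard protocol choice but can overshoot for
  heavy-light-heavy transfers.
- Stokes–Einstein radii at the ångström scale are a continuum idealization;
  the diffusion limit is best treated as an order-of-magnitude cap.
- The deprotonation route collapses microstate branching; molecules with
  near-degenerate site pKas are only approximately described.
- The shipped FPA table and score-term shapes are calibrations to be
  replaced with user data; rule outcomes and contracts, not absolute
  descriptor or score values, are the stable interface.
- Enumeration attaches groups by single bonds replacing one hydrogen;
  multivalent linkers and ring fusions are out of scope.
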