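"""Synthetic input bundles emulating quantum-chemistry and docking outputs.

The protocol consumes tabulated electronic-structure results (reaction Gibbs
energies, barriers, imaginary frequencies, reorganization energies,
deprotonation energies, complexation energies) and docking binding energies.
This module fabricates internally consistent versions of all of those
tables, two ways:

* :func:`generate_fixtures` — a seeded random bundle of the right schema and
  realistic magnitudes, for schema/property testing at any size;
* :func:`study_case_bundle` — a deterministic bundle for the melatonin-
  derivative study case, built by *inverting* the package's own engines
  (TST/Eckart/Marcus/Collins–Kimball, Boltzmann, FPA, Ki) so that forward
  recomputation through the pipeline lands exactly on the study case's
  published totals.  The dM38 structure here is a synthetic stand-in (the
  melatonin scaffold decorated with one thiol and one phenol, 19 heavy
  atoms); all toxicity/SA annotations are solved, not measured.

Nothing here runs, or substitutes for, an electronic-structure or docking
code: these are test fixtures with prescribed outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd

from . import constants as cn
from . import kinetics as kin
from .chelation import ChelationComplex
from .dama import ReactivityIndexes
from .profiles import MoleculeProfile, compute_descriptors
from .scoring import (BindingRecord, ScoreConfig, binding_from_ki,
                      default_score_config)
from .speciation import load_fpa_table, molar_fractions

__all__ = ["FixtureBundle", "generate_fixtures", "study_case_bundle",
           "load_reference_rates", "MELATONIN_SMILES", "DM38_SMILES"]

MELATONIN_SMILES = "CC(=O)NCCc1c[nH]c2ccc(OC)cc12"
#: Synthetic stand-in for the dM38 derivative: melatonin plus one -SH and
#: one -OH on the benzo ring (19 heavy atoms, thiol-then-phenol route).
DM38_SMILES = "CC(=O)NCCc1c[nH]c2cc(S)c(OC)c(O)c12"

#: Printed study-case quantities the deterministic bundle is engineered to
#: reproduce through forward computation.
STUDY_CASE = {
    "pkas": (5.90, 12.12),
    "S_S": {"dM38": 3.61, "melatonin": 3.75, "reference_average": 3.0},
    "k_overall": {"aqueous": 9.96e9, "lipid": 5.17e6},
    "branching_aqueous": {"SET": 0.746, "f-HAT": 0.254},
    "branching_lipid": {"thiol": 0.995, "phenol": 0.005},
    "dominant_complex_population": 0.99993,
    "repair_rates": {"Tyr_fHAT": 1.74e7, "Tyr_SET": 2.44e8,
                     "2dG-I": 2.45e8, "2dG-III": 1.03e6},
    "hydroperoxyl_pka": cn.PKA_HYDROPEROXYL,
}


@dataclass
class FixtureBundle:
    """Everything one pipeline run consumes, as in-memory tables."""

    molecules: pd.DataFrame                 # id, smiles
    annotations: pd.DataFrame               # id, ames, LD50, SA
    reference_stats: pd.DataFrame           # property, mean, dispersion
    fpa_table: pd.DataFrame                 # family, m, C0, level_of_theory
    sites: pd.DataFrame                     # molecule, site, family, dG_BA
    dama_candidates: list[ReactivityIndexes] = field(default_factory=list)
    dama_references: list[ReactivityIndexes] = field(default_factory=list)
    channels: list[kin.ReactionChannel] = field(default_factory=list)
    repair_channels: list[kin.ReactionChannel] = field(default_factory=list)
    complexes: list[ChelationComplex] = field(default_factory=list)
    reductions: pd.DataFrame | None = None  # reductant, kind, free, chelated
    binding: list[BindingRecord] = field(default_factory=list)
    substrate_binding: list[BindingRecord] = field(default_factory=list)
    reference_rates: pd.DataFrame | None = None
    pH: float = cn.PH_DEFAULT
    target_radical_pka: float = cn.PKA_HYDROPEROXYL
    seed: int | None = None


def load_reference_rates() -> pd.DataFrame:
    return pd.read_csv(files("aoxdesign").joinpath("data/reference_rates.csv"),
                       comment="#")


def packaged_fpa_table() -> pd.DataFrame:
    return pd.read_csv(files("aoxdesign").joinpath("data/fpa_params.csv"),
                       comment="#")


# ----------------------------------------------------------------- inversions

def _invert_collins_kimball(k_app: float, k_D: float) -> float:
    if not 0 < k_app < k_D:
        raise ValueError(f"target k_app {k_app:g} must lie below k_D {k_D:g}")
    return k_app * k_D / (k_D - k_app)


def _barrier_for_rate(k_act: float, T: float, sigma: int = 1,
                      kappa: float = 1.0) -> float:
    return -cn.rt_kcal(T) * math.log(k_act / (sigma * kappa * cn.kbt_over_h(T)))


def _solve_fhat_channel(k_app_target: float, *, species: str, state: str,
                        site: str, medium: str, nu_imag: float = 1400.0,
                        rev_offset: float = 8.0, sigma: int = 1,
                        radius_A: float = 6.0, radius_B: float = 1.5,
                        target: str = "", T: float = cn.T_DEFAULT,
                        ) -> kin.ReactionChannel:
    """f-HAT channel whose diffusion-corrected rate equals the target.

    Solves the barrier self-consistently with its own Eckart κ by fixed-point
    iteration through the package's forward engine.
    """
    from scipy.optimize import brentq

    k_D = kin.diffusion_limit(radius_A, radius_B,
                              kin.VISCOSITY_BY_MEDIUM[medium], T)
    k_act = _invert_collins_kimball(k_app_target, k_D)

    def log_mismatch(b: float) -> float:
        kappa = kin.eckart_kappa(b, b + rev_offset, nu_imag, T)
        return (math.log(sigma * kappa * cn.kbt_over_h(T))
                - b / cn.rt_kcal(T) - math.log(k_act))

    # κ ≥ 1 makes the κ=1 estimate a lower bracket; the forward rate is
    # strictly decreasing in the barrier, so the root is unique
    b_lo = max(_barrier_for_rate(k_act, T, sigma, 1.0), 1e-3)
    b_hi = b_lo + 5.0
    while log_mismatch(b_hi) > 0:
        b_hi += 5.0
        if b_hi > b_lo + 60.0:
            raise ArithmeticError("f-HAT barrier inversion did not bracket")
    barrier = brentq(log_mismatch, b_lo, b_hi, xtol=1e-13, rtol=8.9e-16)
    kappa = kin.eckart_kappa(barrier, barrier + rev_offset, nu_imag, T)
    return kin.ReactionChannel(
        species=species, state=state, mechanism="f-HAT", site=site,
        dG0=-rev_offset, dG_barrier_fwd=barrier, dG_barrier_rev=barrier + rev_offset,
        nu_imag=nu_imag, sigma=sigma, medium=medium,
        radius_A=radius_A, radius_B=radius_B, target=target)


def _solve_set_channel(k_app_target: float, *, species: str, state: str,
                       medium: str, lam: float = 15.0, sigma: int = 1,
                       radius_A: float = 6.0, radius_B: float = 1.5,
                       target: str = "", T: float = cn.T_DEFAULT,
                       ) -> kin.ReactionChannel:
    """SET channel (Marcus barrier) hitting the target diffusion-corrected rate."""
    k_D = kin.diffusion_limit(radius_A, radius_B,
                              kin.VISCOSITY_BY_MEDIUM[medium], T)
    k_act = _invert_collins_kimball(k_app_target, k_D)
    barrier = _barrier_for_rate(k_act, T, sigma, 1.0)
    if barrier < 0:
        raise ValueError("target rate exceeds the barrierless TST limit")
    dG0 = lam * (math.sqrt(4.0 * barrier / lam) - 1.0)  # normal-region branch
    return kin.ReactionChannel(
        species=species, state=state, mechanism="SET", dG0=dG0, lam=lam,
        sigma=sigma, medium=medium, radius_A=radius_A, radius_B=radius_B,
        target=target)


def _solve_slack_annotations(profile: MoleculeProfile, target_total: float,
                             cfg: ScoreConfig) -> tuple[float, float, float]:
    """(ames, LD50, SA) values making the selection score equal the target.

    The eight physicochemical terms are fixed by the structure; the three
    annotation terms share the remaining score equally.
    """
    physchem = 0.0
    for name in ("MW", "logP", "HBA", "HBD", "rotatable_bonds", "TPSA",
                 "heavy_atoms", "molar_refractivity"):
        physchem += cfg.weight(name) * cfg.desirability(name, getattr(profile, name))
    slack_terms = ("ames", "LD50", "SA")
    slack_weight = sum(cfg.weight(t) for t in slack_terms)
    d = (target_total - physchem) / slack_weight
    if not 0.0 <= d <= 1.0:
        raise ValueError(
            f"target score {target_total} unreachable: physchem part is "
            f"{physchem:.3f}, shared desirability would be {d:.3f}")
    return (cfg.invert_desirability("ames", d),
            cfg.invert_desirability("LD50", d),
            cfg.invert_desirability("SA", d))


def _dG_BA_for_pka(pka: float, family: str, fpa: dict) -> float:
    p = fpa[family]
    return (pka - p.C0) / p.m


# ------------------------------------------------------------- study case

def reference_statistics() -> pd.DataFrame:
    """Synthetic reference-set statistics (property, mean, dispersion).

    The physicochemical means are plausible central values for small-molecule
    neuroprotectors; the annotation means are fixed so that a profile sitting
    exactly at the reference average scores the study case's reference total.
    """
    cfg = default_score_config()
    rows = [
        ("MW", 250.0, 80.0), ("logP", 2.5, 1.5), ("HBA", 4.0, 2.0),
        ("HBD", 2.0, 1.5), ("rotatable_bonds", 5.0, 2.5), ("TPSA", 70.0, 30.0),
        ("heavy_atoms", 25.0, 8.0), ("molar_refractivity", 75.0, 25.0),
    ]
    ref_profile = MoleculeProfile(id="reference_average", structure="")
    for prop, mean, _ in rows:
        setattr(ref_profile, prop, mean)
    ames_r, ld50_r, sa_r = _solve_slack_annotations(
        ref_profile, STUDY_CASE["S_S"]["reference_average"], cfg)
    rows += [("ames", ames_r, 0.25), ("LD50", ld50_r, 900.0), ("SA", sa_r, 2.0)]
    return pd.DataFrame(rows, columns=["property", "mean", "dispersion"])


def study_case_bundle() -> FixtureBundle:
    """Deterministic bundle reproducing the melatonin-derivative study case.

    Every engineered table is produced by inverting the package's forward
    engines, so running the pipeline on this bundle recomputes the published
    totals (selection scores, speciation fractions, overall rate
    coefficients and branching, dominant-complex population, repair rates,
    multi-target ranking) from scratch.
    """
    cfg = default_score_config()
    fpa = load_fpa_table(files("aoxdesign").joinpath("data/fpa_params.csv"))

    molecules = pd.DataFrame([
        {"id": "dM38", "smiles": DM38_SMILES},
        {"id": "melatonin", "smiles": MELATONIN_SMILES},
    ])

    reference_stats = reference_statistics()

    annotations = []
    for mol_id, smiles in (("dM38", DM38_SMILES), ("melatonin", MELATONIN_SMILES)):
        prof = compute_descriptors(smiles, mol_id=mol_id)
        ames, ld50, sa = _solve_slack_annotations(
            prof, STUDY_CASE["S_S"][mol_id], cfg)
        annotations.append({"id": mol_id, "ames": ames, "LD50": ld50, "SA": sa})
    annotations = pd.DataFrame(annotations)

    # deprotonation sites: thiol leaves first, then the phenol
    pka1, pka2 = STUDY_CASE["pkas"]
    sites = pd.DataFrame([
        {"molecule": "dM38", "site": "SH", "family": "thiol",
         "dG_BA": _dG_BA_for_pka(pka1, "thiol", fpa)},
        {"molecule": "dM38", "site": "phenol-OH", "family": "phenol",
         "dG_BA": _dG_BA_for_pka(pka2, "phenol", fpa)},
    ])
    spec = molar_fractions([pka1, pka2], pH=cn.PH_DEFAULT)
    f_neutral, f_anion = float(spec.fractions[0]), float(spec.fractions[1])

    # eH-DAMA indexes: the mono-anion sits below every reference on both axes
    dama_candidates = [
        ReactivityIndexes("dM38", "monoanion", IE=4.9,
                          BDE={"phenol-OH": 74.5}, molar_fraction=f_anion,
                          set_dG0=-5.0),
        ReactivityIndexes("dM38", "neutral", IE=6.3,
                          BDE={"SH": 80.2, "phenol-OH": 82.0},
                          molar_fraction=f_neutral),
        ReactivityIndexes("melatonin", "neutral", IE=7.1, BDE={"NH": 89.0}),
    ]
    dama_references = [
        ReactivityIndexes("Trolox", "neutral", IE=6.1, BDE={"OH": 78.2}),
        ReactivityIndexes("ascorbic_acid", "neutral", IE=5.7, BDE={"OH": 76.0}),
        ReactivityIndexes("alpha-tocopherol", "neutral", IE=6.0, BDE={"OH": 77.1}),
        ReactivityIndexes("HOO_radical", "neutral", IE=11.5, BDE={"OOH": 87.8}),
    ]

    # AOX-I channels, solved so the weighted totals equal the published
    # overall coefficients with the published mechanism branching
    k_aq, k_lip = STUDY_CASE["k_overall"]["aqueous"], STUDY_CASE["k_overall"]["lipid"]
    channels = [
        _solve_set_channel(STUDY_CASE["branching_aqueous"]["SET"] * k_aq / f_anion,
                           species="dM38", state="monoanion", medium="aqueous"),
        _solve_fhat_channel(STUDY_CASE["branching_aqueous"]["f-HAT"] * k_aq / f_anion,
                            species="dM38", state="monoanion", site="phenol-OH",
                            medium="aqueous"),
        _solve_fhat_channel(STUDY_CASE["branching_lipid"]["thiol"] * k_lip,
                            species="dM38", state="neutral_lipid", site="SH",
                            medium="lipid", nu_imag=1600.0, rev_offset=10.0),
        _solve_fhat_channel(STUDY_CASE["branching_lipid"]["phenol"] * k_lip,
                            species="dM38", state="neutral_lipid",
                            site="phenol-OH", medium="lipid", nu_imag=1600.0,
                            rev_offset=10.0),
    ]

    # AOX-III repair channels (aqueous mono-anion except the lipid target)
    rr = STUDY_CASE["repair_rates"]
    repair_channels = [
        _solve_fhat_channel(280.0, species="dM38", state="neutral_lipid",
                            site="SH", medium="lipid", target="LM",
                            nu_imag=1600.0, rev_offset=1.2),
        _solve_fhat_channel(3.1e7 / f_anion, species="dM38", state="monoanion",
                            site="phenol-OH", medium="aqueous", target="Cys"),
        _solve_fhat_channel(1.5e3 / f_anion, species="dM38", state="monoanion",
                            site="phenol-OH", medium="aqueous", target="His"),
        kin.ReactionChannel(species="dM38", state="monoanion", mechanism="SET",
                            dG0=6.0, lam=20.0, medium="aqueous", target="His"),
        _solve_fhat_channel(8.0e2 / f_anion, species="dM38", state="monoanion",
                            site="phenol-OH", medium="aqueous", target="Leu"),
        _solve_fhat_channel(4.0e3 / f_anion, species="dM38", state="monoanion",
                            site="phenol-OH", medium="aqueous", target="Met"),
        _solve_fhat_channel(2.0e5 / f_anion, species="dM38", state="monoanion",
                            site="phenol-OH", medium="aqueous", target="Trp"),
        _solve_set_channel(1.1e8 / f_neutral, species="dM38", state="neutral",
                           medium="aqueous", lam=40.0, target="Trp"),
        # tyrosine: repaired by both mechanisms; the neutral form carries the
        # SET flux, the mono-anion SET lies deep in the inverted region
        _solve_fhat_channel(rr["Tyr_fHAT"] / f_anion, species="dM38",
                            state="monoanion", site="phenol-OH",
                            medium="aqueous", target="Tyr"),
        _solve_set_channel(rr["Tyr_SET"] / f_neutral, species="dM38",
                           state="neutral", medium="aqueous", lam=40.0,
                           target="Tyr"),
        kin.ReactionChannel(species="dM38", state="monoanion", mechanism="SET",
                            dG0=-45.0, lam=15.0, medium="aqueous", target="Tyr"),
        _solve_set_channel(rr["2dG-I"] / f_anion, species="dM38",
                           state="monoanion", medium="aqueous", lam=40.0,
                           target="2dG-I"),
        _solve_fhat_channel(3.2e4 / f_anion, species="dM38", state="monoanion",
                            site="C4'-H", medium="aqueous", target="2dG-II"),
        _solve_fhat_channel(rr["2dG-III"] / f_anion, species="dM38",
                            state="monoanion", site="8-OH", medium="aqueous",
                            target="2dG-III"),
        kin.ReactionChannel(species="dM38", state="monoanion",
                            mechanism="SHATD-step", site="dehydration",
                            dG0=-12.0, medium="aqueous", target="2dG-III"),
    ]

    # AOX-II: conditional Gibbs energies solved from prescribed Boltzmann
    # populations (all significantly exergonic; one dominant complex)
    p_major = STUDY_CASE["dominant_complex_population"]
    pops = [p_major, 4e-5, 2e-5, 1e-5]
    rt = cn.rt_kcal(cn.T_DEFAULT)
    dG_cond = [-25.0 + rt * math.log(pops[0] / p) for p in pops]
    modes = [("CDCM-cSO", "CDCM", 2), ("CDCM-NO", "CDCM", 1),
             ("DCM-SO", "DCM", 0), ("DCM-NO", "DCM", 0)]
    complexes = [
        ChelationComplex(
            complex_id=name, mode=mode, n_protons=n,
            dG0=dGc + n * cn.rt_ln10_kcal(cn.T_DEFAULT) * cn.PH_DEFAULT)
        for (name, mode, n), dGc in zip(modes, dG_cond)
    ]
    reductions = pd.DataFrame([
        {"reductant": "ascorbate", "kind": "dG", "free": -8.5, "chelated": 4.2},
        {"reductant": "superoxide", "kind": "rate", "free": 2.0e9,
         "chelated": 1.6e4},
    ])

    # polygenic neuroprotection: binding-energy magnitudes (kcal/mol)
    gu = {
        ("dM38", "COMT"): 6.3, ("dM38", "AChE"): 7.0, ("dM38", "MAOB"): 6.8,
        ("melatonin", "COMT"): 5.5, ("melatonin", "AChE"): 6.2,
        ("melatonin", "MAOB"): 5.9,
        ("tolcapone", "COMT"): 8.7, ("tolcapone", "AChE"): 5.1,
        ("tolcapone", "MAOB"): 4.9,
        ("donepezil", "COMT"): 4.5, ("donepezil", "AChE"): 9.6,
        ("donepezil", "MAOB"): 5.0,
        ("safinamide", "COMT"): 4.8, ("safinamide", "AChE"): 5.2,
        ("safinamide", "MAOB"): 8.1,
    }
    binding = [BindingRecord(ligand=l, receptor=r, G_U=g)
               for (l, r), g in gu.items()]
    substrate_binding = [
        BindingRecord(ligand="dopamine", receptor="COMT", G_U=5.0),
        BindingRecord(ligand="acetylcholine", receptor="AChE", G_U=4.3),
        BindingRecord(ligand="phenylethylamine", receptor="MAOB", G_U=4.6),
    ]

    return FixtureBundle(
        molecules=molecules, annotations=annotations,
        reference_stats=reference_stats, fpa_table=packaged_fpa_table(),
        sites=sites, dama_candidates=dama_candidates,
        dama_references=dama_references, channels=channels,
        repair_channels=repair_channels, complexes=complexes,
        reductions=reductions, binding=binding,
        substrate_binding=substrate_binding,
        reference_rates=load_reference_rates(), seed=None,
    )


# ------------------------------------------------------------ random bundles

def generate_fixtures(seed: int, size: int = 12) -> FixtureBundle:
    """Seeded random bundle with the same schema as the study case.

    Profiles span rule pass/fail cases; ΔG_BA values are drawn to yield
    pKas in the 3–13 range under the packaged FPA calibration; channel
    barriers span 2–18 kcal/mol; chelation ΔG sets realize prescribed
    Boltzmann populations; binding energies realize prescribed Ki values.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    fpa = load_fpa_table(files("aoxdesign").joinpath("data/fpa_params.csv"))

    from rdkit import Chem

    from .builder import SubstitutionScheme, enumerate_derivatives
    # substitution sites: C-H carbons of the canonical melatonin ordering
    canon = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.MolFromSmiles(MELATONIN_SMILES)))
    ch_sites = [a.GetIdx() for a in canon.GetAtoms()
                if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
                and a.GetIsAromatic()][:4]
    scheme = SubstitutionScheme(parent=MELATONIN_SMILES, sites=ch_sites,
                                max_additions=2)
    derivatives = enumerate_derivatives(scheme)
    take = derivatives.iloc[:max(size - 1, 1)]
    molecules = pd.concat([
        pd.DataFrame([{"id": "melatonin", "smiles": MELATONIN_SMILES}]),
        take[["id", "smiles"]],
    ], ignore_index=True)

    annotations = pd.DataFrame({
        "id": molecules["id"],
        "ames": rng.uniform(0.0, 1.0, len(molecules)),
        "LD50": rng.lognormal(mean=7.0, sigma=0.8, size=len(molecules)),
        "SA": rng.uniform(1.0, 9.5, len(molecules)),
    })

    reference_stats = reference_statistics()

    families = list(fpa)
    site_rows = []
    for mol_id in molecules["id"]:
        n_sites = int(rng.integers(1, 4))
        pkas = np.sort(rng.uniform(3.0, 13.0, n_sites))
        fams = rng.choice(families, n_sites)
        for j, (pka, fam) in enumerate(zip(pkas, fams)):
            site_rows.append({"molecule": mol_id, "site": f"s{j}",
                              "family": fam,
                              "dG_BA": _dG_BA_for_pka(float(pka), fam, fpa)})
    sites = pd.DataFrame(site_rows)

    dama_candidates = [
        ReactivityIndexes(mol_id, "neutral",
                          IE=float(rng.uniform(4.5, 9.0)),
                          BDE={"site": float(rng.uniform(70.0, 95.0))})
        for mol_id in molecules["id"]
    ]
    dama_references = [
        ReactivityIndexes("Trolox", "neutral", IE=6.1, BDE={"OH": 78.2}),
        ReactivityIndexes("ascorbic_acid", "neutral", IE=5.7, BDE={"OH": 76.0}),
    ]

    channels = []
    for i in range(size):
        mech = rng.choice(["f-HAT", "SET", "RAF"])
        common = dict(species=str(molecules["id"].iloc[i % len(molecules)]),
                      state="neutral", medium=str(rng.choice(["aqueous", "lipid"])),
                      sigma=int(rng.integers(1, 4)),
                      radius_A=float(rng.uniform(2.0, 6.0)),
                      radius_B=float(rng.uniform(1.0, 4.0)))
        if mech == "SET":
            channels.append(kin.ReactionChannel(
                mechanism="SET", dG0=float(rng.uniform(-20.0, 5.0)),
                lam=float(rng.uniform(10.0, 50.0)), **common))
        else:
            fwd = float(rng.uniform(2.0, 18.0))
            channels.append(kin.ReactionChannel(
                mechanism=str(mech), site="site", dG0=-float(rng.uniform(1, 10)),
                dG_barrier_fwd=fwd,
                dG_barrier_rev=fwd + float(rng.uniform(1.0, 12.0)),
                nu_imag=float(rng.uniform(800.0, 2200.0))
                if mech == "f-HAT" else None, **common))

    # chelation set with prescribed populations
    raw = rng.uniform(0.0, 1.0, 4)
    pops = raw / raw.sum()
    rt = cn.rt_kcal(cn.T_DEFAULT)
    dG_cond = [-20.0 + rt * math.log(float(pops.max() / p)) for p in pops]
    complexes = [
        ChelationComplex(complex_id=f"cplx{i}", mode="CDCM" if i % 2 else "DCM",
                         n_protons=(1 if i % 2 else 0),
                         dG0=dGc + (1 if i % 2 else 0)
                         * cn.rt_ln10_kcal(cn.T_DEFAULT) * cn.PH_DEFAULT)
        for i, dGc in enumerate(dG_cond)
    ]

    # binding with prescribed inhibition constants
    receptors = ("COMT", "AChE", "MAOB")
    binding = []
    for mol_id in molecules["id"][:min(len(molecules), 6)]:
        for r in receptors:
            ki = 10.0 ** rng.uniform(-8.0, -3.0)
            binding.append(BindingRecord(ligand=str(mol_id), receptor=r,
                                         G_U=binding_from_ki(ki)))
    substrate_binding = [
        BindingRecord(ligand=f"substrate_{r}", receptor=r,
                      G_U=float(rng.uniform(4.0, 5.5))) for r in receptors
    ]

    return FixtureBundle(
        molecules=molecules, annotations=annotations,
        reference_stats=reference_stats, fpa_table=packaged_fpa_table(),
        sites=sites, dama_candidates=dama_candidates,
        dama_references=dama_references, channels=channels,
        repair_channels=[], complexes=complexes,
        reductions=pd.DataFrame([{"reductant": "ascorbate", "kind": "dG",
                                  "free": float(rng.uniform(-12, -2)),
                                  "chelated": float(rng.uniform(-2, 8))}]),
        binding=binding, substrate_binding=substrate_binding,
        reference_rates=load_reference_rates(), seed=seed,
    )
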