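"""Physicochemical profiling and drug-likeness rule evaluation.

Descriptors relevant to absorption, distribution, metabolism and excretion
are computed from the structure with RDKit; mutagenicity (Ames), acute oral
toxicity (rat LD50) and synthetic accessibility are *inputs* supplied by
external predictors and attached from an annotation table.  Rule screens
cover Lipinski's rule of five, Ghose's rule, Veber's criteria and the
unified window 160 ≤ MW ≤ 480, −0.4 ≤ logP ≤ 5 that satisfies Lipinski and
Ghose simultaneously.  All bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "MoleculeProfile",
    "RuleReport",
    "compute_descriptors",
    "check_druglikeness",
    "load_smiles_file",
    "attach_annotations",
    "profile_table",
    "AMES_PROBABILITY_THRESHOLD",
]

#: An Ames annotation given as a probability is called positive at/above this.
AMES_PROBABILITY_THRESHOLD = 0.5

#: Descriptor implementation recorded in output metadata (the rule windows do
#: not pin a particular logP/TPSA estimator, so the choice must be explicit).
DESCRIPTOR_BACKEND = {
    "logP": "rdkit.Crippen.MolLogP (Wildman–Crippen atom contributions)",
    "TPSA": "rdkit Ertl TPSA",
    "molar_refractivity": "rdkit.Crippen.MolMR",
}

DESCRIPTOR_FIELDS = ("MW", "logP", "HBA", "HBD", "rotatable_bonds", "TPSA",
                     "heavy_atoms", "molar_refractivity")


@dataclass
class MoleculeProfile:
    """A candidate with structure, ADME descriptors and external annotations."""

    id: str
    structure: str
    MW: float | None = None
    logP: float | None = None
    HBA: int | None = None
    HBD: int | None = None
    rotatable_bonds: int | None = None
    TPSA: float | None = None
    heavy_atoms: int | None = None
    molar_refractivity: float | None = None
    ames_positive: float | bool | None = None
    LD50_oral_rat: float | None = None
    synthetic_accessibility: float | None = None
    provenance: list = field(default_factory=list)

    @property
    def ames_probability(self) -> float | None:
        """Ames annotation on a [0, 1] scale (booleans map to 0/1)."""
        if self.ames_positive is None:
            return None
        if isinstance(self.ames_positive, bool):
            return 1.0 if self.ames_positive else 0.0
        return float(self.ames_positive)

    def descriptor_dict(self) -> dict:
        return {f: getattr(self, f) for f in DESCRIPTOR_FIELDS}


@dataclass
class RuleReport:
    """Per-rule pass/fail flags with the offending values listed."""

    flags: dict[str, bool]
    violations: list[str]

    @property
    def all_pass(self) -> bool:
        return all(self.flags.values())

    @property
    def lipinski_pass(self) -> bool:
        return all(v for k, v in self.flags.items() if k.startswith("lipinski"))

    @property
    def ghose_pass(self) -> bool:
        return all(v for k, v in self.flags.items() if k.startswith("ghose"))

    @property
    def veber_pass(self) -> bool:
        return all(v for k, v in self.flags.items() if k.startswith("veber"))


def _parse(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure: {structure!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"structure is not a single connected molecule: {structure!r}")
    return mol


def compute_descriptors(structure: str, mol_id: str = "") -> MoleculeProfile:
    """Profile a structure: canonicalize and compute all ADME descriptors.

    Deterministic for a fixed canonical form; raises ``ValueError`` naming
    the offending input when the structure does not parse.
    """
    mol = _parse(structure)
    canonical = Chem.MolToSmiles(mol)
    # recompute on the canonical atom ordering: additive descriptors sum in
    # atom order, so this makes the profile exact for a fixed canonical form
    mol = Chem.MolFromSmiles(canonical)
    return MoleculeProfile(
        id=mol_id or canonical,
        structure=canonical,
        MW=Descriptors.MolWt(mol),
        logP=Crippen.MolLogP(mol),
        HBA=Lipinski.NumHAcceptors(mol),
        HBD=Lipinski.NumHDonors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        TPSA=rdMolDescriptors.CalcTPSA(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        molar_refractivity=Crippen.MolMR(mol),
    )


#: (rule, descriptor, low, high) — inclusive bounds; None means unbounded.
RULE_BOUNDS = [
    ("lipinski_MW", "MW", None, 500.0),
    ("lipinski_logP", "logP", None, 5.0),
    ("lipinski_HBD", "HBD", None, 5),
    ("lipinski_HBA", "HBA", None, 10),
    ("ghose_MW", "MW", 160.0, 480.0),
    ("ghose_logP", "logP", -0.4, 5.6),
    ("ghose_atoms", "heavy_atoms", 20, 70),
    ("ghose_MR", "molar_refractivity", 40.0, 130.0),
    ("veber_rotb", "rotatable_bonds", None, 10),
    ("veber_TPSA", "TPSA", None, 140.0),
    ("unified_MW", "MW", 160.0, 480.0),
    ("unified_logP", "logP", -0.4, 5.0),
]


def check_druglikeness(profile: MoleculeProfile) -> RuleReport:
    """Evaluate Lipinski, Ghose, Veber and the unified MW/logP windows.

    A pure function of the descriptor values; a missing descriptor raises a
    ``ValueError`` identifying the incomplete field.
    """
    missing = [f for f in DESCRIPTOR_FIELDS if getattr(profile, f) is None]
    if missing:
        raise ValueError(f"incomplete profile for {profile.id}: missing {missing}")
    flags: dict[str, bool] = {}
    violations: list[str] = []
    for rule, attr, lo, hi in RULE_BOUNDS:
        x = getattr(profile, attr)
        ok = (lo is None or x >= lo) and (hi is None or x <= hi)
        flags[rule] = ok
        if not ok:
            window = f"[{lo}, {hi}]".replace("None", "-inf" if lo is None else "inf")
            violations.append(f"{rule}: {attr} = {x:g} outside {window}")
    return RuleReport(flags=flags, violations=violations)


def load_smiles_file(path: str | Path) -> list[MoleculeProfile]:
    """Read 'id<whitespace>SMILES' or bare-SMILES lines into profiles."""
    profiles = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 1:
            smiles, mol_id = parts[0], ""
        else:
            mol_id, smiles = parts[0], parts[1]
        profiles.append(compute_descriptors(smiles, mol_id=mol_id))
    return profiles


def attach_annotations(profiles: list[MoleculeProfile],
                       annotations: pd.DataFrame | str | Path) -> list[MoleculeProfile]:
    """Attach external Ames/LD50/SA predictions from a CSV (id, ames, LD50, SA)."""
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations)
    table = annotations.set_index("id")
    for p in profiles:
        if p.id not in table.index:
            continue
        row = table.loc[p.id]
        p.ames_positive = float(row["ames"])
        p.LD50_oral_rat = float(row["LD50"])
        p.synthetic_accessibility = float(row["SA"])
    return profiles


def profile_table(profiles: list[MoleculeProfile]) -> pd.DataFrame:
    """Descriptor + annotation + rule-flag table, one row per molecule."""
    rows = []
    for p in profiles:
        row = {"id": p.id, "structure": p.structure, **p.descriptor_dict(),
               "ames": p.ames_probability, "LD50": p.LD50_oral_rat,
               "SA": p.synthetic_accessibility}
        try:
            report = check_druglikeness(p)
            row.update(report.flags)
            row["violations"] = "; ".join(report.violations)
        except ValueError:
            row["violations"] = "incomplete profile"
        rows.append(row)
    return pd.DataFrame(rows)
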