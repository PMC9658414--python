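"""Derivative enumeration: decorate a parent scaffold with small groups.

Candidates are built by moderate structural modification — adding up to a
few small functional groups (-OH, -NH2, -SH, -COOH by default) at designated
substitution sites of a parent molecule, one group per site, each attached
by a single bond in place of one hydrogen.  Duplicates arising from scaffold
symmetry are collapsed by canonical-SMILES comparison, so on a symmetry-free
scaffold the candidate count equals Σ_{k=1..m} C(s,k)·g^k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import pandas as pd
import yaml
from rdkit import Chem

__all__ = ["SubstitutionScheme", "enumerate_derivatives", "DEFAULT_GROUPS"]

log = logging.getLogger(__name__)

#: Group token → fragment SMILES whose first atom bonds to the site.
DEFAULT_GROUPS = {
    "-OH": "O",
    "-NH2": "N",
    "-SH": "S",
    "-COOH": "C(=O)O",
}


@dataclass
class SubstitutionScheme:
    """Parent structure, substitution sites and the group alphabet.

    ``sites`` are atom indices into the canonical atom ordering of the
    parent; ``max_additions`` caps how many sites are decorated at once.
    """

    parent: str
    sites: list[int]
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    max_additions: int = 3

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("substitution sites must be distinct")
        if self.max_additions < 1:
            raise ValueError("max_additions must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubstitutionScheme":
        data = yaml.safe_load(Path(path).read_text())
        return cls(parent=data["parent"], sites=list(data["sites"]),
                   groups=list(data.get("groups", DEFAULT_GROUPS)),
                   max_additions=int(data.get("max_additions", 3)))


def _attach(parent: Chem.Mol, assignment: dict[int, str],
            groups: dict[str, str]) -> str | None:
    """Attach one group fragment per assigned site; canonical SMILES or None."""
    rw = Chem.RWMol(parent)
    for site, token in assignment.items():
        frag = Chem.MolFromSmiles(groups[token])
        if frag is None:
            raise ValueError(f"group token {token!r} has invalid fragment SMILES")
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag)
        rw.AddBond(site, offset, Chem.BondType.SINGLE)
    from rdkit import rdBase

    try:
        with rdBase.BlockLogs():
            mol = rw.GetMol()
            Chem.SanitizeMol(mol)
    except Exception as exc:  # valence violation at a site
        log.info("skipping candidate %s: %s", assignment, exc)
        return None
    return Chem.MolToSmiles(mol)


def enumerate_derivatives(scheme: SubstitutionScheme,
                          group_fragments: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Enumerate unique derivatives of the parent under a substitution scheme.

    Returns a provenance table with columns ``id``, ``smiles``, ``sites`` and
    ``groups``; the enumeration is deterministic and order-independent, and
    duplicate structures (e.g., from symmetric sites) keep only their first
    provenance row.
    """
    groups = dict(DEFAULT_GROUPS)
    if group_fragments:
        groups.update(group_fragments)
    unknown = [g for g in scheme.groups if g not in groups]
    if unknown:
        raise ValueError(f"no fragment defined for group tokens {unknown}")

    parent = Chem.MolFromSmiles(scheme.parent)
    if parent is None:
        raise ValueError(f"unparsable parent structure: {scheme.parent!r}")
    # work on the canonical atom ordering so site indices are reproducible
    parent = Chem.MolFromSmiles(Chem.MolToSmiles(parent))
    n_atoms = parent.GetNumAtoms()
    bad = [s for s in scheme.sites if not 0 <= s < n_atoms]
    if bad:
        raise ValueError(f"site indices out of range for parent: {bad}")

    seen: dict[str, dict] = {}
    counter = 0
    for k in range(1, scheme.max_additions + 1):
        for chosen in combinations(scheme.sites, k):
            for assigned in product(scheme.groups, repeat=k):
                assignment = dict(zip(chosen, assigned))
                smiles = _attach(parent, assignment, groups)
                if smiles is None or smiles in seen:
                    continue
                counter += 1
                seen[smiles] = {
                    "id": f"d{counter:03d}",
                    "smiles": smiles,
                    "sites": ",".join(map(str, chosen)),
                    "groups": ",".join(assigned),
                }
    return pd.DataFrame(list(seen.values()),
                        columns=["id", "smiles", "sites", "groups"])
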