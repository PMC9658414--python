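"""Acid–base speciation: fitted-parameters pKa estimates and molar fractions.

pKa values are obtained from the Gibbs-energy difference between a conjugate
base and its acid through the fitted-parameters approach (FPA), a family- and
level-of-theory-specific linear map ``pKa = m·ΔG_BA + C0``.  Given an ordered
deprotonation route, the closed-form sequential-deprotonation equilibrium
yields the molar fraction of each microspecies at a chosen pH.  Candidates
whose neutral fraction at physiological pH falls below 1% are flagged for
removal, because oral-drug-like antioxidants must cross membranes by passive
diffusion of the neutral form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import PH_DEFAULT, T_DEFAULT

__all__ = [
    "FPAParams",
    "SpeciationModel",
    "fpa_pka",
    "molar_fractions",
    "neutral_fraction_filter",
    "load_fpa_table",
    "speciate_sites",
]

#: Acidic-site families with published FPA calibrations.
FAMILIES = ("phenol", "amine", "carboxylic acid", "thiol")


@dataclass(frozen=True)
class FPAParams:
    """Linear FPA calibration for one acidic-site family.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    m:
        Slope, 1/(kcal/mol).
    C0:
        Intercept, pKa units.
    level_of_theory:
        Label of the electronic-structure level the fit was made at.
    """

    family: str
    m: float
    C0: float
    level_of_theory: str = "unspecified"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown acidic-site family: {self.family!r}")
        if self.m == 0:
            raise ValueError("FPA slope m must be non-zero")


@dataclass
class SpeciationModel:
    """Microspecies populations along a sequential deprotonation route.

    ``fractions[j]`` is the molar fraction of the species missing *j* protons
    relative to the fully protonated form; labels default to ``H2A, HA-, A2-``
    style strings.
    """

    pkas: list[float]
    pH: float
    fractions: np.ndarray
    labels: list[str] = field(default_factory=list)
    temperature: float = T_DEFAULT

    @property
    def neutral_fraction(self) -> float:
        """Fraction of the fully protonated (neutral reference) species."""
        return float(self.fractions[0])

    def to_dict(self) -> dict:
        return {
            "pkas": list(map(float, self.pkas)),
            "pH": self.pH,
            "temperature_K": self.temperature,
            "species": [
                {"label": lab, "protons_removed": j, "fraction": float(f)}
                for j, (lab, f) in enumerate(zip(self.labels, self.fractions))
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def fpa_pka(dG_BA: float, params: FPAParams, family: str | None = None) -> float:
    """pKa from the base-minus-acid Gibbs-energy difference, ``m·ΔG_BA + C0``.

    Parameters
    ----------
    dG_BA:
        Gibbs energy of the conjugate base minus that of the acid, kcal/mol.
    params:
        FPA calibration to apply.
    family:
        Optional family of the acidic site; if given it must match
        ``params.family``.
    """
    if family is not None and family != params.family:
        raise ValueError(
            f"site family {family!r} does not match FPA calibration "
            f"for {params.family!r}"
        )
    return params.m * dG_BA + params.C0


def _default_labels(n_species: int) -> list[str]:
    n_acidic = n_species - 1
    labels = []
    for j in range(n_species):
        charge = -j
        if charge == 0:
            labels.append(f"H{n_acidic}A" if n_acidic > 1 else "HA")
        else:
            sign = "-" if charge == -1 else f"{charge}"
            remaining = n_acidic - j
            prefix = f"H{remaining}" if remaining > 1 else ("H" if remaining == 1 else "")
            labels.append(f"{prefix}A{sign}")
    return labels


def molar_fractions(
    pkas: Sequence[float],
    pH: float = PH_DEFAULT,
    labels: Sequence[str] | None = None,
    temperature: float = T_DEFAULT,
) -> SpeciationModel:
    """Closed-form microspecies molar fractions at a given pH.

    For a sequential route with acid constants ``pKa_1 ≤ pKa_2 ≤ …`` the
    species missing *j* protons has relative abundance
    ``10**(j·pH − Σ_{i≤j} pKa_i)``; fractions are these terms normalised to
    unit sum.  The exponents are shift-stabilised before exponentiation.

    Raises
    ------
    ValueError
        If the pKa list is not ascending (the route must deprotonate the most
        acidic site first).
    """
    pkas = [float(p) for p in pkas]
    if any(b < a for a, b in zip(pkas, pkas[1:])):
        raise ValueError("pKa list must be ascending along the deprotonation route")
    n = len(pkas) + 1
    exponents = np.array(
        [j * pH - sum(pkas[:j]) for j in range(n)], dtype=float
    )
    exponents -= exponents.max()
    rel = 10.0 ** exponents
    fractions = rel / rel.sum()
    lab = list(labels) if labels is not None else _default_labels(n)
    if len(lab) != n:
        raise ValueError(f"expected {n} species labels, got {len(lab)}")
    return SpeciationModel(
        pkas=pkas, pH=pH, fractions=fractions, labels=lab, temperature=temperature
    )


def neutral_fraction_filter(model: SpeciationModel, threshold: float = 0.01) -> bool:
    """Keep/discard decision on the neutral-species population.

    Returns ``True`` (keep) unless the neutral fraction is strictly below the
    threshold (default 1%): molecules whose neutral form is negligible at
    physiological pH cannot rely on passive membrane diffusion.
    """
    return not (model.neutral_fraction < threshold)


def load_fpa_table(path: str | Path) -> dict[str, FPAParams]:
    """Read an FPA calibration table (CSV: family, m, C0, level_of_theory)."""
    df = pd.read_csv(path, comment="#")
    required = {"family", "m", "C0"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FPA table missing columns: {sorted(missing)}")
    table: dict[str, FPAParams] = {}
    for row in df.itertuples(index=False):
        table[row.family] = FPAParams(
            family=row.family,
            m=float(row.m),
            C0=float(row.C0),
            level_of_theory=str(getattr(row, "level_of_theory", "unspecified")),
        )
    return table


def speciate_sites(
    sites: pd.DataFrame,
    fpa: dict[str, FPAParams],
    pH: float = PH_DEFAULT,
) -> SpeciationModel:
    """Speciation model for one molecule from a per-site ΔG_BA table.

    ``sites`` must have columns ``site``, ``family`` and ``dG_BA``.  Each
    site's pKa comes from its family's FPA calibration; the deprotonation
    route orders sites by ascending pKa (the most acidic site leaves first),
    collapsing branching microstates onto this dominant route.
    """
    for col in ("site", "family", "dG_BA"):
        if col not in sites.columns:
            raise ValueError(f"site table missing column {col!r}")
    pka_by_site = []
    for row in sites.itertuples(index=False):
        if row.family not in fpa:
            raise ValueError(f"no FPA calibration for family {row.family!r}")
        pka_by_site.append((fpa_pka(float(row.dG_BA), fpa[row.family]), str(row.site)))
    pka_by_site.sort()
    pkas = [p for p, _ in pka_by_site]
    route = [s for _, s in pka_by_site]
    model = molar_fractions(pkas, pH=pH)
    # annotate labels with the site that deprotonates at each step
    model.labels = [model.labels[0]] + [
        f"{lab} (-H@{site})" for lab, site in zip(model.labels[1:], route)
    ]
    return model
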