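"""Metal-chelation thermodynamics and hydroxyl-radical-inactivating-ligand tests.

Chelation of a redox metal (copper, in the neurodegeneration context) can
proceed by direct chelation (DCM) or by coupled deprotonation–chelation
(CDCM), where one or more protons leave the ligand as the metal binds.  CDCM
viability is pH dependent: each released proton contributes
``−RT·ln(10)·pH`` to the conditional Gibbs energy, so chelation becomes more
favourable as the pH rises.  Competing complexes are populated according to
the Maxwell–Boltzmann distribution of their conditional Gibbs energies.

A chelator acts as a hydroxyl-radical-inactivating ligand of type 1 (OIL-1)
when it hinders the metal's reduction step of Fenton-like chemistry; the
assessment compares reduction thermochemistry/kinetics of the free and
chelated metal and classifies the effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import constants as cn

__all__ = [
    "ChelationComplex",
    "ReductionAssessment",
    "conditional_dG",
    "boltzmann_populations",
    "populate_complexes",
    "oil1_assessment",
]

MODES = ("DCM", "CDCM")


@dataclass
class ChelationComplex:
    """A metal–ligand complex with its chelation mode and thermochemistry."""

    complex_id: str
    mode: str
    n_protons: int
    dG0: float
    dG_conditional: float | None = None
    population: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"chelation mode must be one of {MODES}")
        if self.n_protons < 0:
            raise ValueError("released-proton count must be >= 0")
        if self.mode == "DCM" and self.n_protons != 0:
            raise ValueError("direct chelation releases no protons")


@dataclass
class ReductionAssessment:
    """Classification of how chelation alters a metal-reduction step."""

    reductant: str
    free_value: float
    chelated_value: float
    kind: str  # "dG" or "rate"
    classification: str = ""
    fold: float | None = None


def conditional_dG(dG0: float, n_protons: int, pH: float = cn.PH_DEFAULT,
                   T: float = cn.T_DEFAULT) -> float:
    """pH-conditional Gibbs energy ``ΔG′ = ΔG° − n·RT·ln(10)·pH`` (kcal/mol).

    Each proton released into solution at proton activity 10^(−pH) lowers the
    reaction Gibbs energy by RT·ln10 per pH unit (−1.364 kcal/mol per unit at
    298.15 K), so deprotonation-coupled chelation grows more viable with pH.
    """
    if n_protons < 0:
        raise ValueError("n_protons must be >= 0")
    return dG0 - n_protons * cn.rt_ln10_kcal(T) * pH


def boltzmann_populations(dG: Sequence[float], T: float = cn.T_DEFAULT) -> np.ndarray:
    """Maxwell–Boltzmann fractions of complexes with comparable stoichiometry.

    ``p_i = exp(−ΔG_i/RT)/Σ_j exp(−ΔG_j/RT)``, shift-stabilised by
    subtracting the minimum ΔG before exponentiating, so the result is
    invariant to adding a constant to every ΔG.
    """
    dG = np.asarray(dG, dtype=float)
    if dG.size == 0:
        raise ValueError("need at least one complex")
    rt = cn.rt_kcal(T)
    shifted = -(dG - dG.min()) / rt
    weights = np.exp(shifted)
    return weights / weights.sum()


def populate_complexes(complexes: Sequence[ChelationComplex],
                       pH: float = cn.PH_DEFAULT,
                       T: float = cn.T_DEFAULT) -> list[ChelationComplex]:
    """Attach conditional ΔG and Boltzmann populations to competing complexes."""
    for c in complexes:
        c.dG_conditional = conditional_dG(c.dG0, c.n_protons, pH=pH, T=T)
    pops = boltzmann_populations([c.dG_conditional for c in complexes], T=T)
    for c, p in zip(complexes, pops):
        c.population = float(p)
    return list(complexes)


def oil1_assessment(free: ReductionAssessment | None = None,
                    chelated: ReductionAssessment | None = None,
                    *, reductant: str | None = None,
                    free_dG: float | None = None, chelated_dG: float | None = None,
                    free_rate: float | None = None, chelated_rate: float | None = None,
                    fold_threshold: float = 1e4) -> ReductionAssessment:
    """Classify the OIL-1 effect of chelation on one metal-reduction step.

    * ``fully inhibited`` — reduction of the chelated metal is endergonic
      (ΔG′ > 0) while the free metal's is exergonic;
    * ``strongly lowered`` — both remain exergonic but the chelated reaction
      is at least ``fold_threshold`` (default 10⁴) times slower;
    * ``unchanged`` — otherwise.

    Inputs may be given as paired :class:`ReductionAssessment` stubs or as
    keyword values; the reductant must match between the two states.
    """
    if free is not None and chelated is not None:
        if free.reductant != chelated.reductant:
            raise ValueError(
                f"mismatched reductants: {free.reductant!r} vs {chelated.reductant!r}")
        reductant = free.reductant
        if free.kind == "dG":
            free_dG, chelated_dG = free.free_value, chelated.free_value
        else:
            free_rate, chelated_rate = free.free_value, chelated.free_value
    if reductant is None:
        raise ValueError("reductant must be identified")

    classification = "unchanged"
    fold = None
    if free_dG is not None and chelated_dG is not None:
        if free_dG < 0 and chelated_dG > 0:
            classification = "fully inhibited"
        elif free_dG < 0 and chelated_dG < 0:
            # equilibrium-based fold when no rates are supplied
            fold = math.exp((chelated_dG - free_dG) / cn.rt_kcal(cn.T_DEFAULT))
            if free_rate is None and fold >= fold_threshold:
                classification = "strongly lowered"
    if classification != "fully inhibited" and free_rate is not None \
            and chelated_rate is not None and chelated_rate > 0:
        fold = free_rate / chelated_rate
        if fold >= fold_threshold:
            classification = "strongly lowered"
    kind = "dG" if free_rate is None else "rate"
    return ReductionAssessment(
        reductant=reductant,
        free_value=free_dG if kind == "dG" else free_rate,
        chelated_value=chelated_dG if kind == "dG" else chelated_rate,
        kind=kind, classification=classification, fold=fold,
    )
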