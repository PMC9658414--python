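"""Selection, elimination and polygenic scores, and Ki from binding energies.

The multi-objective candidate triage is folded into a single *selection
score* S_S: a weighted sum of eleven terms — eight ADME-relevant
physicochemical descriptors (MW, logP, HBA, HBD, rotatable bonds, TPSA,
heavy atoms, molar refractivity) plus Ames mutagenicity, rat oral LD50 and
synthetic accessibility.  Higher S_S means more drug-like, less toxic,
easier to make.  The functional form of every term is data, not code: a
versioned YAML configuration maps each property through a piecewise-linear
desirability in [0, 1] and a weight, and the engine only guarantees the
structural contracts (term sum, monotonicity in toxicity/ease-of-synthesis).

*Elimination scores* S_E guard against a good total masking a single bad
property: per property, the standardized deviation |x − mean|/dispersion
from a reference set of molecules already used for the target indication.
Large deviations in a *desirable* direction (e.g., much lower mutagenicity)
are flagged as such and never auto-eliminate a candidate.

For receptor binding, docking energies convert to inhibition constants via
``Ki = exp(−G_U/RT)`` (G_U the positive binding-strength magnitude), and the
*polygenic score* S_P aggregates multi-target affinity relative to each
receptor's natural substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import R_KCAL_KI, T_DEFAULT
from .profiles import MoleculeProfile

__all__ = [
    "ScoreConfig",
    "ReferenceSet",
    "ScoreBreakdown",
    "BindingRecord",
    "selection_score",
    "elimination_scores",
    "ki_from_binding",
    "binding_from_ki",
    "polygenic_score",
    "default_score_config",
]

TERM_NAMES = ("MW", "logP", "HBA", "HBD", "rotatable_bonds", "TPSA",
              "heavy_atoms", "molar_refractivity", "ames", "LD50", "SA")


def _term_value(profile: MoleculeProfile, name: str) -> float:
    if name == "ames":
        v = profile.ames_probability
    elif name == "LD50":
        v = profile.LD50_oral_rat
    elif name == "SA":
        v = profile.synthetic_accessibility
    else:
        v = getattr(profile, name)
    if v is None:
        raise ValueError(f"profile {profile.id!r} is missing score term {name!r}")
    return float(v)


@dataclass
class ScoreConfig:
    """Versioned term definitions: weight + piecewise-linear desirability."""

    schema: str
    terms: dict[str, dict]
    elimination: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(schema=str(data.get("schema", "unversioned")),
                  terms=data["terms"],
                  elimination=data.get("elimination", {}))
        missing = set(TERM_NAMES) - set(cfg.terms)
        if missing:
            raise ValueError(f"score config missing terms: {sorted(missing)}")
        return cfg

    def desirability(self, name: str, x: float) -> float:
        knots = self.terms[name]["desirability"]
        xs = [k[0] for k in knots]
        ds = [k[1] for k in knots]
        return float(np.interp(x, xs, ds))

    def weight(self, name: str) -> float:
        return float(self.terms[name]["weight"])

    def invert_desirability(self, name: str, d: float) -> float:
        """A property value achieving desirability ``d`` (first matching knot
        segment, scanning from the high-x end so toxicity terms land on their
        natural branch)."""
        knots = self.terms[name]["desirability"]
        for (x0, d0), (x1, d1) in zip(knots[-2::-1], knots[::-1]):
            lo, hi = sorted((d0, d1))
            if lo <= d <= hi and d0 != d1:
                return x0 + (d - d0) * (x1 - x0) / (d1 - d0)
        for x0, d0 in knots:
            if d0 == d:
                return x0
        raise ValueError(f"desirability {d} unreachable for term {name!r}")


def default_score_config() -> ScoreConfig:
    """The packaged score configuration (data/scores_default.yaml)."""
    return ScoreConfig.from_yaml(files("aoxdesign").joinpath("data/scores_default.yaml"))


@dataclass
class ReferenceSet:
    """Per-property mean and dispersion over the reference molecules."""

    stats: pd.DataFrame  # index: property; columns: mean, dispersion

    def __post_init__(self) -> None:
        bad = self.stats[self.stats["dispersion"] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive dispersion for properties {list(bad.index)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceSet":
        df = pd.read_csv(path).set_index("property")
        return cls(stats=df[["mean", "dispersion"]].astype(float))

    def mean(self, prop: str) -> float:
        return float(self.stats.loc[prop, "mean"])

    def dispersion(self, prop: str) -> float:
        return float(self.stats.loc[prop, "dispersion"])


@dataclass
class ScoreBreakdown:
    """Named term values and totals for one candidate."""

    terms: dict[str, float] = field(default_factory=dict)
    S_S: float | None = None
    S_E: dict[str, float] = field(default_factory=dict)
    S_E_ADMETSA: float | None = None
    desirable_deviation: dict[str, bool] = field(default_factory=dict)


def selection_score(profile: MoleculeProfile, config: ScoreConfig | None = None
                    ) -> ScoreBreakdown:
    """Selection score S_S: the weighted sum of the eleven desirability terms."""
    cfg = config or default_score_config()
    terms = {}
    for name in TERM_NAMES:
        x = _term_value(profile, name)
        terms[name] = cfg.weight(name) * cfg.desirability(name, x)
    return ScoreBreakdown(terms=terms, S_S=float(sum(terms.values())))


def elimination_scores(profile: MoleculeProfile, ref: ReferenceSet,
                       config: ScoreConfig | None = None) -> ScoreBreakdown:
    """Per-property standardized deviations and their ADMETSA aggregate.

    The aggregate is the plain sum of the eleven per-property deviations.  A
    deviation larger than the configured flag threshold whose desirability at
    x is at least that at the reference mean is marked *desirable* (e.g., a
    candidate far less mutagenic than the reference average): reported, never
    auto-eliminating.
    """
    cfg = config or default_score_config()
    threshold = float(cfg.elimination.get("flag_threshold", 2.0))
    se: dict[str, float] = {}
    desirable: dict[str, bool] = {}
    for name in TERM_NAMES:
        x = _term_value(profile, name)
        mean, disp = ref.mean(name), ref.dispersion(name)
        se[name] = abs(x - mean) / disp
        desirable[name] = bool(
            se[name] > threshold
            and cfg.desirability(name, x) >= cfg.desirability(name, mean)
        )
    return ScoreBreakdown(S_E=se, S_E_ADMETSA=float(sum(se.values())),
                          desirable_deviation=desirable)


@dataclass
class BindingRecord:
    """A ligand–receptor binding energy with its derived inhibition constant.

    ``G_U`` is the *positive* binding-strength magnitude in kcal/mol (larger
    means stronger binding, hence smaller Ki).
    """

    ligand: str
    receptor: str
    G_U: float
    Ki: float | None = None
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.Ki is None:
            self.Ki = ki_from_binding(self.G_U, self.T)


def ki_from_binding(G_U: float, T: float = T_DEFAULT) -> float:
    """Inhibition constant ``Ki = exp(−G_U/RT)`` in mol/L (G_U ≥ 0 magnitude)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-G_U / (R_KCAL_KI * T))


def binding_from_ki(Ki: float, T: float = T_DEFAULT) -> float:
    """Inverse map, ``G_U = −RT·ln(Ki)``."""
    if Ki <= 0:
        raise ValueError("Ki must be positive")
    return -R_KCAL_KI * T * math.log(Ki)


def polygenic_score(records: list[BindingRecord],
                    substrates: list[BindingRecord],
                    receptors: tuple[str, ...] = ("COMT", "AChE", "MAOB"),
                    ) -> pd.DataFrame:
    """Multi-target binding aggregate S_P per ligand.

    For each ligand with a record at every receptor, S_P is the mean over
    receptors of its binding-energy magnitude relative to that receptor's
    natural substrate, ``S_P = (1/n)·Σ_r G_U(ligand, r)/G_U(substrate, r)``.
    A ligand binding stronger than the substrate at *all* receptors is
    flagged as a possible efficient inhibitor of the panel.
    """
    sub = {}
    for rec in substrates:
        sub[rec.receptor] = rec
    missing_sub = [r for r in receptors if r not in sub]
    if missing_sub:
        raise ValueError(f"no substrate record for receptors {missing_sub}")

    by_ligand: dict[str, dict[str, BindingRecord]] = {}
    for rec in records:
        by_ligand.setdefault(rec.ligand, {})[rec.receptor] = rec

    rows = []
    for ligand, recs in by_ligand.items():
        missing = [r for r in receptors if r not in recs]
        if missing:
            raise ValueError(f"ligand {ligand!r} lacks records for {missing}")
        ratios = [recs[r].G_U / sub[r].G_U for r in receptors]
        stronger = all(recs[r].G_U > sub[r].G_U for r in receptors)
        rows.append({
            "ligand": ligand,
            "S_P": float(np.mean(ratios)),
            **{f"GU_{r}": recs[r].G_U for r in receptors},
            **{f"Ki_{r}": recs[r].Ki for r in receptors},
            "stronger_than_substrates": stronger,
            "note": "may be an efficient inhibitor" if stronger else "",
        })
    return pd.DataFrame(rows).sort_values("S_P", ascending=False,
                                          ignore_index=True)
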