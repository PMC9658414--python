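"""Orchestration of the full design protocol.

Stages run in the protocol's order: profile/score the candidates, triage to
subset 1 on the selection/elimination scores, map subset 1 on the eH-DAMA
and keep up to six (subset 2), then evaluate speciation, radical-scavenging
kinetics (AOX-I), chelation/OIL behavior (AOX-II), biomolecule repair
(AOX-III) and the multi-target binding post-processing.  Every candidate
carries a provenance trail of pass/fail decisions; partial runs are allowed
from any stage whose inputs are present in the bundle.

The report is a pure function of (config, inputs): serializing it with
sorted keys yields byte-identical output on re-runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import constants as cn
from . import kinetics as kin
from .chelation import oil1_assessment, populate_complexes
from .dama import build_eh_dama
from .fixtures import FixtureBundle
from .profiles import (attach_annotations, check_druglikeness,
                       compute_descriptors)
from .scoring import (ReferenceSet, ScoreConfig, default_score_config,
                      elimination_scores, polygenic_score, selection_score)
from .speciation import (load_fpa_table, molar_fractions,
                         neutral_fraction_filter, speciate_sites)

__all__ = ["RunConfig", "run_pipeline", "PipelineInputError", "STAGES"]

STAGES = ("profile", "score", "subset1", "dama", "subset2", "speciation",
          "kinetics", "chelation", "repair", "polygenic")

STATE_NAMES = ("neutral", "monoanion", "dianion", "trianion", "tetraanion")


class PipelineInputError(ValueError):
    """A requested stage is missing an input it cannot proceed without."""


@dataclass
class RunConfig:
    """Run-wide knobs: pH, temperature, selection caps and thresholds."""

    pH: float = cn.PH_DEFAULT
    temperature: float = cn.T_DEFAULT
    media: list[str] = field(default_factory=lambda: ["aqueous", "lipid"])
    score_config_path: str | None = None
    fpa_table_path: str | None = None
    reference_set_path: str | None = None
    subset1_size: int = 10
    subset2_size: int = 6
    neutral_fraction_threshold: float = 0.01
    oil_fold_threshold: float = 1e4
    max_undesirable_deviations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset1_size < 1 or self.subset2_size < 1:
            raise ValueError("selection caps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def score_config(self) -> ScoreConfig:
        if self.score_config_path:
            return ScoreConfig.from_yaml(self.score_config_path)
        return default_score_config()


def _fraction_map(model) -> dict[str, float]:
    """State-name → molar-fraction mapping; lipid medium keeps the neutral."""
    out = {name: float(f)
           for name, f in zip(STATE_NAMES, model.fractions)}
    out["neutral_lipid"] = 1.0
    return out


def run_pipeline(config: RunConfig, bundle: FixtureBundle,
                 stages: tuple[str, ...] | list[str] | None = None) -> dict:
    """Execute the requested stages in protocol order and return the report."""
    explicit = stages is not None
    requested = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise PipelineInputError(f"unknown stages {unknown}")
    requested = [s for s in STAGES if s in requested]

    report: dict = {"schema_version": "aoxdesign-report/1",
                    "config": asdict(config), "stages": {},
                    "provenance": {}, "warnings": []}
    prov: dict[str, list] = report["provenance"]

    def trail(mol_id: str, stage: str, decision: str, reason: str = "") -> None:
        prov.setdefault(mol_id, []).append(
            {"stage": stage, "decision": decision, "reason": reason})

    def skip(stage: str, reason: str) -> None:
        report["stages"][stage] = {"skipped": reason}

    def require(stage: str, dep: str):
        """Dependency check: fail fast for explicitly requested stages,
        degrade to a chained skip on a default full run."""
        out = report["stages"].get(dep)
        if out is None or "skipped" in out:
            reason = (f"requires output of stage {dep!r}, which "
                      f"{'was skipped: ' + out['skipped'] if out else 'did not run'}")
            if explicit:
                raise PipelineInputError(f"stage {stage!r} {reason}")
            skip(stage, reason)
            return None
        return out

    cfg_scores = config.score_config()
    profiles: dict = {}
    speciations: dict = {}

    # ---------------------------------------------------------------- profile
    if "profile" in requested:
        if bundle.molecules is None or not len(bundle.molecules):
            skip("profile", "no molecule table in inputs")
        else:
            rows = {}
            for rec in bundle.molecules.itertuples(index=False):
                p = compute_descriptors(rec.smiles, mol_id=rec.id)
                profiles[rec.id] = p
            if bundle.annotations is not None:
                attach_annotations(list(profiles.values()), bundle.annotations)
            for mol_id, p in profiles.items():
                rep = check_druglikeness(p)
                rows[mol_id] = {**p.descriptor_dict(),
                                "ames": p.ames_probability,
                                "LD50": p.LD50_oral_rat,
                                "SA": p.synthetic_accessibility,
                                "rule_flags": rep.flags,
                                "violations": rep.violations}
                trail(mol_id, "profile",
                      "pass" if rep.all_pass else "flagged",
                      "; ".join(rep.violations))
            report["stages"]["profile"] = {"profiles": rows}

    # ------------------------------------------------------------------ score
    if "score" in requested:
        if require("score", "profile") is None:
            pass
        elif bundle.reference_stats is None:
            skip("score", "no reference-set statistics in inputs")
        else:
            ref = ReferenceSet(
                bundle.reference_stats.set_index("property")[["mean", "dispersion"]])
            out = {}
            for mol_id, p in profiles.items():
                sel = selection_score(p, cfg_scores)
                eli = elimination_scores(p, ref, cfg_scores)
                out[mol_id] = {"S_S": sel.S_S, "terms": sel.terms,
                               "S_E": eli.S_E, "S_E_ADMETSA": eli.S_E_ADMETSA,
                               "desirable_deviation": eli.desirable_deviation}
                trail(mol_id, "score", "scored", f"S_S={sel.S_S:.4f}")
            report["stages"]["score"] = {"scores": out}

    # ---------------------------------------------------------------- subset1
    subset1: list[str] = []
    score_out = report["stages"].get("score")
    if "subset1" in requested and require("subset1", "score") is not None:
        scores = score_out["scores"]
        threshold = float(cfg_scores.elimination.get("flag_threshold", 2.0))
        ranked = sorted(scores, key=lambda m: -scores[m]["S_S"])
        for mol_id in ranked:
            s = scores[mol_id]
            undesirable = sum(
                1 for prop, se in s["S_E"].items()
                if se > threshold and not s["desirable_deviation"][prop])
            if undesirable > config.max_undesirable_deviations:
                trail(mol_id, "subset1", "dropped",
                      f"{undesirable} large undesirable deviations")
            elif len(subset1) < config.subset1_size:
                subset1.append(mol_id)
                trail(mol_id, "subset1", "kept", "")
            else:
                trail(mol_id, "subset1", "dropped", "below subset-1 cap")
        report["stages"]["subset1"] = {"selected": subset1}

    # ------------------------------------------------------------------- dama
    selection = None
    if "dama" in requested:
        if not bundle.dama_candidates:
            skip("dama", "no reactivity-index table in inputs")
        else:
            cands = bundle.dama_candidates
            if subset1:
                cands = [c for c in cands if c.species in subset1] or cands
            selection = build_eh_dama(cands, bundle.dama_references,
                                      cap=config.subset2_size)
            report["warnings"].extend(selection.warnings)
            report["stages"]["dama"] = {
                "ranking": [{"species": r.species, "state": r.state,
                             "IE": r.IE, "min_BDE": r.min_BDE}
                            for r in selection.ranking],
                "selected": [f"{r.species}/{r.state}" for r in selection.selected],
            }

    # ---------------------------------------------------------------- subset2
    subset2: list[str] = []
    if "subset2" in requested and require("subset2", "dama") is not None:
        seen = []
        for r in selection.selected:
            if r.species not in seen:
                seen.append(r.species)
        subset2 = seen[:config.subset2_size]
        for mol_id in subset2:
            trail(mol_id, "subset2", "kept", "eH-DAMA selection")
        report["stages"]["subset2"] = {"selected": subset2}

    # -------------------------------------------------------------- speciation
    if "speciation" in requested:
        if bundle.sites is None or not len(bundle.sites):
            skip("speciation", "no acidic-site table in inputs")
        else:
            if config.fpa_table_path:
                fpa = load_fpa_table(config.fpa_table_path)
            else:
                from importlib.resources import files as _files
                fpa = load_fpa_table(_files("aoxdesign") / "data/fpa_params.csv")
            out = {}
            focus = subset2 or list(bundle.sites["molecule"].unique())
            for mol_id in focus:
                rows = bundle.sites[bundle.sites["molecule"] == mol_id]
                if not len(rows):
                    continue
                model = speciate_sites(rows, fpa, pH=config.pH)
                keep = neutral_fraction_filter(
                    model, config.neutral_fraction_threshold)
                speciations[mol_id] = model
                out[mol_id] = {"pkas": model.pkas,
                               "fractions": [float(f) for f in model.fractions],
                               "neutral_fraction": model.neutral_fraction,
                               "keep": bool(keep)}
                trail(mol_id, "speciation",
                      "kept" if keep else "discarded",
                      f"neutral fraction {model.neutral_fraction:.4f}")
            report["stages"]["speciation"] = {"models": out}

    # ---------------------------------------------------------------- kinetics
    if "kinetics" in requested:
        if not bundle.channels:
            skip("kinetics", "no reaction-channel table in inputs")
        else:
            radical_fraction = molar_fractions(
                [bundle.target_radical_pka], pH=config.pH).neutral_fraction
            ref_rates = bundle.reference_rates
            out = {}
            groups: dict[tuple[str, str], list] = {}
            for ch in bundle.channels:
                groups.setdefault((ch.species, ch.medium), []).append(ch)
            for (species, medium), chans in sorted(groups.items()):
                if species in speciations:
                    fractions = _fraction_map(speciations[species])
                else:
                    fractions = {ch.state: 1.0 for ch in chans}
                rated = [kin.evaluate_channel(ch, T=config.temperature)
                         for ch in chans]
                k_total, rated = kin.overall_rate(rated, fractions)
                entry = {
                    "k_overall": k_total,
                    "channels": [{"mechanism": r.channel.mechanism,
                                  "site": r.channel.site,
                                  "state": r.channel.state,
                                  "k_app": r.k_app, "kappa": r.kappa,
                                  "k_D": r.k_D,
                                  "branching": r.branching}
                                 for r in rated],
                }
                if ref_rates is not None:
                    refs = ref_rates[ref_rates["medium"] == medium]
                    entry["fold_vs_references"] = kin.compare_to_references(
                        k_total, medium,
                        dict(zip(refs["antioxidant"], refs["k"])),
                        target_fraction=radical_fraction)
                out[f"{species}/{medium}"] = entry
                trail(species, "kinetics", "evaluated",
                      f"{medium}: k_overall={k_total:.3e}")
            report["stages"]["kinetics"] = {
                "results": out, "radical_neutral_fraction": radical_fraction}

    # --------------------------------------------------------------- chelation
    if "chelation" in requested:
        if not bundle.complexes:
            skip("chelation", "no complexation table in inputs")
        else:
            populated = populate_complexes(bundle.complexes, pH=config.pH,
                                           T=config.temperature)
            out = {"complexes": [
                {"id": c.complex_id, "mode": c.mode, "n_protons": c.n_protons,
                 "dG0": c.dG0, "dG_conditional": c.dG_conditional,
                 "population": c.population} for c in populated]}
            if bundle.reductions is not None:
                assessments = []
                for row in bundle.reductions.itertuples(index=False):
                    kwargs = {"reductant": row.reductant,
                              "fold_threshold": config.oil_fold_threshold}
                    if row.kind == "dG":
                        kwargs.update(free_dG=float(row.free),
                                      chelated_dG=float(row.chelated))
                    else:
                        kwargs.update(free_rate=float(row.free),
                                      chelated_rate=float(row.chelated))
                    a = oil1_assessment(**kwargs)
                    assessments.append({"reductant": a.reductant,
                                        "classification": a.classification,
                                        "fold": a.fold})
                out["oil1"] = assessments
            report["stages"]["chelation"] = out

    # ------------------------------------------------------------------ repair
    if "repair" in requested:
        if not bundle.repair_channels:
            skip("repair", "no repair-channel table in inputs")
        else:
            out = {}
            by_species: dict[str, list] = {}
            for ch in bundle.repair_channels:
                by_species.setdefault(ch.species, []).append(ch)
            for species, chans in sorted(by_species.items()):
                if species in speciations:
                    fractions = _fraction_map(speciations[species])
                else:
                    fractions = {ch.state: 1.0 for ch in chans}
                out[species] = kin.repair_routes(chans, fractions,
                                                T=config.temperature)
            report["stages"]["repair"] = out

    # --------------------------------------------------------------- polygenic
    if "polygenic" in requested:
        if not bundle.binding or not bundle.substrate_binding:
            skip("polygenic", "no binding-energy table in inputs")
        else:
            receptors = tuple(sorted({b.receptor for b in bundle.substrate_binding}))
            complete = {}
            for b in bundle.binding:
                complete.setdefault(b.ligand, set()).add(b.receptor)
            usable = [b for b in bundle.binding
                      if complete[b.ligand] >= set(receptors)]
            table = polygenic_score(usable, bundle.substrate_binding,
                                    receptors=receptors)
            report["stages"]["polygenic"] = {
                "receptors": list(receptors),
                "ranking": table.to_dict(orient="records")}
            for rec in table.itertuples(index=False):
                trail(rec.ligand, "polygenic",
                      "candidate inhibitor" if rec.stronger_than_substrates
                      else "weaker than substrates", f"S_P={rec.S_P:.4f}")

    return report


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    """Serialize a run report deterministically (sorted keys, no timestamps)."""
    text = json.dumps(report, indent=2, sort_keys=True, default=float)
    if path is not None:
        Path(path).write_text(text)
    return text
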