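"""Selection/elimination scores, inhibition constants and the polygenic score."""

import numpy as np
import pandas as pd
import pytest

from aoxdesign.profiles import MoleculeProfile
from aoxdesign.scoring import (BindingRecord, ReferenceSet, binding_from_ki,
                               elimination_scores,
                               ki_from_binding, polygenic_score,
                               selection_score)

PROPS = dict(MW=300.0, logP=2.0, HBA=4, HBD=2, rotatable_bonds=4, TPSA=80.0,
             heavy_atoms=25, molar_refractivity=80.0, ames_positive=0.3,
             LD50_oral_rat=1500.0, synthetic_accessibility=3.5)


def _profile(**over):
    vals = {**PROPS, **over}
    return MoleculeProfile(id="x", structure="", **vals)


def _reference(mean_over=None):
    rows = [("MW", 250.0, 80.0), ("logP", 2.5, 1.5), ("HBA", 4.0, 2.0),
            ("HBD", 2.0, 1.5), ("rotatable_bonds", 5.0, 2.5),
            ("TPSA", 70.0, 30.0), ("heavy_atoms", 25.0, 8.0),
            ("molar_refractivity", 75.0, 25.0), ("ames", 0.5, 0.25),
            ("LD50", 2000.0, 900.0), ("SA", 5.0, 2.0)]
    df = pd.DataFrame(rows, columns=["property", "mean", "dispersion"])
    if mean_over:
        for k, v in mean_over.items():
            df.loc[df["property"] == k, "mean"] = v
    return ReferenceSet(df.set_index("property")[["mean", "dispersion"]])


class TestSelectionScore:
    def test_total_is_sum_of_terms(self):
        bd = selection_score(_profile())
        assert bd.S_S == pytest.approx(sum(bd.terms.values()), abs=1e-9)
        assert len(bd.terms) == 11

    def test_reproducible_and_order_free(self):
        a, b = selection_score(_profile()), selection_score(_profile())
        assert a.S_S == pytest.approx(b.S_S, abs=1e-12)

    def test_higher_mutagenicity_never_raises_score(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            lo, hi = sorted(rng.uniform(0, 1, 2))
            s_lo = selection_score(_profile(ames_positive=lo)).S_S
            s_hi = selection_score(_profile(ames_positive=hi)).S_S
            assert s_hi <= s_lo + 1e-12

    def test_easier_synthesis_never_lowers_score(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            easy, hard = sorted(rng.uniform(1, 10, 2))
            assert (selection_score(_profile(synthetic_accessibility=easy)).S_S
                    >= selection_score(
                        _profile(synthetic_accessibility=hard)).S_S - 1e-12)

    def test_rule_compliance_scores_above_violation(self):
        inside = selection_score(_profile(MW=300.0)).S_S
        outside = selection_score(_profile(MW=590.0)).S_S
        assert inside > outside

    def test_missing_term_is_a_named_error(self):
        with pytest.raises(ValueError, match="LD50"):
            selection_score(_profile(LD50_oral_rat=None))


class TestEliminationScores:
    def test_zero_at_reference_mean(self):
        ref = _reference({"MW": PROPS["MW"]})
        assert elimination_scores(_profile(), ref).S_E["MW"] == 0.0

    def test_aggregate_matches_independent_recomputation(self):
        rng = np.random.default_rng(23)
        ref = _reference()
        for _ in range(50):
            p = _profile(MW=float(rng.uniform(100, 600)),
                         logP=float(rng.uniform(-2, 7)),
                         ames_positive=float(rng.uniform(0, 1)),
                         synthetic_accessibility=float(rng.uniform(1, 10)))
            bd = elimination_scores(p, ref)
            stats = ref.stats
            oracle = sum(
                abs(x - stats.loc[prop, "mean"]) / stats.loc[prop, "dispersion"]
                for prop, x in [("MW", p.MW), ("logP", p.logP),
                                ("HBA", p.HBA), ("HBD", p.HBD),
                                ("rotatable_bonds", p.rotatable_bonds),
                                ("TPSA", p.TPSA),
                                ("heavy_atoms", p.heavy_atoms),
                                ("molar_refractivity", p.molar_refractivity),
                                ("ames", p.ames_positive),
                                ("LD50", p.LD50_oral_rat),
                                ("SA", p.synthetic_accessibility)])
            assert bd.S_E_ADMETSA == pytest.approx(oracle, rel=1e-12)

    def test_low_toxicity_deviation_flagged_desirable(self):
        # far less mutagenic than the reference mean: large but welcome
        bd = elimination_scores(_profile(ames_positive=0.0),
                                _reference({"ames": 0.9}))
        assert bd.S_E["ames"] > 2.0
        assert bd.desirable_deviation["ames"] is True

    def test_high_toxicity_deviation_not_flagged_desirable(self):
        bd = elimination_scores(_profile(ames_positive=1.0),
                                _reference({"ames": 0.1}))
        assert bd.S_E["ames"] > 2.0
        assert bd.desirable_deviation["ames"] is False

    def test_zero_dispersion_is_a_configuration_error(self):
        df = _reference().stats.copy()
        df.loc["MW", "dispersion"] = 0.0
        with pytest.raises(ValueError, match="dispersion"):
            ReferenceSet(df)


class TestInhibitionConstant:
    def test_zero_binding_gives_molar_ki(self):
        assert ki_from_binding(0.0) == 1.0

    def test_printed_convention_value(self):
        # Ki = exp(-G_U/RT) with R = 1.9872e-3 kcal/(mol K)
        # agreement to the printed 3 significant figures
        assert ki_from_binding(5.0, 298.15) == pytest.approx(2.16e-4, rel=5e-3)

    def test_round_trip_to_1e9(self):
        for gu in (0.5, 3.2, 7.9, 12.0):
            assert binding_from_ki(ki_from_binding(gu)) == pytest.approx(
                gu, abs=1e-9)

    def test_strictly_decreasing_in_binding_strength(self):
        gus = np.linspace(0, 15, 30)
        kis = [ki_from_binding(g) for g in gus]
        assert all(a > b for a, b in zip(kis, kis[1:]))


def _records(gu_by_ligand):
    return [BindingRecord(ligand=l, receptor=r, G_U=g)
            for l, by_r in gu_by_ligand.items() for r, g in by_r.items()]


SUBSTRATES = _records({"sub": {"COMT": 5.0, "AChE": 4.3, "MAOB": 4.6}})
for s in SUBSTRATES:
    s.ligand = {"COMT": "dopamine", "AChE": "acetylcholine",
                "MAOB": "phenylethylamine"}[s.receptor]


class TestPolygenicScore:
    def test_stronger_ligand_outranks_weaker(self):
        table = polygenic_score(_records({
            "deriv": {"COMT": 6.3, "AChE": 7.0, "MAOB": 6.8},
            "parent": {"COMT": 5.5, "AChE": 6.2, "MAOB": 5.9},
        }), SUBSTRATES)
        sp = table.set_index("ligand")["S_P"]
        assert sp["deriv"] > sp["parent"]

    def test_identical_records_identical_scores(self):
        table = polygenic_score(_records({
            "a": {"COMT": 6.0, "AChE": 6.0, "MAOB": 6.0},
            "b": {"COMT": 6.0, "AChE": 6.0, "MAOB": 6.0},
        }), SUBSTRATES)
        assert table["S_P"].nunique() == 1

    def test_all_targets_stronger_than_substrate_flagged(self):
        table = polygenic_score(_records({
            "strong": {"COMT": 6.0, "AChE": 6.0, "MAOB": 6.0},
            "weak": {"COMT": 4.0, "AChE": 6.0, "MAOB": 6.0},
        }), SUBSTRATES)
        notes = table.set_index("ligand")["note"]
        assert notes["strong"] == "may be an efficient inhibitor"
        assert notes["weak"] == ""

    def test_missing_receptor_record_is_an_error(self):
        with pytest.raises(ValueError, match="lacks records"):
            polygenic_score(_records({"x": {"COMT": 6.0}}), SUBSTRATES)
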