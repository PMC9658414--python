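"""FPA pKa estimation and closed-form acid–base speciation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoxdesign.speciation import (FPAParams, fpa_pka, molar_fractions,
                                  neutral_fraction_filter, speciate_sites)


def equilibrium_solver_fractions(pkas, pH):
    """Independent oracle: solve the sequential equilibria as a linear system.

    Unknowns are the species concentrations at total 1; each equilibrium
    contributes K_i·c_i − a_H·c_{i+1} = 0 with a_H = 10^(−pH), rows scaled
    for conditioning.
    """
    n = len(pkas) + 1
    A = np.zeros((n, n))
    b = np.zeros(n)
    aH = 10.0 ** (-pH)
    for i, pka in enumerate(pkas):
        K = 10.0 ** (-pka)
        scale = max(K, aH)
        A[i, i] = K / scale
        A[i, i + 1] = -aH / scale
    A[n - 1, :] = 1.0
    b[n - 1] = 1.0
    return np.linalg.solve(A, b)


class TestFpa:
    def test_linear_map(self):
        p = FPAParams(family="phenol", m=1.0, C0=0.0)
        assert fpa_pka(5.0, p) == 5.0

    def test_zero_crossing(self):
        p = FPAParams(family="thiol", m=0.25, C0=-3.0)
        assert fpa_pka(-p.C0 / p.m, p) == pytest.approx(0.0, abs=1e-12)

    def test_parameters_recovered_by_least_squares(self):
        # synthetic (dG, pKa) pairs generated from a known calibration
        m_true, c_true = 0.271, -61.3
        dG = np.linspace(250.0, 320.0, 25)
        pka = np.array([fpa_pka(g, FPAParams("phenol", m_true, c_true))
                        for g in dG])
        m_fit, c_fit = np.polyfit(dG, pka, 1)
        assert m_fit == pytest.approx(m_true, abs=1e-9)
        assert c_fit == pytest.approx(c_true, abs=1e-9)

    def test_family_mismatch_rejected(self):
        p = FPAParams(family="phenol", m=0.3, C0=1.0)
        with pytest.raises(ValueError, match="family"):
            fpa_pka(5.0, p, family="thiol")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            FPAParams(family="sulfonic acid", m=0.3, C0=1.0)


class TestMolarFractions:
    def test_half_equivalence_point(self):
        m = molar_fractions([4.8], pH=4.8)
        assert m.fractions == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_fractions_sum_to_one(self):
        m = molar_fractions([2.0, 6.5, 11.0], pH=7.0)
        assert m.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_ascending_route_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            molar_fractions([9.0, 4.0], pH=7.0)

    @given(st.lists(st.floats(0.0, 14.0), min_size=1, max_size=4),
           st.floats(0.0, 14.0))
    @settings(max_examples=200, deadline=None)
    def test_closed_form_matches_equilibrium_solver(self, pkas, pH):
        pkas = sorted(pkas)
        m = molar_fractions(pkas, pH=pH)
        oracle = equilibrium_solver_fractions(pkas, pH)
        assert np.allclose(m.fractions, oracle, atol=1e-10, rtol=0)
        assert m.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_neutral_fraction_monotone_decreasing_in_pH(self):
        pkas = [5.9, 12.12]
        grid = [molar_fractions(pkas, pH).neutral_fraction
                for pH in np.linspace(0, 14, 60)]
        assert all(a >= b for a, b in zip(grid, grid[1:]))

    def test_fully_deprotonated_fraction_monotone_increasing_in_pH(self):
        pkas = [5.9, 12.12]
        grid = [float(molar_fractions(pkas, pH).fractions[-1])
                for pH in np.linspace(0, 14, 60)]
        assert all(a <= b for a, b in zip(grid, grid[1:]))


class TestNeutralFilter:
    @pytest.mark.parametrize("pka,pH,keep", [
        (5.5, 7.4, True),     # neutral fraction ~0.0124
        (4.8, 7.4, False),    # 0.0025
    ])
    def test_threshold_decisions(self, pka, pH, keep):
        assert neutral_fraction_filter(molar_fractions([pka], pH)) is keep

    def test_exactly_at_threshold_is_kept(self):
        # the rule discards only strictly below 1%
        m = molar_fractions([4.8], pH=7.4)
        m.fractions[0] = 0.01
        assert neutral_fraction_filter(m) is True


class TestSiteRouting:
    def test_route_orders_sites_by_ascending_pka(self):
        fpa = {"thiol": FPAParams("thiol", 1.0, 0.0),
               "phenol": FPAParams("phenol", 1.0, 0.0)}
        sites = pd.DataFrame([
            {"molecule": "m", "site": "OH", "family": "phenol", "dG_BA": 12.0},
            {"molecule": "m", "site": "SH", "family": "thiol", "dG_BA": 6.0},
        ])
        model = speciate_sites(sites, fpa, pH=7.4)
        assert model.pkas == [6.0, 12.0]
        assert "SH" in model.labels[1] and "OH" in model.labels[2]
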