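"""TST, tunneling, Marcus, diffusion and pH-weighted overall rates."""

import numpy as np
import pytest

from aoxdesign import constants as cn
from aoxdesign.kinetics import (ReactionChannel, collins_kimball,
                                compare_to_references, diffusion_limit,
                                eckart_kappa, evaluate_channel,
                                marcus_barrier, overall_rate, repair_routes,
                                tst_rate)


def eckart_kappa_oracle(V1, V2, nu, T=298.15, n=250001):
    """Fine-grid trapezoid oracle using the direct (non-log) Eckart formula."""
    C = cn.wavenumber_to_energy_kcal(nu)
    rt = cn.rt_kcal(T)
    x = np.linspace(0.0, V1 / rt + 60.0, n)
    E = x * rt
    a1, a2 = 2 * np.pi * V1 / C, 2 * np.pi * V2 / C
    denom = a1 ** -0.5 + a2 ** -0.5
    with np.errstate(invalid="ignore"):
        a = 2 * np.sqrt(a1 * E / V1) / denom
        b = 2 * np.sqrt(np.maximum(a1 * E / V1 + a2 - a1, 0.0)) / denom
    d2 = a1 * a2 - np.pi ** 2 / 4
    coshd = np.cosh(2 * np.sqrt(d2)) if d2 >= 0 else np.cos(2 * np.sqrt(-d2))
    P = (np.cosh(a + b) - np.cosh(a - b)) / (np.cosh(a + b) + coshd)
    P[E <= max(0.0, V1 - V2)] = 0.0
    return np.trapezoid(P * np.exp(V1 / rt - x), x)


class TestTst:
    def test_barrierless_rate_is_kbt_over_h(self):
        assert tst_rate(0.0) == pytest.approx(6.21e12, rel=1e-3)

    def test_rate_vanishes_for_huge_barrier(self):
        assert tst_rate(300.0) < 1e-180

    def test_path_degeneracy_is_multiplicative(self):
        assert tst_rate(5.0, sigma=2) == pytest.approx(2 * tst_rate(5.0))

    def test_strictly_decreasing_in_barrier(self):
        ks = [tst_rate(g) for g in np.linspace(0.0, 30.0, 40)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            tst_rate(5.0, T=0.0)


class TestEckart:
    def test_no_barrier_no_enhancement(self):
        assert eckart_kappa(1e-4, 1e-4, 1000.0) == pytest.approx(1.0, abs=1e-2)

    def test_vanishing_frequency_gives_unit_kappa(self):
        assert eckart_kappa(8.0, 15.0, 1.0) == pytest.approx(1.0, abs=1e-3)

    def test_kappa_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            v1 = rng.uniform(1.0, 15.0)
            k = eckart_kappa(v1, v1 + rng.uniform(0.5, 10.0),
                             rng.uniform(300.0, 2200.0))
            assert k >= 1.0

    def test_matches_fine_grid_trapezoid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            v1 = rng.uniform(2.0, 12.0)
            v2 = v1 + rng.uniform(1.0, 10.0)
            nu = rng.uniform(600.0, 1800.0)
            assert eckart_kappa(v1, v2, nu) == pytest.approx(
                eckart_kappa_oracle(v1, v2, nu), rel=1e-6)

    def test_kappa_increases_with_imaginary_frequency(self):
        ks = [eckart_kappa(6.0, 12.0, nu)
              for nu in np.linspace(300.0, 2400.0, 12)]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            eckart_kappa(-1.0, 5.0, 1000.0)
        with pytest.raises(ValueError):
            eckart_kappa(5.0, 5.0, -10.0)


class TestMarcus:
    def test_minimum_at_minus_lambda(self):
        assert marcus_barrier(-40.0, 40.0) == 0.0

    def test_thermoneutral_barrier_is_quarter_lambda(self):
        assert marcus_barrier(0.0, 40.0) == pytest.approx(10.0)

    def test_inverted_region_symmetry(self):
        lam = 33.0
        for delta in np.linspace(0.0, 50.0, 20):
            assert marcus_barrier(-lam + delta, lam) == pytest.approx(
                marcus_barrier(-lam - delta, lam), abs=1e-12)

    def test_positive_lambda_required(self):
        with pytest.raises(ValueError):
            marcus_barrier(0.0, -1.0)


class TestDiffusion:
    def test_equal_radii_value_in_water(self):
        # radius-independent closed form ~7.4e9 M^-1 s^-1 at 298.15 K
        k = diffusion_limit(3.0, 3.0)
        assert k == pytest.approx(7.42e9, rel=1e-2)
        assert diffusion_limit(1.0, 1.0) == pytest.approx(k)

    def test_scales_linearly_with_T_over_eta(self):
        k = diffusion_limit(2.0, 4.0, viscosity=8.91e-4)
        assert diffusion_limit(2.0, 4.0, viscosity=8.91e-4 / 2) == pytest.approx(2 * k)

    def test_collins_kimball_limits(self):
        assert collins_kimball(1e14, 1e9) == pytest.approx(1e9, rel=1e-4)
        assert collins_kimball(1e9, 1e9) == pytest.approx(5e8)
        assert collins_kimball(1e3, 1e9) == pytest.approx(1e3, rel=1e-5)

    def test_apparent_rate_never_exceeds_diffusion_limit(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            ka, kd = 10 ** rng.uniform(2, 14), 10 ** rng.uniform(8, 11)
            assert collins_kimball(ka, kd) <= kd


def _channel(**over):
    base = dict(species="m", state="neutral", mechanism="f-HAT", site="OH",
                dG0=-5.0, dG_barrier_fwd=6.0, dG_barrier_rev=11.0,
                nu_imag=1200.0, sigma=1, medium="aqueous")
    base.update(over)
    return ReactionChannel(**base)


class TestOverallRate:
    def test_single_channel_branching_is_unity(self):
        rated = [evaluate_channel(_channel())]
        k, rated = overall_rate(rated, {"neutral": 1.0})
        assert rated[0].branching == pytest.approx(1.0)
        assert k == pytest.approx(rated[0].k_app)

    def test_weighted_sum_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(13)
        fractions = {"neutral": 0.031, "monoanion": 0.969}
        rated = [evaluate_channel(_channel(
            state=rng.choice(["neutral", "monoanion"]),
            dG_barrier_fwd=float(rng.uniform(2, 14)),
            dG_barrier_rev=float(rng.uniform(2, 14) + 8),
            sigma=int(rng.integers(1, 4)))) for _ in range(12)]
        k, rated = overall_rate(rated, fractions)
        oracle = sum(fractions[r.channel.state] * r.k_app for r in rated)
        assert k == pytest.approx(oracle, rel=1e-12)
        assert sum(r.branching for r in rated) == pytest.approx(1.0, abs=1e-9)

    def test_single_species_fraction_one_reduces_to_plain_sum(self):
        rated = [evaluate_channel(_channel(dG_barrier_fwd=b))
                 for b in (4.0, 7.0)]
        k, _ = overall_rate(rated, {"neutral": 1.0})
        assert k == pytest.approx(sum(r.k_app for r in rated))

    def test_missing_fraction_raises(self):
        with pytest.raises(KeyError, match="monoanion"):
            overall_rate([evaluate_channel(_channel(state="monoanion"))],
                         {"neutral": 1.0})


class TestReferencesAndRepair:
    def test_fold_differences_three_significant_figures(self):
        folds = compare_to_references(5.17e6, "lipid",
                                      {"Trolox": 3.40e3, "AA": 5.71e3})
        assert folds == {"Trolox": 1520.0, "AA": 905.0}

    def test_aqueous_comparison_weights_by_radical_fraction(self):
        folds = compare_to_references(9.96e9, "aqueous", {"Trolox": 8.96e4},
                                      target_fraction=0.0025)
        assert folds["Trolox"] == pytest.approx(278.0)

    def test_reference_equal_to_candidate_is_unity(self):
        assert compare_to_references(1e5, "lipid", {"x": 1e5}) == {"x": 1.0}

    def test_endergonic_set_excluded_from_kinetics(self):
        chans = [
            _channel(target="His"),
            ReactionChannel(species="m", state="neutral", mechanism="SET",
                            dG0=+6.0, lam=20.0, medium="aqueous", target="His"),
        ]
        rep = repair_routes(chans, {"neutral": 1.0})
        assert rep["His"]["status"] == "repaired"
        assert "SET" not in rep["His"]["k_by_mechanism"]
        assert rep["His"]["mechanisms"]["SET"][0]["excluded"] == "endergonic SET"

    def test_both_mechanisms_summed_when_viable(self):
        chans = [
            _channel(target="Tyr"),
            ReactionChannel(species="m", state="neutral", mechanism="SET",
                            dG0=-8.0, lam=30.0, medium="aqueous", target="Tyr"),
        ]
        rep = repair_routes(chans, {"neutral": 1.0})
        mech = rep["Tyr"]["k_by_mechanism"]
        assert set(mech) == {"f-HAT", "SET"}
        assert rep["Tyr"]["k_total"] == pytest.approx(sum(mech.values()))

    def test_no_viable_channel_reports_not_repaired(self):
        chans = [ReactionChannel(species="m", state="neutral", mechanism="SET",
                                 dG0=+9.0, lam=25.0, target="Leu")]
        rep = repair_routes(chans, {"neutral": 1.0})
        assert rep["Leu"]["status"] == "not repaired"
        assert rep["Leu"]["k_total"] == 0.0

    def test_endergonic_dehydration_voids_shatd_route(self):
        chans = [
            _channel(mechanism="SHATD-step", target="2dG-III"),
            ReactionChannel(species="m", state="neutral",
                            mechanism="SHATD-step", site="dehydration",
                            dG0=+3.0, target="2dG-III"),
        ]
        rep = repair_routes(chans, {"neutral": 1.0})
        assert rep["2dG-III"]["status"] == "not repaired"
        assert "dehydration" in rep["2dG-III"]["reason"]

    def test_channel_validation(self):
        with pytest.raises(ValueError, match="mechanism"):
            ReactionChannel(species="m", state="n", mechanism="HAT??")
        with pytest.raises(ValueError, match="reorganization"):
            ReactionChannel(species="m", state="n", mechanism="SET", dG0=-5.0)
        with pytest.raises(ValueError, match="sigma"):
            _channel(sigma=0)
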