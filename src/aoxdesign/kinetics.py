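"""Rate coefficients for radical-scavenging and repair reactions.

The kinetic model follows the overall-radical-scavenging-activity recipe used
for quantum-chemistry-based antioxidant kinetics:

* conventional transition-state theory (TST) on a 1 M standard state,
  ``k = σ·κ·(k_B·T/h)·exp(−ΔG‡/RT)``, with reaction-path degeneracy σ;
* asymmetric-Eckart tunneling transmission κ for formal hydrogen-atom
  transfer (f-HAT) channels, from the forward/reverse barriers and the
  imaginary frequency of the transition state;
* Marcus theory for single-electron-transfer (SET) barriers,
  ``ΔG‡ = (λ/4)·(1 + ΔG°/λ)²`` with reorganization energy λ;
* Smoluchowski/Stokes–Einstein diffusion limits and the Collins–Kimball
  interpolation ``k_app = k_D·k_act/(k_D + k_act)``;
* molar-fraction weighting of per-protonation-state rate coefficients at the
  working pH, ``k_total = Σ_s f_s · Σ_channels k_app``.

All energies are kcal/mol, frequencies cm⁻¹, radii Å, temperatures K and
bimolecular rate coefficients M⁻¹ s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import quad

from . import constants as cn

__all__ = [
    "ReactionChannel",
    "RateResult",
    "tst_rate",
    "eckart_kappa",
    "marcus_barrier",
    "diffusion_limit",
    "collins_kimball",
    "evaluate_channel",
    "overall_rate",
    "compare_to_references",
    "repair_routes",
]

MECHANISMS = ("SET", "f-HAT", "RAF", "SHATD-step")

VISCOSITY_BY_MEDIUM = {
    "aqueous": cn.VISCOSITY_WATER,
    "lipid": cn.VISCOSITY_LIPID,
}


@dataclass
class ReactionChannel:
    """One mechanism/site/protonation-state reaction pathway.

    ``dG_barrier_fwd``/``dG_barrier_rev`` are Gibbs activation energies from
    electronic-structure input (f-HAT/RAF); SET channels instead carry the
    reorganization energy ``lam`` and obtain their barrier from Marcus
    theory.  ``sigma`` is the reaction-path degeneracy, an input integer.
    """

    species: str
    state: str
    mechanism: str
    site: str = ""
    dG0: float | None = None
    dG_barrier_fwd: float | None = None
    dG_barrier_rev: float | None = None
    nu_imag: float | None = None
    lam: float | None = None
    sigma: int = 1
    medium: str = "aqueous"
    radius_A: float = 3.0
    radius_B: float = 3.0
    target: str = ""

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.sigma < 1:
            raise ValueError("reaction-path degeneracy sigma must be >= 1")
        if self.mechanism == "SET" and (self.lam is None or self.lam <= 0):
            raise ValueError("SET channels require a positive reorganization energy")


@dataclass
class RateResult:
    """Per-channel kinetic quantities (all bimolecular, M⁻¹ s⁻¹)."""

    k_tst: float
    kappa: float
    k_act: float
    k_D: float
    k_app: float
    dG_barrier: float
    channel: ReactionChannel | None = None
    branching: float | None = None


def tst_rate(dG_barrier: float, T: float = cn.T_DEFAULT, sigma: int = 1,
             kappa: float = 1.0) -> float:
    """Conventional TST rate, ``σ·κ·(k_B·T/h)·exp(−ΔG‡/RT)``.

    On the 1 M standard state the same expression serves bimolecular
    channels (units M⁻¹ s⁻¹).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if kappa < 1 or sigma < 1:
        raise ValueError("sigma and kappa must both be >= 1")
    return sigma * kappa * cn.kbt_over_h(T) * math.exp(-dG_barrier / cn.rt_kcal(T))


def marcus_barrier(dG0: float, lam: float) -> float:
    """Marcus activation energy ``(λ/4)·(1 + ΔG°/λ)²``.

    Vanishes at ΔG° = −λ and rises again for more exergonic reactions (the
    inverted region).
    """
    if lam <= 0:
        raise ValueError("reorganization energy must be positive")
    return 0.25 * lam * (1.0 + dG0 / lam) ** 2


def _eckart_log_transmission(E: float, V1: float, V2: float, C: float) -> float:
    """log(P(E)) for the asymmetric Eckart barrier; -inf below threshold.

    ``C`` is the imaginary-frequency energy h·ν* (kcal/mol); energies are
    measured from the reactant asymptote.  Evaluated in log space so the
    hyperbolic cosines never overflow.
    """
    if E <= max(0.0, V1 - V2):
        return -math.inf
    alpha1 = 2.0 * math.pi * V1 / C
    alpha2 = 2.0 * math.pi * V2 / C
    denom = 1.0 / math.sqrt(alpha1) + 1.0 / math.sqrt(alpha2)
    a = 2.0 * math.sqrt(alpha1 * E / V1) / denom
    b = 2.0 * math.sqrt(alpha1 * E / V1 + alpha2 - alpha1) / denom
    d2 = alpha1 * alpha2 - 0.25 * math.pi ** 2

    def log_cosh(x: float) -> float:
        x = abs(x)
        # log((e^x + e^-x)/2)
        return x + math.log1p(math.exp(-2.0 * x)) - math.log(2.0)

    log_num_cosh = log_cosh(a - b)
    log_den_cosh = log_cosh(a + b)
    if d2 >= 0.0:
        log_d_cosh = log_cosh(2.0 * math.sqrt(d2))
        log_num = np.logaddexp(log_num_cosh, log_d_cosh)
        log_den = np.logaddexp(log_den_cosh, log_d_cosh)
    else:
        cos_d = math.cos(2.0 * math.sqrt(-d2))  # |cos| <= 1, may be negative
        log_num = log_num_cosh + math.log1p(cos_d * math.exp(-log_num_cosh))
        log_den = log_den_cosh + math.log1p(cos_d * math.exp(-log_den_cosh))
    ratio = log_num - log_den  # <= 0
    p = -math.expm1(ratio)
    return math.log(p) if p > 0.0 else -math.inf


def eckart_kappa(dG_fwd: float, dG_rev: float, nu_imag: float,
                 T: float = cn.T_DEFAULT) -> float:
    """Eckart tunneling transmission coefficient for an f-HAT barrier.

    κ is the Boltzmann average of the asymmetric-Eckart transmission
    probability divided by the classical over-the-barrier flux,

    ``κ = exp(ΔG‡_fwd/RT) · ∫ P(E)·exp(−E/RT) dE/RT``,

    evaluated by adaptive quadrature (relative tolerance 1e-8).  κ ≥ 1 and
    κ → 1 as the imaginary frequency (or the barrier) goes to zero.
    """
    if dG_fwd <= 0 or dG_rev <= 0:
        raise ValueError("Eckart barriers must be positive")
    if nu_imag <= 0:
        raise ValueError("imaginary frequency must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    C = cn.wavenumber_to_energy_kcal(nu_imag)
    rt = cn.rt_kcal(T)
    v1_red = dG_fwd / rt

    def integrand(x: float) -> float:
        logp = _eckart_log_transmission(x * rt, dG_fwd, dG_rev, C)
        arg = logp + v1_red - x
        return math.exp(arg) if arg > -700.0 else 0.0

    upper = v1_red + 60.0
    import warnings
    from scipy.integrate import IntegrationWarning

    with warnings.catch_warnings():
        # round-off warnings are expected near machine precision; convergence
        # is verified explicitly below
        warnings.simplefilter("ignore", IntegrationWarning)
        value, err = quad(integrand, 0.0, upper, epsrel=1e-8, epsabs=0.0,
                          limit=400)
        tail, _ = quad(integrand, upper, np.inf, epsrel=1e-6, epsabs=1e-12,
                       limit=200)
    kappa = value + tail
    if not np.isfinite(kappa) or kappa <= 0.0 or err > 1e-4 * max(value, 1.0):
        raise ArithmeticError(
            "Eckart quadrature did not converge: "
            f"value={kappa!r}, abs_err={err!r}, barriers=({dG_fwd}, {dG_rev}), "
            f"nu_imag={nu_imag}, T={T}"
        )
    return kappa


def diffusion_limit(radius_A: float, radius_B: float,
                    viscosity: float = cn.VISCOSITY_WATER,
                    T: float = cn.T_DEFAULT) -> float:
    """Smoluchowski diffusion-limited rate coefficient, M⁻¹ s⁻¹.

    ``k_D = 4π·R_AB·D_AB·N_A`` with Stokes–Einstein diffusion coefficients
    ``D_i = k_B·T/(6π·η·a_i)`` and ``R_AB = a_A + a_B``.  For equal radii the
    result is radius-independent (≈7.4e9 in water at 298.15 K).
    """
    if radius_A <= 0 or radius_B <= 0 or viscosity <= 0 or T <= 0:
        raise ValueError("radii, viscosity and temperature must be positive")
    a_A = radius_A * cn.ANGSTROM
    a_B = radius_B * cn.ANGSTROM
    D = cn.KB_J * T / (6.0 * math.pi * viscosity)
    D_AB = D / a_A + D / a_B
    k_m3 = 4.0 * math.pi * (a_A + a_B) * D_AB * cn.NA
    return k_m3 * 1e3  # m^3/(mol s) -> L/(mol s)


def collins_kimball(k_act: float, k_D: float) -> float:
    """Diffusion-corrected apparent rate ``k_D·k_act/(k_D + k_act)``."""
    if k_act <= 0 or k_D <= 0:
        raise ValueError("rate coefficients must be positive")
    return k_D * k_act / (k_D + k_act)


def evaluate_channel(channel: ReactionChannel, T: float = cn.T_DEFAULT,
                     viscosity: float | None = None) -> RateResult:
    """Thermal rate for one channel: barrier → TST → tunneling → diffusion.

    SET barriers come from Marcus theory (no tunneling); f-HAT channels get
    an Eckart κ when an imaginary frequency is supplied; RAF and SHATD steps
    are treated like f-HAT.
    """
    if viscosity is None:
        try:
            viscosity = VISCOSITY_BY_MEDIUM[channel.medium]
        except KeyError:
            raise ValueError(f"unknown medium {channel.medium!r} and no viscosity given")
    if channel.mechanism == "SET":
        if channel.dG0 is None:
            raise ValueError("SET channel requires dG0 for the Marcus barrier")
        barrier = marcus_barrier(channel.dG0, channel.lam)
        kappa = 1.0
    else:
        if channel.dG_barrier_fwd is None:
            raise ValueError(f"{channel.mechanism} channel requires dG_barrier_fwd")
        barrier = channel.dG_barrier_fwd
        kappa = 1.0
        if channel.nu_imag is not None and channel.dG_barrier_rev is not None:
            kappa = eckart_kappa(channel.dG_barrier_fwd, channel.dG_barrier_rev,
                                 channel.nu_imag, T)
    k_tst = tst_rate(barrier, T=T, sigma=1, kappa=1.0)
    k_act = channel.sigma * kappa * k_tst
    k_D = diffusion_limit(channel.radius_A, channel.radius_B, viscosity, T)
    k_app = collins_kimball(k_act, k_D)
    return RateResult(k_tst=k_tst, kappa=kappa, k_act=k_act, k_D=k_D,
                      k_app=k_app, dG_barrier=barrier, channel=channel)


def _state_fractions(speciation) -> Mapping[str, float]:
    if isinstance(speciation, Mapping):
        return speciation
    return {lab: float(f) for lab, f in zip(speciation.labels, speciation.fractions)}


def overall_rate(rated: Sequence[RateResult], speciation) -> tuple[float, list[RateResult]]:
    """Molar-fraction-weighted overall rate coefficient and branching ratios.

    ``speciation`` is either a :class:`~aoxdesign.speciation.SpeciationModel`
    or a mapping state-label → molar fraction.  Every channel's state must
    have a fraction.  Returns ``(k_total, rated)`` with each result's
    ``branching`` set to its weighted share of ``k_total``.
    """
    fractions = _state_fractions(speciation)
    weighted = []
    for r in rated:
        state = r.channel.state
        if state not in fractions:
            raise KeyError(f"no molar fraction for protonation state {state!r}")
        weighted.append(fractions[state] * r.k_app)
    k_total = float(sum(weighted))
    if k_total > 0:
        for r, w in zip(rated, weighted):
            r.branching = w / k_total
    return k_total, rated


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig - 1}e}")


def compare_to_references(k_overall: float, medium: str,
                          reference_rates: Mapping[str, float],
                          target_fraction: float | None = None) -> dict[str, float]:
    """Fold-differences of a candidate's overall rate vs reference antioxidants.

    In aqueous medium the candidate's rate is first multiplied by the target
    radical's neutral molar fraction at the working pH (the reference values
    are apparent, pH-conditioned coefficients).  Folds are rounded to three
    significant figures.
    """
    effective = k_overall
    if medium == "aqueous" and target_fraction is not None:
        effective = k_overall * target_fraction
    return {name: _round_sig(effective / k_ref)
            for name, k_ref in reference_rates.items()}


#: Mechanisms each repair target admits.  Lipid repair is f-HAT from the
#: thiol; amino-acid residues are repaired by f-HAT and, where exergonic,
#: SET; oxidised DNA has three routes: SET on guanine radical cations (I),
#: f-HAT at the deoxyribose C4 radical (II) and the two-step SHATD on
#: 8-OH-dG lesions (III).
REPAIR_TARGETS = (
    "LM", "Cys", "His", "Leu", "Met", "Trp", "Tyr",
    "2dG-I", "2dG-II", "2dG-III",
)


def repair_routes(channels: Iterable[ReactionChannel], speciation,
                  T: float = cn.T_DEFAULT) -> dict[str, dict]:
    """Per-target repair report for damaged lipids, residues and DNA.

    Endergonic SET channels are excluded from the kinetics (electron
    transfer is only counted when thermochemically viable).  For the SHATD
    route the hydrogen-transfer step is rate limiting; the dehydration step
    (``site == 'dehydration'``, thermochemistry only) is checked for
    exergonicity and voids the route when endergonic.  Targets with no
    viable channel are reported as ``"not repaired"``.
    """
    fractions = _state_fractions(speciation)
    by_target: dict[str, list[ReactionChannel]] = {}
    for ch in channels:
        by_target.setdefault(ch.target or "unassigned", []).append(ch)

    report: dict[str, dict] = {}
    for target, chans in by_target.items():
        entry: dict = {"target": target, "mechanisms": {}, "status": "repaired"}
        dehydration = [c for c in chans if c.site == "dehydration"]
        kinetic = [c for c in chans if c.site != "dehydration"]
        if dehydration:
            endergonic = [c for c in dehydration if (c.dG0 or 0.0) > 0]
            entry["dehydration_dG0"] = [c.dG0 for c in dehydration]
            if endergonic:
                report[target] = {**entry, "status": "not repaired",
                                  "reason": "dehydration step endergonic",
                                  "k_total": 0.0}
                continue
        viable: list[RateResult] = []
        for ch in kinetic:
            if ch.mechanism == "SET" and ch.dG0 is not None and ch.dG0 > 0:
                entry["mechanisms"].setdefault(ch.mechanism, []).append(
                    {"state": ch.state, "excluded": "endergonic SET"})
                continue
            r = evaluate_channel(ch, T=T)
            viable.append(r)
            entry["mechanisms"].setdefault(ch.mechanism, []).append(
                {"state": ch.state, "k_app": r.k_app, "kappa": r.kappa})
        if not viable:
            report[target] = {**entry, "status": "not repaired",
                              "reason": "no viable channel", "k_total": 0.0}
            continue
        k_total, _ = overall_rate(viable, fractions)
        entry["k_total"] = k_total
        by_mech: dict[str, float] = {}
        for r in viable:
            w = fractions[r.channel.state] * r.k_app
            by_mech[r.channel.mechanism] = by_mech.get(r.channel.mechanism, 0.0) + w
        entry["k_by_mechanism"] = by_mech
        report[target] = entry
    return report
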