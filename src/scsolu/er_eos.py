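"""Esmaeilzadeh-Roshanfekr cubic EoS route to solid solubility in SC-CO2.

The ER equation of state,

    P = RT/(v - b) - a(T) / (v (v + c) + c (v - c)),

is a three-parameter cubic whose attraction term denominator is
``v^2 + 2 c v - c^2``.  Pure-component parameters follow from the critical
conditions (dP/dv = d2P/dv2 = 0 at Tc, Pc) closed with a prescribed
critical compressibility; a Soave-type alpha(T) supplies the temperature
dependence.  Mixtures use the two-parameter van der Waals (vdW2) rules
with binary interaction corrections kij (attraction) and lij (co-volume);
the third parameter mixes linearly.

Solid solubility y2 at (T, P) is the classical solid-SCF equilibrium
closure: the pure-solid fugacity (sublimation pressure with Poynting
correction) equated to the solute fugacity in the fluid, iterated on y2
with the EoS fugacity coefficient.  The binary parameters (kij, lij) are
regressed per isotherm by differential evolution on AARD%.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .co2_properties import R_GAS
from .optimizers import DEConfig, OptimizeResult, de_minimize

__all__ = [
    "SublimationModel",
    "SolutePhysProps",
    "ErParams",
    "EosIsothermFit",
    "er_omegas",
    "er_pure_params",
    "er_volume_roots",
    "mixture_params",
    "fugacity_coeff",
    "solid_solubility_eos",
    "fit_binary_params",
    "joback_critical",
    "constantinou_gani_omega",
    "CO2_PROPS",
    "lumiracoxib_props",
]

_R = R_GAS  # J/(mol K)
_SQRT2 = np.sqrt(2.0)

#: default critical compressibility closing the ER critical-condition system;
#: 0.30 balances vapor- and liquid-like CO2 density accuracy over the
#: studied supercritical window (mean deviation ~4% vs the reference EoS)
DEFAULT_ZETA_C = 0.30


@dataclass(frozen=True)
class SublimationModel:
    """Two-parameter Clausius-Clapeyron sublimation pressure: ln(P/Pa) = A - B/T."""

    A: float
    B: float

    def __call__(self, T: float) -> float:
        """Sublimation pressure in Pa."""
        return float(np.exp(self.A - self.B / T))


@dataclass(frozen=True)
class SolutePhysProps:
    """Solute constants for the EoS route.

    M (g/mol), Tc (K), Pc (bar), acentric factor, solid molar volume Vs
    (cm3/mol) and a sublimation-pressure model.
    """

    M: float
    Tc: float
    Pc: float
    omega: float
    Vs: float
    psub: SublimationModel

    def __post_init__(self) -> None:
        if min(self.Tc, self.Pc, self.Vs) <= 0:
            raise ValueError("Tc, Pc and Vs must be positive")


@dataclass(frozen=True)
class ErParams:
    """ER EoS parameters in SI units: a (Pa m6/mol2), b and c (m3/mol)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.a < 0:
            raise ValueError("require b > 0 and a >= 0")


@dataclass
class EosIsothermFit:
    """Per-isotherm binary interaction parameters with the achieved AARD%."""

    T: float
    kij: float
    lij: float
    aard_pct: float
    meta: dict = field(default_factory=dict)


@functools.lru_cache(maxsize=32)
def er_omegas(zeta_c: float = DEFAULT_ZETA_C) -> tuple[float, float, float]:
    """Dimensionless (Omega_a, Omega_b, Omega_c) from the critical conditions.

    Imposing a triple volume root at (Tc, Pc) gives three equations in
    (Omega_a, Omega_b, Omega_c, Zc); fixing the critical compressibility
    Zc = zeta_c closes the system, which is then solved numerically once
    and cached.
    """
    z = float(zeta_c)

    def resid(oc: float) -> float:
        ob = 3.0 * z - 1.0 + 2.0 * oc
        oa = 3.0 * z * z + 5.0 * oc * oc + 6.0 * z * oc
        return oa * ob - ob * oc * oc - oc * oc - z ** 3

    # smallest positive root; bracket by scanning
    grid = np.linspace(1e-6, 0.6, 2401)
    vals = [resid(x) for x in grid]
    oc = None
    for x0, x1, f0, f1 in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if f0 == 0.0 or f0 * f1 < 0:
            oc = brentq(resid, x0, x1, xtol=1e-15)
            break
    if oc is None:
        raise ValueError(f"no Omega solution for zeta_c={zeta_c}")
    ob = 3.0 * z - 1.0 + 2.0 * oc
    oa = 3.0 * z * z + 5.0 * oc * oc + 6.0 * z * oc
    if ob <= 0:
        raise ValueError(f"unphysical Omega_b for zeta_c={zeta_c}")
    return float(oa), float(ob), float(oc)


def _soave_m(omega: float) -> float:
    return 0.480 + 1.574 * omega - 0.176 * omega * omega


@functools.lru_cache(maxsize=4096)
def er_pure_params(Tc: float, Pc: float, omega: float, T: float,
                   zeta_c: float = DEFAULT_ZETA_C) -> ErParams:
    """Pure-component ER parameters at temperature T (Pc in bar).

    a(T) = Omega_a R^2 Tc^2 / Pc * alpha(T) with the Soave alpha
    [1 + m (1 - sqrt(T/Tc))]^2; b and c are temperature independent.
    """
    if min(T, Tc, Pc) <= 0:
        raise ValueError("T, Tc, Pc must be positive")
    oa, ob, oc = er_omegas(zeta_c)
    Pc = Pc * 1e5
    alpha = (1.0 + _soave_m(omega) * (1.0 - np.sqrt(T / Tc))) ** 2
    return ErParams(
        a=oa * _R * _R * Tc * Tc / Pc * alpha,
        b=ob * _R * Tc / Pc,
        c=oc * _R * Tc / Pc,
    )


def er_pressure(T: float, v: float, params: ErParams) -> float:
    """ER EoS pressure (bar) at temperature T (K) and molar volume v (m3/mol)."""
    p = _R * T / (v - params.b) - params.a / (v * (v + params.c) + params.c * (v - params.c))
    return p / 1e5


def _cubic_roots(p: float, q: float, r: float) -> np.ndarray:
    """Roots of x^3 + p x^2 + q x + r by the trigonometric/Cardano method."""
    # depressed cubic t^3 + at + b with x = t - p/3
    a = q - p * p / 3.0
    b = 2.0 * p ** 3 / 27.0 - p * q / 3.0 + r
    shift = -p / 3.0
    disc = (b / 2.0) ** 2 + (a / 3.0) ** 3
    if disc > 0.0:  # one real root
        s = np.sqrt(disc)
        u = np.cbrt(-b / 2.0 + s)
        v = np.cbrt(-b / 2.0 - s)
        t1 = u + v
        imag = np.sqrt(3.0) / 2.0 * (u - v)
        return np.array([t1 + shift,
                         complex(-t1 / 2.0 + shift, imag),
                         complex(-t1 / 2.0 + shift, -imag)])
    if a == 0.0:
        return np.full(3, shift + np.cbrt(-b))
    m = 2.0 * np.sqrt(-a / 3.0)
    arg = np.clip(3.0 * b / (a * m), -1.0, 1.0)
    theta = np.arccos(arg) / 3.0
    return np.array([m * np.cos(theta - 2.0 * np.pi * k / 3.0) + shift
                     for k in range(3)], dtype=complex)


def er_volume_roots(T: float, P_bar: float, params: ErParams) -> np.ndarray:
    """Real molar-volume roots (m3/mol, ascending) of the ER EoS at (T, P).

    All returned roots satisfy |P(v) - P|/P < 1e-10 and v > b.
    """
    if P_bar <= 0:
        raise ValueError("P must be positive")
    P = P_bar * 1e5
    a, b, c = params.a, params.b, params.c
    RT = _R * T
    coeffs = [
        1.0,
        (2.0 * c - b) - RT / P,
        a / P - c * c - 2.0 * b * c - 2.0 * c * RT / P,
        b * c * c + RT * c * c / P - a * b / P,
    ]
    roots = _cubic_roots(coeffs[1], coeffs[2], coeffs[3])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9 * np.abs(roots.real + 1e-300)].real)
    # exclude artifacts below the attraction-denominator singularity at
    # v = (sqrt(2)-1) c when that lies above the covolume
    v_min = max(b, (_SQRT2 - 1.0) * c)
    good = [v for v in real
            if v > v_min and abs(er_pressure(T, v, params) - P_bar) / P_bar < 1e-10]
    if not good:
        # fall back to polishing near-real roots
        good = []
        for v in np.sort(roots.real):
            if v <= v_min:
                continue
            lo_b = max(v * 0.5, v_min * (1.0 + 1e-9))
            try:
                vref = brentq(lambda x: er_pressure(T, x, params) - P_bar,
                              lo_b, v * 2.0, xtol=1e-18, rtol=8.9e-16)
                if abs(er_pressure(T, vref, params) - P_bar) / P_bar < 1e-10:
                    good.append(vref)
            except (ValueError, ZeroDivisionError):
                continue
    good = [v for v in good if v > v_min]
    if not good:
        raise ValueError(f"no physical volume root at T={T} K, P={P_bar} bar")
    return np.array(sorted(set(np.round(good, 20))))


def mixture_params(y, pure: list[ErParams], kij: float = 0.0, lij: float = 0.0) -> ErParams:
    """vdW2 mixing: quadratic a and b with (1-kij)/(1-lij) corrections, linear c.

    a_m = sum_ij y_i y_j (1-k_ij) sqrt(a_i a_j);
    b_m = sum_ij y_i y_j (1-l_ij) (b_i+b_j)/2;  c_m = sum_i y_i c_i.
    """
    y = np.asarray(y, dtype=float)
    if abs(y.sum() - 1.0) > 1e-10:
        raise ValueError("composition must sum to 1")
    n = y.size
    if n != len(pure):
        raise ValueError("composition/parameter length mismatch")
    K = np.full((n, n), kij)
    L = np.full((n, n), lij)
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(L, 0.0)
    av = np.array([p.a for p in pure])
    bv = np.array([p.b for p in pure])
    cv = np.array([p.c for p in pure])
    aij = (1.0 - K) * np.sqrt(np.outer(av, av))
    bij = (1.0 - L) * 0.5 * (bv[:, None] + bv[None, :])
    return ErParams(
        a=float(y @ aij @ y),
        b=float(y @ bij @ y),
        c=float(y @ cv),
    )


def _lnphi_all(y, T, P_bar, pure, kij, lij):
    """ln(phi_i) for every component at the minimum-Gibbs volume root."""
    y = np.asarray(y, dtype=float)
    mix = mixture_params(y, pure, kij, lij)
    roots = er_volume_roots(T, P_bar, mix)
    if roots.size > 1:
        # pick the root of lowest total Gibbs energy
        g = [_mix_residual_g(T, P_bar, v, mix) + np.log(P_bar * 1e5 * v / (_R * T))
             for v in roots]
        v = roots[int(np.argmin(g))]
    else:
        v = roots[0]
    return _lnphi_at_volume(y, T, P_bar, v, mix, pure, kij, lij), v


def _mix_residual_g(T, P_bar, v, mix: ErParams) -> float:
    """Residual Gibbs energy / RT at (T, P, v) for root selection."""
    P = P_bar * 1e5
    a, b, c = mix.a, mix.b, mix.c
    Z = P * v / (_R * T)
    d = v * v + 2.0 * c * v - c * c
    L = np.log((v - (_SQRT2 - 1.0) * c) / (v + (_SQRT2 + 1.0) * c)) if c != 0 else 0.0
    # g_res/RT = Z - 1 - ln Z + ln(v/(v-b)) + a L / (2 sqrt2 c R T)
    attract = a * L / (2.0 * _SQRT2 * c * _R * T) if c != 0 else -a / (v * _R * T)
    return Z - 1.0 - np.log(Z) + np.log(v / (v - b)) + attract


def _lnphi_at_volume(y, T, P_bar, v, mix, pure, kij, lij):
    P = P_bar * 1e5
    RT = _R * T
    n = len(pure)
    av = np.array([p.a for p in pure])
    bv = np.array([p.b for p in pure])
    cv = np.array([p.c for p in pure])
    K = np.full((n, n), kij); np.fill_diagonal(K, 0.0)
    Lm = np.full((n, n), lij); np.fill_diagonal(Lm, 0.0)
    aij = (1.0 - K) * np.sqrt(np.outer(av, av))
    bij = (1.0 - Lm) * 0.5 * (bv[:, None] + bv[None, :])
    abar = 2.0 * aij @ y                    # d(n^2 a_m)/dn_i / n
    bbar = 2.0 * bij @ y - mix.b            # d(n b_m)/dn_i
    am, bm, cm = mix.a, mix.b, mix.c
    if v <= max(bm, (_SQRT2 - 1.0) * cm):
        raise ValueError("volume root below the physical branch")
    Z = P * v / RT
    d = v * v + 2.0 * cm * v - cm * cm
    if cm > 0:
        L = np.log((v - (_SQRT2 - 1.0) * cm) / (v + (_SQRT2 + 1.0) * cm))
        term_a = (abar / (2.0 * _SQRT2 * cm) - am * cv / (2.0 * _SQRT2 * cm * cm)) * L
        term_c = -am * cv * v / (cm * d)
    else:
        # c -> 0 limit: attraction integral reduces to -abar/v
        L = 0.0
        term_a = -abar / v
        term_c = np.zeros(n)
    lnphi = (np.log(v / (v - bm)) + bbar / (v - bm)
             + (term_a + term_c) / RT - np.log(Z))
    return lnphi


def fugacity_coeff(i: int, y, T: float, P_bar: float, pure: list[ErParams],
                   kij: float = 0.0, lij: float = 0.0) -> float:
    """ln(phi_i) of component i in the mixture at (T, P).

    Analytic form for the ER EoS with vdW2 mixing, evaluated at the
    minimum-Gibbs-energy volume root.
    """
    lnphi, _ = _lnphi_all(y, T, P_bar, pure, kij, lij)
    return float(lnphi[i])


#: CO2 critical constants for the EoS route (K, bar, acentric factor)
CO2_PROPS = {"Tc": 304.13, "Pc": 73.77, "omega": 0.2236}


def solid_solubility_eos(T: float, P_bar: float, props: SolutePhysProps,
                         kij: float = 0.0, lij: float = 0.0,
                         zeta_c: float = DEFAULT_ZETA_C,
                         tol: float = 1e-10, max_iter: int = 200) -> float:
    """Mole-fraction solubility of a solid solute in CO2 from the ER EoS.

    Solves   y2 = (Psub/P) exp(Vs (P - Psub)/(R T)) / phi2(y2, T, P)
    by damped fixed-point iteration started from the ideal value Psub/P.
    The solid phase is pure solute; phi2 comes from the mixture EoS.
    """
    P = P_bar * 1e5
    psub = props.psub(T)
    vs = props.Vs * 1e-6  # cm3/mol -> m3/mol
    poynting = np.exp(vs * (P - psub) / (_R * T))
    ideal = psub / P * poynting
    pure = [
        er_pure_params(CO2_PROPS["Tc"], CO2_PROPS["Pc"], CO2_PROPS["omega"], T, zeta_c),
        er_pure_params(props.Tc, props.Pc, props.omega, T, zeta_c),
    ]
    def lnphi2(y2: float) -> float:
        lnphi, _ = _lnphi_all(np.array([1.0 - y2, y2]), T, P_bar, pure, kij, lij)
        return float(lnphi[1])

    # fast path: plain successive substitution, damped on oscillation;
    # converges in a handful of steps for weakly coupled (dilute) cases
    y2 = min(psub / P, 0.5)
    history = []
    prev_step = np.inf
    dampings = 0
    for _ in range(min(12, max_iter)):
        y_new = min(max(ideal * np.exp(-np.clip(lnphi2(y2), -690.0, 690.0)), 1e-30), 0.9)
        history.append(y_new)
        step = abs(y_new - y2)
        if step <= tol * max(y_new, 1e-30):
            return float(y_new)
        if step > prev_step:
            dampings += 1
            if dampings >= 2:
                break  # hand the strongly coupled case to the bracketing path
            y_new = 0.5 * (y2 + y_new)
        prev_step = step
        y2 = y_new

    # robust path: the equilibrium condition as a root problem in ln y2.
    # g = ln y + ln phi2(y) - ln(ideal) is very negative for y -> 0 and
    # crosses zero at equilibrium; bracket on a geometric grid and refine.
    log_ideal = np.log(ideal)

    def g(ln_y: float) -> float:
        return ln_y + lnphi2(float(np.exp(ln_y))) - log_ideal

    lo = np.log(min(ideal, 1e-12))
    grid = np.linspace(lo, np.log(0.5), 14)
    prev_x, prev_g = lo, g(lo)
    if prev_g < 0:
        for x in grid[1:]:
            try:
                gx = g(float(x))
            except (ValueError, RuntimeError, ZeroDivisionError):
                break
            if gx >= 0:
                ln_root = brentq(g, prev_x, float(x), xtol=tol, maxiter=max_iter)
                return float(np.exp(ln_root))
            prev_x, prev_g = float(x), gx
    raise RuntimeError(
        f"solid_solubility_eos did not converge at T={T}, P={P_bar}; trace tail "
        f"{history[-5:]}"
    )


def fit_binary_params(records, props: SolutePhysProps, de_config: DEConfig | None = None,
                      zeta_c: float = DEFAULT_ZETA_C,
                      bounds=((-1.0, 1.0), (-1.0, 1.0))) -> EosIsothermFit:
    """Regress (kij, lij) on one isotherm by DE-minimizing the AARD%.

    ``records`` is a sequence of SolubilityRecord at a single temperature.
    """
    temps = {r.T for r in records}
    if len(temps) != 1:
        raise ValueError("records must form a single isotherm")
    if len(records) < 4:
        raise ValueError("need at least 4 records on the isotherm")
    T = records[0].T
    P = np.array([r.P for r in records])
    y = np.array([r.y2 for r in records])

    def objective(x) -> float:
        k, l = x
        try:
            yc = np.array([solid_solubility_eos(T, p, props, k, l, zeta_c) for p in P])
        except (RuntimeError, ValueError, ZeroDivisionError):
            return 1e6
        return float(100.0 * np.mean(np.abs(y - yc) / y))

    cfg = de_config or DEConfig(pop_size=20, max_generations=60)
    res: OptimizeResult = de_minimize(objective, bounds, cfg)
    return EosIsothermFit(T=float(T), kij=float(res.x[0]), lij=float(res.x[1]),
                          aard_pct=float(res.fun),
                          meta={"seed": cfg.seed, "zeta_c": zeta_c,
                                "generations": len(res.trace) - 1})


# --- group-contribution property estimation -------------------------------

def _load_groups(name: str) -> pd.DataFrame:
    path = Path(str(importlib.resources.files("scsolu.data").joinpath(name)))
    return pd.read_csv(path, comment="#").set_index("group")


@functools.lru_cache(maxsize=1)
def _joback_table() -> pd.DataFrame:
    return _load_groups("joback_groups.csv")


@functools.lru_cache(maxsize=1)
def _cg_table() -> pd.DataFrame:
    return _load_groups("cg_first_order.csv")


def joback_critical(group_counts: dict, Tb: float | None = None,
                    n_atoms: int | None = None) -> tuple[float, float]:
    """Joback estimates of (Tc in K, Pc in bar) from a group multiset.

    ``group_counts`` maps group labels (see ``joback_groups.csv``) to counts.
    Tc requires the normal boiling point; when ``Tb`` is None the Joback Tb
    estimate 198.2 + sum(tb_k) is used.  ``n_atoms`` (all atoms including H)
    is required for Pc; if omitted it is taken from the table's atom counts.
    """
    if not group_counts:
        raise ValueError("empty group set")
    tbl = _joback_table()
    unknown = [g for g in group_counts if g not in tbl.index]
    if unknown:
        raise ValueError(f"unknown Joback group labels: {unknown}")
    counts = pd.Series(group_counts, dtype=float)
    s_tc = float((counts * tbl.loc[counts.index, "dTc"]).sum())
    s_pc = float((counts * tbl.loc[counts.index, "dPc"]).sum())
    if Tb is None:
        Tb = 198.2 + float((counts * tbl.loc[counts.index, "dTb"]).sum())
    if n_atoms is None:
        n_atoms = int(round(float((counts * tbl.loc[counts.index, "atoms"]).sum())))
    Tc = Tb / (0.584 + 0.965 * s_tc - s_tc * s_tc)
    Pc = (0.113 + 0.0032 * n_atoms - s_pc) ** -2
    return float(Tc), float(Pc)


def constantinou_gani_omega(group_counts: dict) -> float:
    """Acentric factor from first-order Constantinou-Gani contributions.

    omega = 0.4085 [ln(sum_k N_k w1_k + 1.1507)]^(1/0.5050).
    """
    if not group_counts:
        raise ValueError("empty group set")
    tbl = _cg_table()
    unknown = [g for g in group_counts if g not in tbl.index]
    if unknown:
        raise ValueError(f"unknown CG group labels: {unknown}")
    counts = pd.Series(group_counts, dtype=float)
    w1 = float((counts * tbl.loc[counts.index, "w1"]).sum())
    arg = w1 + 1.1507
    if arg <= 1.0:
        raise ValueError("group sum too small for the CG acentric-factor form")
    return float(0.4085 * np.log(arg) ** (1.0 / 0.5050))


#: documented lumiracoxib group assignments (2 aromatic rings: one bearing
#: F, Cl and the NH bridge; the other CH3, CH2COOH and the NH bridge)
LUMIRACOXIB_JOBACK = {
    "=CH- (ring)": 6, "=C< (ring)": 6, "-CH3": 1, ">CH2": 1,
    "-F": 1, "-Cl": 1, "-COOH": 1, ">NH": 1,
}
LUMIRACOXIB_CG = {"ACH": 6, "AC": 2, "ACCH3": 1, "ACF": 1, "ACCl": 1,
                  "CH2": 1, "COOH": 1, "NH": 1}


def lumiracoxib_props(psub: SublimationModel | None = None) -> SolutePhysProps:
    """Lumiracoxib constants for the EoS route.

    Critical constants, acentric factor and solid molar volume are the
    group-contribution estimates used throughout the lumiracoxib analysis
    (Tc = 768.76 K, Pc = 18.18 bar, omega = 0.9875, Vs = 215 cm3/mol).
    No measured sublimation pressure exists for lumiracoxib, so the default
    ``psub`` is a synthetic placeholder calibrated to the typical range of
    low-volatility drugs (~1e-3 Pa at 323 K, sublimation enthalpy
    ~120 kJ/mol); results that depend on it are indicative only.
    """
    return SolutePhysProps(
        M=293.72, Tc=768.76, Pc=18.18, omega=0.9875, Vs=215.0,
        psub=psub or SublimationModel(A=37.756, B=14433.0),
    )
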