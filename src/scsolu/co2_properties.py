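"""Pure-CO2 density from the Span-Wagner reference equation of state.

The solubility correlations in this package all take the density of the
supercritical solvent as their independent variable, so the package carries
its own implementation of the Span-Wagner multiparameter Helmholtz equation
of state for carbon dioxide (the reference formulation behind NIST/REFPROP
CO2 tables).  Only the residual part is implemented: density at given
(T, P) requires nothing else.

The supported envelope, 290-350 K and 60-600 bar, covers the 308.15-338.15 K,
120-400 bar region where drug solubilities are measured, with margin.  Within
it the implementation is cross-validated in the test suite against the
critical-point identities and against the (independently parameterised)
ancillary saturation equations via a Maxwell equal-area construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FluidState",
    "co2_density",
    "co2_state",
    "M_CO2",
    "R_GAS",
    "T_CRIT",
    "P_CRIT",
    "RHO_CRIT",
]

#: molar mass of CO2 used for molar/mass conversions, g/mol
M_CO2 = 44.01
#: universal gas constant, J/(mol K), as used throughout the package
R_GAS = 8.314

# Span-Wagner formulation constants (note the EoS's own R and M differ
# slightly from the rounded package-level constants above; the EoS must be
# evaluated with its native values).
_R_SW = 8.31451  # J/(mol K)
_M_SW = 44.0098e-3  # kg/mol
T_CRIT = 304.1282  # K
P_CRIT = 73.773  # bar
RHO_CRIT = 467.6  # kg/m3

_T_MIN, _T_MAX = 290.0, 350.0
_P_MIN, _P_MAX = 60.0, 600.0

# --- residual Helmholtz energy: polynomial + exponential terms (i = 1..34) ---
_N = np.array([
    0.38856823203161e0, 0.29385475942740e1, -0.55867188534934e1,
    -0.76753199592477e0, 0.31729005580416e0, 0.54803315897767e0,
    0.12279411220335e0, 0.21658961543220e1, 0.15841735109724e1,
    -0.23132705405503e0, 0.58116916431436e-1, -0.55369137205382e0,
    0.48946615909422e0, -0.24275739843501e-1, 0.62494790501678e-1,
    -0.12175860225246e0, -0.37055685270086e0, -0.16775879700426e-1,
    -0.11960736637987e0, -0.45619362508778e-1, 0.35612789270346e-1,
    -0.74427727132052e-2, -0.17395704902432e-2, -0.21810121289527e-1,
    0.24332166559236e-1, -0.37440133423463e-1, 0.14338715756878e0,
    -0.13491969083286e0, -0.23151225053480e-1, 0.12363125492901e-1,
    0.21058321972940e-2, -0.33958519026368e-3, 0.55993651771592e-2,
    -0.30335118055646e-3,
])
_D = np.array([1, 1, 1, 1, 2, 2, 3, 1, 2, 4, 5, 5, 5, 6, 6, 6, 1, 1, 4, 4,
               4, 7, 8, 2, 3, 3, 5, 5, 6, 6, 7, 8, 8, 10], dtype=float)
_T_EXP = np.array([0.0, 0.75, 1.0, 2.0, 0.75, 2.0, 0.75, 1.5, 1.5, 2.5, 0.0,
                   1.5, 2.0, 0.0, 1.0, 2.0, 3.0, 6.0, 3.0, 6.0, 8.0, 6.0,
                   0.0, 7.0, 12.0, 16.0, 22.0, 24.0, 16.0, 24.0, 8.0, 2.0,
                   28.0, 14.0])
_C = np.array([0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2,
               2, 2, 2, 3, 3, 3, 4, 4, 4, 4, 4, 4, 4, 4], dtype=float)

# --- Gaussian bell terms (i = 35..39) ---
_NG = np.array([-0.21365488688320e3, 0.26641569149272e5, -0.24027212204557e5,
                -0.28341603423999e3, 0.21247284400179e3])
_DG = np.array([2.0, 2.0, 2.0, 3.0, 3.0])
_TG = np.array([1.0, 0.0, 1.0, 3.0, 3.0])
_ALPHA = np.array([25.0, 25.0, 25.0, 15.0, 20.0])
_BETA = np.array([325.0, 300.0, 300.0, 275.0, 275.0])
_GAMMA = np.array([1.16, 1.19, 1.19, 1.25, 1.22])
_EPS = np.array([1.0, 1.0, 1.0, 1.0, 1.0])

# --- non-analytic critical-region terms (i = 40..42) ---
_NN = np.array([-0.66642276540751e0, 0.72608632349897e0, 0.55068668612842e-1])
_AN = np.array([3.5, 3.5, 3.0])
_BN = np.array([0.875, 0.925, 0.875])
_BETAN = np.array([0.300, 0.300, 0.300])
_AAN = np.array([0.700, 0.700, 0.700])
_BBN = np.array([0.3, 0.3, 1.0])
_CCN = np.array([10.0, 10.0, 12.5])
_DDN = np.array([275.0, 275.0, 275.0])


def _alpha_r_delta(delta: float, tau: float) -> float:
    """d(alpha_r)/d(delta) at constant tau (dimensionless)."""
    d, t, c, n = _D, _T_EXP, _C, _N
    poly = n[:7] * d[:7] * delta ** (d[:7] - 1) * tau ** t[:7]
    e = np.exp(-(delta ** c[7:]))
    expo = (n[7:] * e * delta ** (d[7:] - 1) * tau ** t[7:]
            * (d[7:] - c[7:] * delta ** c[7:]))
    out = poly.sum() + expo.sum()

    dd = delta - _EPS
    tt = tau - _GAMMA
    g = _NG * delta ** _DG * tau ** _TG * np.exp(-_ALPHA * dd ** 2 - _BETA * tt ** 2)
    out += np.sum(g * (_DG / delta - 2.0 * _ALPHA * dd))

    # non-analytic terms: Delta^b * delta * psi with
    #   theta = (1 - tau) + A*((delta-1)^2)^(1/(2 beta))
    #   Delta = theta^2 + B*((delta-1)^2)^a
    dm1 = delta - 1.0
    dm1sq = dm1 * dm1
    if dm1sq == 0.0:
        # removable point: every delta-derivative factor carries (delta-1)
        theta = 1.0 - tau
        Delta = theta * theta
        psi = np.exp(-_DDN * (tau - 1.0) ** 2)
        out += np.sum(_NN * Delta ** _BN * psi)
        return float(out)
    theta = (1.0 - tau) + _AAN * dm1sq ** (1.0 / (2.0 * _BETAN))
    Delta = theta ** 2 + _BBN * dm1sq ** _AN
    psi = np.exp(-_CCN * dm1sq - _DDN * (tau - 1.0) ** 2)
    dpsi = -2.0 * _CCN * dm1 * psi
    dDelta = dm1 * (_AAN * theta * (2.0 / _BETAN) * dm1sq ** (1.0 / (2.0 * _BETAN) - 1.0)
                    + 2.0 * _BBN * _AN * dm1sq ** (_AN - 1.0))
    out += np.sum(_NN * (Delta ** _BN * (psi + delta * dpsi)
                         + _BN * Delta ** (_BN - 1.0) * dDelta * delta * psi))
    return float(out)


def pressure_from_density(T: float, rho: float) -> float:
    """Pressure (bar) of pure CO2 at temperature T (K) and density rho (kg/m3)."""
    delta = rho / RHO_CRIT
    tau = T_CRIT / T
    rho_molar = rho / _M_SW  # mol/m3
    p_pa = rho_molar * _R_SW * T * (1.0 + delta * _alpha_r_delta(delta, tau))
    return p_pa / 1.0e5


def saturation_pressure(T: float) -> float:
    """Ancillary vapor-pressure equation, bar (valid Tt..Tc)."""
    th = 1.0 - T / T_CRIT
    a = (-7.0602087 * th + 1.9391218 * th ** 1.5
         - 1.6463597 * th ** 2 - 3.2995634 * th ** 4)
    return P_CRIT * np.exp(a * T_CRIT / T)


def saturated_liquid_density(T: float) -> float:
    """Ancillary saturated-liquid density, kg/m3."""
    th = 1.0 - T / T_CRIT
    a = (1.9245108 * th ** 0.34 - 0.62385555 * th ** 0.5
         - 0.32731127 * th ** (10.0 / 6.0) + 0.39245142 * th ** (11.0 / 6.0))
    return RHO_CRIT * np.exp(a)


def saturated_vapor_density(T: float) -> float:
    """Ancillary saturated-vapor density, kg/m3."""
    th = 1.0 - T / T_CRIT
    a = (-1.7074879 * th ** 0.34 - 0.82274670 * th ** 0.5
         - 4.6008549 * th - 10.111178 * th ** (7.0 / 3.0)
         - 29.742252 * th ** (14.0 / 3.0))
    return RHO_CRIT * np.exp(a)


def _check_envelope(T: float, P: float) -> None:
    if not (_T_MIN <= T <= _T_MAX) or not (_P_MIN <= P <= _P_MAX):
        raise ValueError(
            f"(T={T} K, P={P} bar) outside the supported CO2 envelope "
            f"[{_T_MIN}, {_T_MAX}] K x [{_P_MIN}, {_P_MAX}] bar"
        )


def co2_density(T: float, P: float) -> float:
    """Density of pure CO2 (kg/m3) at T (K) and P (bar).

    Solves the Span-Wagner equation of state for the density of the stable
    phase.  Below the critical temperature the phase is chosen by comparing
    P with the saturation pressure; above it the isotherm is monotone and
    the root is unique.

    Raises
    ------
    ValueError
        If (T, P) falls outside 290-350 K or 60-600 bar.
    """
    T, P = float(T), float(P)
    _check_envelope(T, P)
    if T < T_CRIT:
        ps = saturation_pressure(T)
        if P > ps:
            lo = 0.995 * saturated_liquid_density(T)
            hi = 1600.0
        else:
            lo = 1e-6
            hi = 1.005 * saturated_vapor_density(T)
    else:
        lo, hi = 1e-6, 1400.0
    f = lambda rho: pressure_from_density(T, rho) - P
    # widen the liquid-side bracket if the ancillary start is slightly inside
    flo = f(lo)
    if flo > 0.0:
        lo *= 0.95
        flo = f(lo)
    if flo > 0.0 or f(hi) < 0.0:
        raise ValueError(f"no density root bracketed at T={T} K, P={P} bar")
    rho = brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16, maxiter=200)
    return float(rho)


@dataclass(frozen=True)
class FluidState:
    """CO2 state point: temperature (K), pressure (bar), density.

    ``rho_mass`` is in kg/m3; ``rho_molar`` (kmol/m3) is derived from it with
    M = 44.01 g/mol and is exact by construction.
    """

    T: float
    P: float
    rho_mass: float

    def __post_init__(self) -> None:
        if self.T <= 0 or self.P <= 0 or self.rho_mass <= 0:
            raise ValueError("FluidState requires positive T, P and density")

    @property
    def rho_molar(self) -> float:
        """Molar density in kmol/m3."""
        return self.rho_mass / M_CO2


def co2_state(T: float, P: float) -> FluidState:
    """Bundle (T, P) with the Span-Wagner CO2 density as a :class:`FluidState`."""
    return FluidState(T=float(T), P=float(P), rho_mass=co2_density(T, P))
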