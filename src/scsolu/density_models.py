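"""Semi-empirical density-based solubility correlations.

Five classic correlations link the mole-fraction solubility y2 of a solid
in supercritical CO2 to temperature and solvent density rho:

* **Chrastil** (association model): ``ln s = a + b/T + c ln rho`` with s the
  solute mass concentration (kg/m3); c is the association number and the
  1/T coefficient carries the total (vaporization + solvation) enthalpy,
  dH_total = -R b.
* **Modified Chrastil**: a bounded three-parameter form fitted by a global
  optimizer (the staged GA) directly on the mole-fraction AARD.
* **Mendez-Santiago-Teja (MST)**: ``T ln(y P/Pref) = a + b T + c rho`` with
  Pref = 1 bar; its single-line collapse underlies the self-consistency
  test.
* **Bartle**: ``ln(y P/Pref) = a + b/T + c (rho - rho_ref)``,
  rho_ref = 700 kg/m3, fitted with the two-stage average-slope procedure;
  dH_vap = -R b.
* **Kumar-Johnston (KJ)**: ``ln y = a + b/T + c rho_molar`` with the molar
  density in kmol/m3.

All linear fits are ordinary least squares in each model's transformed
space; fit quality is reported as AARD%/ARD%/MSE/R2 on mole fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .co2_properties import FluidState, M_CO2, R_GAS
from .optimizers import GAConfig, ga_staged_minimize
from .solubility_data import (
    SolubilityTable,
    mass_concentration,
    mole_fraction_from_mass_concentration,
)

__all__ = [
    "FitStatistics",
    "CorrelationFit",
    "EnthalpyResult",
    "fit_statistics",
    "fit_chrastil",
    "fit_mst",
    "fit_bartle",
    "fit_kj",
    "fit_modified_chrastil",
    "predict",
    "enthalpies",
    "MODEL_IDS",
]

MODEL_IDS = ("chrastil", "modified_chrastil", "mst", "bartle", "kj")

#: MST / Bartle reference pressure, bar (0.1 MPa)
P_REF = 1.0
#: Bartle reference density, kg/m3
RHO_REF = 700.0


@dataclass(frozen=True)
class FitStatistics:
    """Deviation statistics between experimental and calculated solubilities."""

    aard_pct: float
    ard_pct: float
    mse: float
    r2: float
    n: int


@dataclass
class CorrelationFit:
    """A fitted density-based correlation: identifier, (a, b, c), statistics."""

    model_id: str
    a: float
    b: float
    c: float
    M_solute: float
    stats: FitStatistics | None = None
    meta: dict = field(default_factory=dict)

    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass(frozen=True)
class EnthalpyResult:
    """Dissolution enthalpies (kJ/mol) from the Chrastil and Bartle fits."""

    dH_total: float
    dH_vaporization: float

    @property
    def dH_solvation(self) -> float:
        """Hess's law: solvation = total - vaporization."""
        return self.dH_total - self.dH_vaporization


def fit_statistics(y_exp: Sequence[float], y_calc: Sequence[float]) -> FitStatistics:
    """AARD%, ARD%, MSE and R2 of calculated vs experimental solubilities.

    AARD% = (100/N) sum |y_exp - y_calc| / y_exp ;
    ARD%  = (100/N) sum (y_exp - y_calc) / y_exp (signed bias);
    R2 uses the experimental mean as reference.
    """
    ye = np.asarray(y_exp, dtype=float)
    yc = np.asarray(y_calc, dtype=float)
    if ye.shape != yc.shape or ye.ndim != 1 or ye.size == 0:
        raise ValueError("y_exp and y_calc must be equal-length nonempty vectors")
    if np.any(ye == 0.0):
        raise ValueError("y_exp must be nonzero")
    rel = (ye - yc) / ye
    sstot = np.sum((ye - ye.mean()) ** 2)
    ssres = np.sum((ye - yc) ** 2)
    r2 = 1.0 - ssres / sstot if sstot > 0 else (1.0 if ssres == 0 else -np.inf)
    return FitStatistics(
        aard_pct=float(100.0 * np.mean(np.abs(rel))),
        ard_pct=float(100.0 * np.mean(rel)),
        mse=float(np.mean((ye - yc) ** 2)),
        r2=float(r2),
        n=int(ye.size),
    )


def _arrays(table: SolubilityTable, densities: Sequence[FluidState]):
    if len(densities) != len(table):
        raise ValueError("densities must align with table records")
    T = np.array([r.T for r in table])
    P = np.array([r.P for r in table])
    y = table.y()
    rho = np.array([s.rho_mass for s in densities])
    for s, r in zip(densities, table):
        if (s.T, s.P) != (r.T, r.P):
            raise ValueError(f"density state ({s.T}, {s.P}) does not match record ({r.T}, {r.P})")
    return T, P, y, rho


def _check_fittable(T: np.ndarray, rho: np.ndarray) -> None:
    if T.size < 4:
        raise ValueError("need at least 4 records to fit a three-parameter correlation")
    if np.unique(T).size < 2:
        raise ValueError("rank-deficient design: need at least 2 temperatures")
    if np.unique(rho).size < 2:
        raise ValueError("rank-deficient design: need at least 2 distinct densities")


def _ols(X: np.ndarray, z: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return coef


def fit_chrastil(table: SolubilityTable, densities: Sequence[FluidState]) -> CorrelationFit:
    """OLS fit of ln s = a + b/T + c ln rho; statistics on mole fractions."""
    T, P, y, rho = _arrays(table, densities)
    _check_fittable(T, rho)
    s = mass_concentration(y, rho, table.M_solute)
    X = np.column_stack([np.ones_like(T), 1.0 / T, np.log(rho)])
    a, b, c = _ols(X, np.log(s))
    fit = CorrelationFit("chrastil", float(a), float(b), float(c), table.M_solute,
                         meta={"density_source": "span-wagner"})
    yc = _predict_arrays(fit, T, P, rho)
    fit.stats = fit_statistics(y, yc)
    if not (0.0 < c < 20.0):
        fit.meta["warning"] = f"association number c={c:.3g} outside the usual (0, 20) range"
    return fit


def fit_mst(table: SolubilityTable, densities: Sequence[FluidState]) -> CorrelationFit:
    """OLS fit of T ln(y P/Pref) = a + b T + c rho, Pref = 1 bar."""
    T, P, y, rho = _arrays(table, densities)
    _check_fittable(T, rho)
    lhs = T * np.log(y * P / P_REF)
    X = np.column_stack([np.ones_like(T), T, rho])
    a, b, c = _ols(X, lhs)
    fit = CorrelationFit("mst", float(a), float(b), float(c), table.M_solute,
                         meta={"density_source": "span-wagner", "P_ref_bar": P_REF})
    fit.stats = fit_statistics(y, _predict_arrays(fit, T, P, rho))
    return fit


def fit_kj(table: SolubilityTable, densities: Sequence[FluidState]) -> CorrelationFit:
    """OLS fit of ln y = a + b/T + c rho_molar (kmol/m3)."""
    T, P, y, rho = _arrays(table, densities)
    _check_fittable(T, rho)
    X = np.column_stack([np.ones_like(T), 1.0 / T, rho / M_CO2])
    a, b, c = _ols(X, np.log(y))
    fit = CorrelationFit("kj", float(a), float(b), float(c), table.M_solute,
                         meta={"density_source": "span-wagner"})
    fit.stats = fit_statistics(y, _predict_arrays(fit, T, P, rho))
    return fit


def fit_bartle(table: SolubilityTable, densities: Sequence[FluidState]) -> CorrelationFit:
    """Two-stage average-slope fit of ln(y P/Pref) = a + b/T + c (rho - rho_ref).

    Stage 1 regresses ln(y P/Pref) on (rho - 700) within each isotherm and
    averages the slopes into c.  The isotherm intercepts are then recomputed
    with the slope held at c, and stage 2 regresses those intercepts on 1/T
    to give a and b.  (With a free per-isotherm slope in stage 2 the
    intercepts absorb slope scatter and the final correlation degrades;
    holding the common slope is what makes the averaging meaningful.)
    """
    T, P, y, rho = _arrays(table, densities)
    temps = np.unique(T)
    if temps.size < 2:
        raise ValueError("need at least 2 isotherms")
    lhs = np.log(y * P / P_REF)
    slopes = {}
    for Ti in temps:
        m = T == Ti
        if m.sum() < 3:
            raise ValueError(f"isotherm {Ti} K has fewer than 3 points")
        A = np.column_stack([np.ones(m.sum()), rho[m] - RHO_REF])
        icpt, slope = _ols(A, lhs[m])
        slopes[float(Ti)] = float(slope)
    c = float(np.mean(list(slopes.values())))
    intercepts = {float(Ti): float(np.mean(lhs[T == Ti] - c * (rho[T == Ti] - RHO_REF)))
                  for Ti in temps}
    A2 = np.column_stack([np.ones(temps.size), 1.0 / temps])
    a, b = _ols(A2, np.array([intercepts[float(Ti)] for Ti in temps]))
    fit = CorrelationFit("bartle", float(a), float(b), c, table.M_solute,
                         meta={"density_source": "span-wagner",
                               "isotherm_slopes": slopes,
                               "isotherm_intercepts": intercepts,
                               "P_ref_bar": P_REF, "rho_ref": RHO_REF})
    fit.stats = fit_statistics(y, _predict_arrays(fit, T, P, rho))
    return fit


def _modified_chrastil_y(a: float, b: float, c: float, T: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Bounded modified-Chrastil solubility with f0 = 1 and D in kg/m3.

    W = (R T D / f0)^(c-1) exp(a + b/T); y = Q / (1 + c Q) with Q = W/(1+W).
    Rescaling D's units only shifts the fitted a by (c-1) ln k.
    """
    lnW = (c - 1.0) * np.log(R_GAS * T * D) + a + b / T
    W = np.exp(np.clip(lnW, -700.0, 700.0))
    Q = W / (1.0 + W)
    return Q / (1.0 + c * Q)


DEFAULT_EQ14_BOUNDS = ((-80.0, 20.0), (-20000.0, 5000.0), (1.01, 15.0))


def fit_modified_chrastil(
    table: SolubilityTable,
    densities: Sequence[FluidState],
    config: GAConfig | None = None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_EQ14_BOUNDS,
) -> CorrelationFit:
    """Fit the modified Chrastil model by minimizing AARD% with the staged GA."""
    T, P, y, rho = _arrays(table, densities)
    _check_fittable(T, rho)

    def objective(params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        out = np.empty(params.shape[0])
        for i, (a, b, c) in enumerate(params):
            yc = _modified_chrastil_y(a, b, c, T, rho)
            out[i] = 100.0 * np.mean(np.abs(y - yc) / y)
        return out if out.size > 1 else out

    cfg = config or GAConfig()
    res = ga_staged_minimize(lambda X: objective(X), bounds, cfg, vectorized=True)
    a, b, c = res.x
    fit = CorrelationFit("modified_chrastil", float(a), float(b), float(c), table.M_solute,
                         meta={"density_source": "span-wagner", "optimizer_seed": cfg.seed,
                               "achieved_aard_pct": res.fun, "f0": 1.0,
                               "ga_stages": res.meta.get("stages")})
    fit.stats = fit_statistics(y, _predict_arrays(fit, T, P, rho))
    return fit


def _predict_arrays(fit: CorrelationFit, T: np.ndarray, P: np.ndarray,
                    rho: np.ndarray) -> np.ndarray:
    a, b, c = fit.a, fit.b, fit.c
    if fit.model_id == "chrastil":
        s = np.exp(a + b / T + c * np.log(rho))
        return mole_fraction_from_mass_concentration(s, rho, fit.M_solute)
    if fit.model_id == "mst":
        return (P_REF / P) * np.exp((a + b * T + c * rho) / T)
    if fit.model_id == "bartle":
        return (P_REF / P) * np.exp(a + b / T + c * (rho - RHO_REF))
    if fit.model_id == "kj":
        return np.exp(a + b / T + c * rho / M_CO2)
    if fit.model_id == "modified_chrastil":
        return _modified_chrastil_y(a, b, c, T, rho)
    raise ValueError(f"unknown model_id {fit.model_id!r}")


def predict(fit: CorrelationFit, T: float, P: float, state: FluidState) -> float:
    """Mole-fraction solubility predicted by a fitted correlation at (T, P)."""
    if (state.T, state.P) != (T, P):
        raise ValueError("FluidState does not correspond to the requested (T, P)")
    out = _predict_arrays(fit, np.atleast_1d(float(T)), np.atleast_1d(float(P)),
                          np.atleast_1d(state.rho_mass))
    return float(out[0])


def predict_table(fit: CorrelationFit, table: SolubilityTable,
                  densities: Sequence[FluidState]) -> np.ndarray:
    """Vectorized :func:`predict` over a whole table."""
    T, P, _, rho = _arrays(table, densities)
    return _predict_arrays(fit, T, P, rho)


def enthalpies(chrastil_fit: CorrelationFit, bartle_fit: CorrelationFit) -> EnthalpyResult:
    """Dissolution enthalpies from the 1/T coefficients of two fits.

    dH_total = -R b_chrastil, dH_vap = -R b_bartle (kJ/mol); the solvation
    enthalpy follows by Hess's law as their difference.
    """
    if chrastil_fit.model_id != "chrastil" or bartle_fit.model_id != "bartle":
        raise ValueError("expected a chrastil fit and a bartle fit")
    return EnthalpyResult(
        dH_total=-R_GAS * chrastil_fit.b / 1000.0,
        dH_vaporization=-R_GAS * bartle_fit.b / 1000.0,
    )
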