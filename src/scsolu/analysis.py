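"""Derived analyses: crossover pressure, MST self-consistency, model ranking.

The *crossover pressure* is where the temperature dependence of solubility
reverses: below it the loss of solvent density with temperature dominates
(y falls with T along an isobar), above it the growing sublimation pressure
dominates (y rises with T).  It is reported as a tabulated grid pressure —
the data grid is coarse, and interpolating fitted isotherms would
manufacture precision.

The *self-consistency test* collapses all isotherms onto a single line in
MST coordinates, T ln(y P/Pref) - b T vs. rho; a high pooled R2 supports
the correlation's functional form and its use for modest extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .co2_properties import FluidState
from .density_models import (
    CorrelationFit,
    P_REF,
    enthalpies,
    fit_bartle,
    fit_chrastil,
    fit_kj,
    fit_modified_chrastil,
    fit_mst,
)
from .optimizers import GAConfig
from .solubility_data import SolubilityTable

__all__ = [
    "CrossoverResult",
    "SelfConsistencyResult",
    "crossover_pressure",
    "self_consistency_mst",
    "compare_models",
]


@dataclass(frozen=True)
class CrossoverResult:
    """Crossover pressure (bar, or None) and per-pressure y-vs-T trend signs."""

    pressure: float | None
    per_pressure_trend: dict[float, int]


@dataclass(frozen=True)
class SelfConsistencyResult:
    r2_collapsed: float
    per_isotherm_residual_spread: dict[float, float]
    extrapolation_residuals: tuple[float, ...] = ()


def crossover_pressure(table: SolubilityTable) -> CrossoverResult:
    """Locate the crossover pressure from isobaric temperature trends.

    For every pressure shared by at least two isotherms the y-vs-T sequence
    is classified as strictly decreasing (-1), strictly increasing (+1) or
    non-monotone (0).  The crossover is the highest pressure with trend -1,
    provided some higher shared pressure trends +1; otherwise None.
    """
    temps = table.temperatures
    if len(temps) < 2:
        raise ValueError("need at least 2 isotherms")
    by_pressure: dict[float, list[tuple[float, float]]] = {}
    for r in table:
        by_pressure.setdefault(r.P, []).append((r.T, r.y2))
    trends: dict[float, int] = {}
    for p, pts in sorted(by_pressure.items()):
        if len(pts) < 2:
            continue
        ys = [y for _, y in sorted(pts)]
        d = np.diff(ys)
        trends[p] = -1 if np.all(d < 0) else (1 if np.all(d > 0) else 0)
    ps = sorted(trends)
    crossing = None
    for p in ps:
        if trends[p] == -1 and any(trends[q] == 1 for q in ps if q > p):
            crossing = p
    return CrossoverResult(pressure=crossing, per_pressure_trend=trends)


def self_consistency_mst(
    fit: CorrelationFit,
    table: SolubilityTable,
    densities: Sequence[FluidState],
    extrapolation_states: Sequence[tuple[FluidState, float]] | None = None,
) -> SelfConsistencyResult:
    """Pooled single-line collapse of the MST correlation.

    Computes z = T ln(y P / Pref) - b T for every record and regresses z on
    rho across all isotherms together; ``r2_collapsed`` is that line's R2.
    Optional (state, y) pairs outside the fitted range are scored as
    residuals against the same line.
    """
    if fit.model_id != "mst":
        raise ValueError("self-consistency test requires an MST fit")
    T = np.array([r.T for r in table])
    P = np.array([r.P for r in table])
    y = table.y()
    rho = np.array([s.rho_mass for s in densities])
    z = T * np.log(y * P / P_REF) - fit.b * T
    X = np.column_stack([np.ones_like(rho), rho])
    coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    pred = X @ coef
    sstot = np.sum((z - z.mean()) ** 2)
    r2 = 1.0 - np.sum((z - pred) ** 2) / sstot if sstot > 0 else 1.0
    spread = {}
    for Ti in table.temperatures:
        m = T == Ti
        spread[float(Ti)] = float(np.std(z[m] - pred[m]))
    extras = ()
    if extrapolation_states:
        extras = tuple(
            float((st.T * np.log(yv * st.P / P_REF) - fit.b * st.T)
                  - (coef[0] + coef[1] * st.rho_mass))
            for st, yv in extrapolation_states
        )
    return SelfConsistencyResult(r2_collapsed=float(r2),
                                 per_isotherm_residual_spread=spread,
                                 extrapolation_residuals=extras)


def compare_models(
    table: SolubilityTable,
    densities: Sequence[FluidState],
    seed: int = 0,
    ga_config: GAConfig | None = None,
) -> dict:
    """Fit all five correlations and rank them by AARD%.

    Returns a JSON-ready report: ranked model list with parameters and
    statistics, dissolution enthalpies, and the crossover annotation.
    """
    cfg = ga_config or GAConfig(seed=seed)
    fits = {
        "chrastil": fit_chrastil(table, densities),
        "mst": fit_mst(table, densities),
        "bartle": fit_bartle(table, densities),
        "kj": fit_kj(table, densities),
        "modified_chrastil": fit_modified_chrastil(table, densities, cfg),
    }
    ranked = sorted(fits.values(), key=lambda f: f.stats.aard_pct)
    dh = enthalpies(fits["chrastil"], fits["bartle"])
    xover = crossover_pressure(table)
    return {
        "solute": table.solute_name,
        "n_records": len(table),
        "seed": seed,
        "ranking": [f.model_id for f in ranked],
        "models": {
            f.model_id: {
                "a": f.a, "b": f.b, "c": f.c,
                "aard_pct": f.stats.aard_pct,
                "ard_pct": f.stats.ard_pct,
                "mse": f.stats.mse,
                "r2": f.stats.r2,
                "n": f.stats.n,
            }
            for f in fits.values()
        },
        "enthalpies_kJ_mol": {
            "total": dh.dH_total,
            "vaporization": dh.dH_vaporization,
            "solvation": dh.dH_solvation,
        },
        "crossover_pressure_bar": xover.pressure,
        "pressure_trends": {str(k): v for k, v in xover.per_pressure_trend.items()},
    }
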