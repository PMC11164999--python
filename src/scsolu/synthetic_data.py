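"""Synthetic solubility tables with known ground truth.

Every fitting and analysis stage of the package is testable without any
measurement: a forward model (one of the five correlations, or the EoS
route) is evaluated on a (T, P) grid and corrupted with multiplicative
lognormal noise whose coefficient of variation mirrors the few-percent
relative scatter of triplicate gravimetric measurements.  The generator
mirrors the structure of the measured lumiracoxib table by default: a
4 x 8 grid with one missing near-critical cell and noise CV of 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .co2_properties import FluidState, co2_state
from .density_models import CorrelationFit, _predict_arrays
from .solubility_data import SolubilityRecord, SolubilityTable

__all__ = ["SyntheticSpec", "generate_table", "generate_crossover_surface",
            "DEFAULT_GRID", "table3_mimic_spec"]

#: the measured lumiracoxib grid: 4 isotherms x 8 isobars
DEFAULT_GRID = (
    (308.15, 318.15, 328.15, 338.15),
    (120.0, 160.0, 200.0, 240.0, 280.0, 320.0, 360.0, 400.0),
)


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic solubility surface."""

    generator_model: str
    true_params: tuple[float, float, float]
    grid: tuple[Sequence[float], Sequence[float]] = DEFAULT_GRID
    noise_cv: float = 0.05
    seed: int = 0
    dropout: frozenset = frozenset()
    M_solute: float = 293.72
    solute_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.grid[0] or not self.grid[1]:
            raise ValueError("grid must be non-empty")


def table3_mimic_spec(seed: int = 0, noise_cv: float = 0.05) -> SyntheticSpec:
    """A Chrastil surface spanning ~5e-5..3.5e-4 on the measured grid.

    Parameters are chosen so the noiseless surface covers the same
    mole-fraction range as the measured lumiracoxib data, with the
    (338.15 K, 120 bar) cell dropped.
    """
    return SyntheticSpec(
        generator_model="chrastil",
        true_params=(-22.6, -2960.0, 4.75),
        noise_cv=noise_cv,
        seed=seed,
        dropout=frozenset({(338.15, 120.0)}),
    )


def _grid_states(spec: SyntheticSpec, densities=None) -> list[FluidState]:
    cells = [(T, P) for T in spec.grid[0] for P in spec.grid[1]
             if (T, P) not in spec.dropout]
    if densities is not None:
        lookup = {(s.T, s.P): s for s in densities}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise ValueError(f"no density provided for grid cells {missing}")
        return [lookup[c] for c in cells]
    return [co2_state(T, P) for T, P in cells]


def generate_table(spec: SyntheticSpec, densities: Sequence[FluidState] | None = None
                   ) -> tuple[SolubilityTable, dict]:
    """Evaluate the forward model on the grid and apply lognormal noise.

    The noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` and unit mean (the mean-one correction exp(-sigma^2/2) is
    applied), so averaging replicates converges to the noiseless surface.
    Returns the table and a ground-truth record.
    """
    states = _grid_states(spec, densities)
    T = np.array([s.T for s in states])
    P = np.array([s.P for s in states])
    rho = np.array([s.rho_mass for s in states])
    a, b, c = spec.true_params
    fit = CorrelationFit(spec.generator_model, a, b, c, spec.M_solute)
    y0 = _predict_arrays(fit, T, P, rho)
    bad = ~((y0 > 0.0) & (y0 < 1.0))
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"parameters yield unphysical y={y0[i]:.3g} at cell "
            f"(T={T[i]}, P={P[i]})"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv ** 2))
        noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=y0.size)
    else:
        noise = np.ones_like(y0)
    y = np.clip(y0 * noise, 1e-300, 1.0 - 1e-12)
    records = [
        SolubilityRecord(T=float(t), P=float(p), y2=float(yv),
                         u_y=float(spec.noise_cv * yv))
        for t, p, yv in zip(T, P, y)
    ]
    table = SolubilityTable(solute_name=spec.solute_name, M_solute=spec.M_solute,
                            records=records)
    truth = {
        "generator_model": spec.generator_model,
        "true_params": tuple(spec.true_params),
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "noiseless_y": y0.tolist(),
    }
    return table, truth


def generate_crossover_surface(
    boundary_bar: float,
    grid: tuple[Sequence[float], Sequence[float]] = DEFAULT_GRID,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> SolubilityTable:
    """Construct isotherms whose y-vs-T trend flips sign at ``boundary_bar``.

    Pressures at or below the boundary decrease with temperature (density
    effect dominant); higher pressures increase (sublimation-pressure
    effect dominant), so :func:`crossover_pressure` must return the
    boundary grid pressure.  Raises for a single-pressure grid.
    """
    temps, pressures = grid
    if len(pressures) < 2:
        raise ValueError("crossover surface needs at least 2 grid pressures")
    if len(temps) < 2:
        raise ValueError("crossover surface needs at least 2 isotherms")
    pressures = sorted(pressures)
    temps = sorted(temps)
    rng = np.random.default_rng(seed)
    records = []
    t0 = temps[0]
    for p in pressures:
        base = 1e-4 * (p / pressures[0]) ** 0.8
        # fractional change per kelvin, matching the ~2%/K magnitude of the
        # measured isobars: negative below/at the boundary, positive above
        slope = -0.02 if p <= boundary_bar else +0.02
        for T in temps:
            y = base * (1.0 + slope * (T - t0))
            if noise_cv > 0:
                sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
                y *= rng.lognormal(-0.5 * sigma * sigma, sigma)
            records.append(SolubilityRecord(T=float(T), P=float(p), y2=float(y),
                                            u_y=float(noise_cv * y) if noise_cv else None))
    return SolubilityTable(solute_name="synthetic-crossover", M_solute=293.72,
                           records=records)
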