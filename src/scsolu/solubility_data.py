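"""Solubility data model, unit conversions and CSV I/O.

A solubility table is a collection of (T, P, y2) equilibrium measurements of
a solid drug dissolved in supercritical CO2, with optional standard
uncertainties.  Two measured tables ship with the package as CSV fixtures:
the 31-point lumiracoxib data set (four isotherms, 308.15-338.15 K,
120-400 bar) and the 6-point nimesulide validation set.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .co2_properties import M_CO2

__all__ = [
    "SolubilityRecord",
    "SolubilityTable",
    "mole_fraction_from_amounts",
    "mass_concentration",
    "mole_fraction_from_mass_concentration",
    "load_table",
    "write_table",
    "lumiracoxib_table",
    "nimesulide_table",
]

_CSV_COLUMNS = ["T_K", "P_bar", "y2", "u_y"]


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium measurement: T (K), P (bar), mole fraction y2, u(y2)."""

    T: float
    P: float
    y2: float
    u_y: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.y2 < 1.0):
            raise ValueError(f"mole fraction y2={self.y2} outside (0, 1)")
        if self.u_y is not None and self.u_y < 0:
            raise ValueError("uncertainty u_y must be non-negative")


@dataclass
class SolubilityTable:
    """An ordered set of solubility records for one solute.

    (T, P) pairs must be unique; missing grid cells are simply absent rows.
    """

    solute_name: str
    M_solute: float
    records: list[SolubilityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.M_solute <= 0:
            raise ValueError("M_solute must be positive (g/mol)")
        seen = set()
        for r in self.records:
            key = (r.T, r.P)
            if key in seen:
                raise ValueError(f"duplicate (T, P) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityRecord]:
        return iter(self.records)

    @property
    def temperatures(self) -> list[float]:
        """Sorted distinct temperatures (the isotherms)."""
        return sorted({r.T for r in self.records})

    def isotherm(self, T: float) -> list[SolubilityRecord]:
        """Records at temperature T, sorted by pressure."""
        return sorted((r for r in self.records if r.T == T), key=lambda r: r.P)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": [r.T for r in self.records],
                "P_bar": [r.P for r in self.records],
                "y2": [r.y2 for r in self.records],
                "u_y": [r.u_y if r.u_y is not None else np.nan for r in self.records],
            }
        )

    def y(self) -> np.ndarray:
        """Mole-fraction solubilities as an array, in record order."""
        return np.array([r.y2 for r in self.records])


def mole_fraction_from_amounts(n_drug: float, n_co2: float) -> float:
    """Mole-fraction solubility y2 = n_drug / (n_drug + n_co2).

    This is how the gravimetric measurement is reduced: the dissolved drug
    mass and the CO2 charge are converted to moles and ratioed.
    """
    if n_co2 <= 0:
        raise ValueError("n_co2 must be positive")
    if n_drug < 0:
        raise ValueError("n_drug must be non-negative")
    return n_drug / (n_drug + n_co2)


def mass_concentration(y2: float, rho_co2: float, M_solute: float) -> float:
    """Solute mass concentration s (kg/m3) from mole fraction.

    s = rho_CO2 * y2 * M_solute / ((1 - y2) * M_CO2); the form used by the
    Chrastil correlation, whose dependent variable is ln s.
    """
    y2 = np.asarray(y2, dtype=float)
    if np.any(y2 >= 1.0) or np.any(y2 <= 0.0):
        raise ValueError("y2 must lie in (0, 1)")
    return rho_co2 * y2 * M_solute / ((1.0 - y2) * M_CO2)


def mole_fraction_from_mass_concentration(s: float, rho_co2: float, M_solute: float) -> float:
    """Invert :func:`mass_concentration`: y2 = (s/M_s) / (s/M_s + rho/M_CO2)."""
    n_ratio = np.asarray(s, dtype=float) / M_solute
    return n_ratio / (n_ratio + rho_co2 / M_CO2)


class SolubilityParseError(ValueError):
    """CSV did not parse into a valid solubility table."""


def load_table(path: str | Path, solute_name: str = "", M_solute: float = 1.0) -> SolubilityTable:
    """Read a solubility table from CSV with header ``T_K,P_bar,y2[,u_y]``.

    Raises :class:`SolubilityParseError` with the offending row number for
    duplicate state points, non-numeric cells or out-of-range mole fractions.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SolubilityParseError(f"{path}: empty file") from exc
    missing = [c for c in ("T_K", "P_bar", "y2") if c not in df.columns]
    if missing:
        raise SolubilityParseError(f"{path}: missing required columns {missing}")
    if "u_y" not in df.columns:
        df["u_y"] = np.nan
    records = []
    seen = set()
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            T, P, y2 = float(row["T_K"]), float(row["P_bar"]), float(row["y2"])
            u = float(row["u_y"])
        except (TypeError, ValueError) as exc:
            raise SolubilityParseError(f"{path}:{rownum}: non-numeric cell") from exc
        if not (0.0 < y2 < 1.0):
            raise SolubilityParseError(f"{path}:{rownum}: y2={y2} outside (0, 1)")
        if (T, P) in seen:
            raise SolubilityParseError(f"{path}:{rownum}: duplicate (T, P)=({T}, {P})")
        seen.add((T, P))
        records.append(SolubilityRecord(T=T, P=P, y2=y2, u_y=None if np.isnan(u) else u))
    return SolubilityTable(solute_name=solute_name, M_solute=M_solute, records=records)


def write_table(table: SolubilityTable, path: str | Path) -> None:
    """Write a table to CSV (full precision, '.' decimal separator)."""
    df = table.to_frame()
    # default formatting writes the shortest round-trip representation
    df.to_csv(path, index=False)


def _fixture_path(name: str) -> Path:
    return Path(str(importlib.resources.files("scsolu.data").joinpath(name)))


def lumiracoxib_table() -> SolubilityTable:
    """The packaged 31-point lumiracoxib solubility table (M = 293.72 g/mol)."""
    return load_table(_fixture_path("lumiracoxib_table3.csv"),
                      solute_name="lumiracoxib", M_solute=293.72)


def nimesulide_table() -> SolubilityTable:
    """The packaged 6-point nimesulide validation table (M = 308.31 g/mol)."""
    return load_table(_fixture_path("nimesulide_table2.csv"),
                      solute_name="nimesulide", M_solute=308.31)


def nimesulide_reference_values() -> pd.DataFrame:
    """Nimesulide comparison set: this-work vs. literature mole fractions.

    Returns a frame with columns T_K, P_bar, y2_work, y2_lit used to
    validate the gravimetric apparatus against earlier measurements.
    """
    df = pd.read_csv(_fixture_path("nimesulide_table2.csv"))
    return df.rename(columns={"y2": "y2_work"})
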