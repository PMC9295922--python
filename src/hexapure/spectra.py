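"""Reflectance/irradiance spectra: container, CSV I/O, resampling.

All model computations in this package happen on a common wavelength grid.
The canonical grid is 300–700 nm inclusive at 1-nm steps (401 points),
covering the range over which flower reflectance is spectrally modulated
and bee photoreceptors are sensitive. The endpoints are conventional rather
than physically privileged, so the grid is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "canonical_grid",
    "read_spectra",
    "write_spectra",
    "resample",
]

SpectrumKind = Literal["reflectance", "irradiance", "sensitivity"]

#: Fractional reflectance slightly above 1 is tolerated (measurement noise)
#: and clipped; anything above this is treated as a unit mistake.
REFLECTANCE_CLIP_LIMIT = 1.05


def canonical_grid(start: float = 300.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """Wavelength grid in nm, inclusive of both endpoints."""
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    if grid[-1] > stop + 1e-9:
        grid = grid[grid <= stop + 1e-9]
    return grid


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm.
    values
        Non-negative samples: reflectance fraction in [0, 1], irradiance in
        arbitrary quantum units, or dimensionless sensitivity.
    kind
        One of ``"reflectance"``, ``"irradiance"``, ``"sensitivity"``.
    label
        Identifier (CSV column header on round trips).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "reflectance"
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError(
                f"spectrum {self.label!r}: wavelengths and values must be "
                f"1-D and equal length (got {wl.shape} vs {vals.shape})"
            )
        if wl.size < 2:
            raise ValueError(f"spectrum {self.label!r}: need at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(
                f"spectrum {self.label!r}: wavelengths must be strictly increasing"
            )
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"spectrum {self.label!r}: non-finite values")
        if np.any(vals < 0):
            raise ValueError(f"spectrum {self.label!r}: negative values")
        if self.kind == "reflectance" and np.any(vals > 1.0):
            vmax = float(vals.max())
            if vmax <= REFLECTANCE_CLIP_LIMIT:
                warnings.warn(
                    f"spectrum {self.label!r}: reflectance up to {vmax:.4f} "
                    "clipped to 1 (assumed measurement noise)",
                    stacklevel=2,
                )
                object.__setattr__(self, "values", np.minimum(vals, 1.0))
            else:
                raise ValueError(
                    f"spectrum {self.label!r}: reflectance {vmax:.4f} > "
                    f"{REFLECTANCE_CLIP_LIMIT}; check units (percent vs fraction)"
                )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at a single wavelength (no extrapolation)."""
        wl = self.wavelengths_nm
        if not (wl[0] - 1e-9 <= wavelength_nm <= wl[-1] + 1e-9):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside measured range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, wl, self.values))

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)


def _normalize_units(
    values: np.ndarray, unit_hint: str, column: str
) -> np.ndarray:
    if unit_hint == "fraction":
        return values
    if unit_hint == "percent":
        return values / 100.0
    if unit_hint == "auto":
        # Percent data is recognisable: fractional reflectance never
        # meaningfully exceeds 1.
        if np.nanmax(values) > 1.5:
            return values / 100.0
        return values
    raise ValueError(f"unknown unit_hint {unit_hint!r} for column {column!r}")


def read_spectra(
    path: str | Path,
    unit_hint: Literal["fraction", "percent", "auto"] = "auto",
    kind: SpectrumKind = "reflectance",
) -> list[Spectrum]:
    """Read a wide CSV of spectra: a ``wavelength`` column plus one column
    per stimulus.

    Percent-scaled columns (``unit_hint="auto"``: any value > 1.5) are
    rescaled to fractions, per column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column plus >=1 stimulus column")
    for col in df.columns:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            row = int(bad.index[0]) + 2  # 1-based, plus header line
            raise ValueError(
                f"{path}: non-numeric cell in column {col!r} at file line {row}"
            )
        if df[col].isna().any():
            row = int(df[df[col].isna()].index[0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at file line {row}")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError(f"{path}: wavelength column must be strictly increasing")
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"{path}: negative values in column {col!r}")
        vals = _normalize_units(vals, unit_hint, col)
        out.append(Spectrum(wl, vals, kind=kind, label=str(col)))
    return out


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing one wavelength grid to a wide CSV."""
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if len(s) != len(spectra[0]) or not np.allclose(s.wavelengths_nm, wl):
            raise ValueError("all spectra must share one wavelength grid")
    data = {"wavelength": wl}
    for s in spectra:
        data[s.label or f"s{len(data)}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def resample(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linear interpolation onto ``grid``; no extrapolation."""
    grid = np.asarray(list(grid), dtype=float)
    wl = s.wavelengths_nm
    if grid[0] < wl[0] - 1e-9 or grid[-1] > wl[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] nm exceeds measured range "
            f"[{wl[0]}, {wl[-1]}] nm of spectrum {s.label!r}; "
            "extrapolation is not performed"
        )
    return Spectrum(grid, np.interp(grid, wl, s.values), kind=s.kind, label=s.label)


def ensure_on_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Return ``s`` itself when already on ``grid``, else resample."""
    if len(s) == grid.size and np.allclose(s.wavelengths_nm, grid):
        return s
    return resample(s, grid)
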