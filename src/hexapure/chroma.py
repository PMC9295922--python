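"""Vision-model-independent "chroma" of a reflectance spectrum.

The statistic widely used in the pollination literature:
``chroma = (R_max − R_min) / R_mean`` over a stated wavelength range. It is
computed from the reflectance spectrum alone — no photoreceptors, illuminant
or background enter — so it is identical for any observer, and it depends on
the wavelength range chosen for the computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = ["ChromaResult", "endler_chroma"]


@dataclass(frozen=True)
class ChromaResult:
    r_max: float
    r_min: float
    r_mean: float
    chroma: float
    range_nm: tuple[float, float]


def endler_chroma(
    s: Spectrum, range_nm: tuple[float, float] = (300.0, 700.0)
) -> ChromaResult:
    """``(R_max − R_min)/R_mean`` over grid points within ``range_nm``
    (endpoints inclusive; unweighted mean, which on a uniform grid equals
    the integral mean).

    Scale-invariant: chroma(k·R) = chroma(R), so the overall brightness of
    the spectrum does not matter. Zero iff the spectrum is constant on the
    range. An all-zero spectrum has no defined chroma.
    """
    low, high = range_nm
    wl = s.wavelengths_nm
    if low < wl[0] - 1e-9 or high > wl[-1] + 1e-9:
        raise ValueError(
            f"range [{low}, {high}] nm not covered by spectrum "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    mask = (wl >= low - 1e-9) & (wl <= high + 1e-9)
    vals = s.values[mask]
    r_mean = float(vals.mean())
    if r_mean <= 0:
        raise ValueError(
            f"spectrum {s.label!r} is zero over [{low}, {high}] nm; "
            "chroma undefined (zero mean reflectance)"
        )
    r_max = float(vals.max())
    r_min = float(vals.min())
    return ChromaResult(
        r_max=r_max,
        r_min=r_min,
        r_mean=r_mean,
        chroma=(r_max - r_min) / r_mean,
        range_nm=(float(low), float(high)),
    )
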