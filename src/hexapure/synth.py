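"""Synthetic flower and leaf reflectance spectra.

Flower colour arises from two separable optical processes: wavelength-
selective absorption by pigments (sets hue and colourfulness) and broadband
backscattering by petal structures (sets brightness). The generator mirrors
this with a Beer–Lambert-style model

    R(λ) = S · exp(−c · A(λ))

where S is the scattering level, c the pigment amount, and A(λ) a fixed
absorbance profile per colour class. Four classes emulate common flower
colour types: white (weak UV-absorbing sigmoid edge), yellow (UV/blue-
absorbing sigmoid), purple/blue (mid-wavelength absorbance band), and
UV-reflecting red (absorbing the mid range, transmitting in the UV and far
red). Increasing c deepens absorption and hence colourfulness; S scales
brightness without changing spectral shape.

Additive Gaussian measurement noise (clipped to [0, 1]) emulates
spectrometer output. Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, canonical_grid

__all__ = ["FloraConfig", "COLOUR_CLASSES", "flower_spectrum", "generate_flora"]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(lam: np.ndarray, mu: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - mu) / width) ** 2))


# Absorbance profiles A(λ), unit peak height; parameters versioned here so a
# change in class shape is an explicit, reviewable edit.
CLASS_PARAMS: dict[str, dict[str, float]] = {
    # weak UV absorbance tail with a sigmoid edge near 380 nm
    "white_sigmoid": {"edge_nm": 380.0, "slope_nm": 25.0, "amplitude": 0.5},
    # unit absorbance below an inflection near 500 nm
    "yellow_uv_absorbing": {"edge_nm": 500.0, "slope_nm": 20.0, "amplitude": 1.0},
    # Gaussian absorbance band centred ~540 nm, width ~60 nm
    "band_purple_blue": {"centre_nm": 540.0, "width_nm": 60.0, "amplitude": 1.0},
    # absorbing 400–600 nm, transmitting in the UV and above ~620 nm
    "uv_red": {"rise_nm": 390.0, "fall_nm": 610.0, "slope_nm": 15.0, "amplitude": 1.0},
}

COLOUR_CLASSES = tuple(CLASS_PARAMS)


def _absorbance(colour_class: str, lam: np.ndarray) -> np.ndarray:
    p = CLASS_PARAMS.get(colour_class)
    if p is None:
        raise ValueError(
            f"unknown colour class {colour_class!r}; available: {COLOUR_CLASSES}"
        )
    if colour_class in ("white_sigmoid", "yellow_uv_absorbing"):
        return p["amplitude"] * _logistic((p["edge_nm"] - lam) / p["slope_nm"])
    if colour_class == "band_purple_blue":
        return p["amplitude"] * _gauss(lam, p["centre_nm"], p["width_nm"])
    # uv_red: double sigmoid — high between rise and fall, low outside
    return (
        p["amplitude"]
        * _logistic((lam - p["rise_nm"]) / p["slope_nm"])
        * _logistic((p["fall_nm"] - lam) / p["slope_nm"])
    )


def flower_spectrum(
    colour_class: str,
    pigment_amount: float,
    scatter: float,
    grid: np.ndarray | None = None,
    label: str = "",
) -> Spectrum:
    """Noise-free flower reflectance ``R(λ) = scatter·exp(−c·A(λ))``."""
    if pigment_amount < 0:
        raise ValueError("pigment_amount must be >= 0")
    if not (0 < scatter <= 1):
        raise ValueError("scatter must be in (0, 1]")
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    vals = scatter * np.exp(-pigment_amount * _absorbance(colour_class, grid))
    return Spectrum(grid, vals, kind="reflectance", label=label or colour_class)


@dataclass(frozen=True)
class FloraConfig:
    """Study conditions for a synthetic flora.

    Defaults: 200 flowers in equal class proportions, pigment amounts
    uniform on [0.3, 6] (near-achromatic through strongly coloured), scatter
    uniform on [0.3, 0.9], spectrometer-like additive noise of sd 0.005.
    """

    n_flowers: int = 200
    class_mix: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in COLOUR_CLASSES}
    )
    pigment_amount_range: tuple[float, float] = (0.3, 6.0)
    scatter_range: tuple[float, float] = (0.3, 0.9)
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flowers <= 0:
            raise ValueError("n_flowers must be > 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        unknown = set(self.class_mix) - set(COLOUR_CLASSES)
        if unknown:
            raise ValueError(f"unknown colour classes {unknown}")
        lo, hi = self.pigment_amount_range
        if not (0 <= lo <= hi):
            raise ValueError("pigment_amount_range must be 0 <= low <= high")
        slo, shi = self.scatter_range
        if not (0 < slo <= shi <= 1):
            raise ValueError("scatter_range must be within (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_flora(
    config: FloraConfig, grid: np.ndarray | None = None
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Draw a synthetic flora: ``n_flowers`` spectra plus a metadata table
    (label, class, pigment_amount, scatter), reproducible from the seed.

    Per flower: colour class sampled from ``class_mix``, pigment amount and
    scatter uniform on their ranges, then i.i.d. Gaussian noise of sd
    ``noise_sd`` per grid point, clipped to [0, 1].
    """
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    drawn = rng.choice(len(classes), size=config.n_flowers, p=probs)
    pigment = rng.uniform(*config.pigment_amount_range, size=config.n_flowers)
    scatter = rng.uniform(*config.scatter_range, size=config.n_flowers)

    spectra: list[Spectrum] = []
    rows = []
    for i in range(config.n_flowers):
        cls = classes[drawn[i]]
        label = f"flower_{i:04d}"
        base = flower_spectrum(cls, pigment[i], scatter[i], grid, label=label)
        vals = base.values
        if config.noise_sd > 0:
            vals = vals + rng.normal(0.0, config.noise_sd, size=grid.size)
        vals = np.clip(vals, 0.0, 1.0)
        spectra.append(Spectrum(grid, vals, kind="reflectance", label=label))
        rows.append(
            {
                "label": label,
                "colour_class": cls,
                "pigment_amount": pigment[i],
                "scatter": scatter[i],
            }
        )
    return spectra, pd.DataFrame(rows)
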