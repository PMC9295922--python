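"""Pollinator visual systems: photoreceptor templates, illuminants, backgrounds.

Photoreceptor spectral sensitivities are built from the Govardovskii A1
visual-pigment nomogram (closed-form alpha band plus an optional ultraviolet
beta band). The beta band gives the blue and green receptors their low but
non-zero ultraviolet sensitivity, which is what folds the short-wavelength
end of the monochromatic line towards the achromatic centre.

Receptor peak wavelengths for the bundled bee systems are the conventional
measured values; they are parameters here, not constants, because published
colour-space constructions for the same species visibly disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, canonical_grid, ensure_on_grid

__all__ = [
    "Photoreceptor",
    "RnlNoise",
    "VisualSystem",
    "govardovskii_template",
    "standard_system",
    "default_illuminant",
    "green_leaf_background",
    "STANDARD_LAMBDA_MAX",
]

# Conventional receptor peaks (nm), UV/B/G, for the bundled systems.
# The stingless-bee entry reuses honeybee values under its own label, the
# usual practice where direct measurements are unavailable.
STANDARD_LAMBDA_MAX: dict[str, tuple[float, float, float]] = {
    "honeybee": (344.0, 436.0, 544.0),
    "bumblebee": (328.0, 428.0, 536.0),
    "stingless_bee": (344.0, 436.0, 544.0),
}

# Govardovskii A1 alpha-band constants.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104
# Beta-band constants.
_A_BETA = 0.26


def govardovskii_template(
    lambda_max_nm: float,
    grid: np.ndarray | None = None,
    include_beta: bool = True,
) -> Spectrum:
    """A1 visual-pigment absorbance template, peak-normalised to 1.

    Alpha band: ``S(λ) = 1 / (exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D)``
    with ``x = λmax/λ`` and ``a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940)``.

    Beta band (``include_beta``): a Gaussian
    ``A_β·exp(−((λ − λ_mβ)/d)²)`` with ``A_β = 0.26``,
    ``λ_mβ = 189 + 0.315·λmax`` and ``d = −40.5 + 0.195·λmax``.
    """
    if not (300.0 <= lambda_max_nm <= 600.0):
        raise ValueError(f"lambda_max {lambda_max_nm} nm outside [300, 600] nm")
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    x = lambda_max_nm / grid
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    s = alpha
    if include_beta:
        lam_beta = 189.0 + 0.315 * lambda_max_nm
        d = -40.5 + 0.195 * lambda_max_nm
        s = s + _A_BETA * np.exp(-(((grid - lam_beta) / d) ** 2))
    s = s / s.max()
    return Spectrum(grid, s, kind="sensitivity", label=f"template_{lambda_max_nm:g}nm")


def beta_band_centre(lambda_max_nm: float) -> float:
    """Centre wavelength (nm) of the beta band for a pigment of given peak."""
    return 189.0 + 0.315 * lambda_max_nm


@dataclass(frozen=True)
class Photoreceptor:
    """One receptor class: name, peak wavelength, peak-normalised sensitivity."""

    name: str
    lambda_max_nm: float
    sensitivity: Spectrum

    def __post_init__(self) -> None:
        v = self.sensitivity.values
        if abs(v.max() - 1.0) > 1e-6:
            raise ValueError(
                f"receptor {self.name}: sensitivity must be peak-normalised "
                f"(max {v.max():.8f})"
            )


@dataclass(frozen=True)
class RnlNoise:
    """Receptor-noise parameters for the receptor noise-limited model.

    ``omega`` is the single-receptor noise (Weber fraction); ``eta`` the
    relative receptor abundances UV:B:G. The per-channel noise is
    ``e_i = omega / sqrt(eta_i)``.
    """

    omega: float = 0.12
    eta: tuple[float, float, float] = (1.0, 0.471, 4.412)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if any(x <= 0 for x in self.eta):
            raise ValueError("receptor abundances must be > 0")

    @property
    def e(self) -> np.ndarray:
        return self.omega / np.sqrt(np.asarray(self.eta, dtype=float))


@dataclass(frozen=True)
class VisualSystem:
    """A trichromatic visual system: three receptors (ascending peak),
    illuminant, adapting background, and RNL noise parameters."""

    species_label: str
    receptors: tuple[Photoreceptor, Photoreceptor, Photoreceptor]
    illuminant: Spectrum
    background: Spectrum
    rnl_noise: RnlNoise = field(default_factory=RnlNoise)

    def __post_init__(self) -> None:
        if len(self.receptors) != 3:
            raise ValueError("exactly 3 receptors required (trichromat)")
        peaks = [r.lambda_max_nm for r in self.receptors]
        if not (peaks[0] < peaks[1] < peaks[2]):
            raise ValueError(f"receptors must have ascending lambda_max, got {peaks}")
        grid = self.grid
        for s, what in [(self.illuminant, "illuminant"), (self.background, "background")]:
            if len(s) != grid.size or not np.allclose(s.wavelengths_nm, grid):
                raise ValueError(f"{what} not on the receptor wavelength grid")

    @property
    def grid(self) -> np.ndarray:
        return self.receptors[0].sensitivity.wavelengths_nm

    @property
    def sensitivity_matrix(self) -> np.ndarray:
        """(3, n_wavelengths) array of receptor sensitivities, UV/B/G order."""
        return np.stack([r.sensitivity.values for r in self.receptors])


def default_illuminant(name: str = "flat_quantum", grid: np.ndarray | None = None) -> Spectrum:
    """Built-in illuminants in quantum units.

    ``flat_quantum``: constant 1 (equal quanta at every wavelength).
    ``d65_approx``: a smooth daylight-shaped curve, positive everywhere —
    a broad Gaussian centred in the visible with a mild UV shoulder; a
    convenience stand-in for open daylight, not the CIE tabulation.
    """
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    if name == "flat_quantum":
        vals = np.ones_like(grid)
    elif name == "d65_approx":
        vals = 0.35 + np.exp(-0.5 * ((grid - 560.0) / 180.0) ** 2)
        vals = vals / vals.max()
    else:
        raise ValueError(
            f"unknown illuminant {name!r}; available: flat_quantum, d65_approx"
        )
    return Spectrum(grid, vals, kind="irradiance", label=name)


def green_leaf_background(
    chlorophyll_amount: float = 1.5,
    scatter_level: float = 0.6,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Parametric green-leaf reflectance: a flat scattering baseline with
    chlorophyll absorption bands at 450 and 680 nm.

    ``R(λ) = scatter_level · exp(−chlorophyll_amount · [g(λ;450,40) + g(λ;680,20)])``
    with ``g(λ;μ,w) = exp(−((λ−μ)/w)²)`` a unit-height Gaussian, producing the
    characteristic green reflectance peak near 550 nm.
    """
    if chlorophyll_amount < 0:
        raise ValueError("chlorophyll_amount must be >= 0")
    if not (0 < scatter_level <= 1):
        raise ValueError("scatter_level must be in (0, 1]")
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    absorb = np.exp(-(((grid - 450.0) / 40.0) ** 2)) + np.exp(
        -(((grid - 680.0) / 20.0) ** 2)
    )
    vals = scatter_level * np.exp(-chlorophyll_amount * absorb)
    return Spectrum(grid, vals, kind="reflectance", label="green_leaf")


def standard_system(
    name: str,
    grid: np.ndarray | None = None,
    include_beta: bool = True,
    illuminant: Spectrum | None = None,
    background: Spectrum | None = None,
    rnl_noise: RnlNoise | None = None,
) -> VisualSystem:
    """Build one of the bundled bee visual systems.

    Receptors come from :func:`govardovskii_template` (beta band on by
    default); the default illuminant is ``flat_quantum`` and the default
    adapting background is :func:`green_leaf_background` (1.5, 0.6).
    """
    if name not in STANDARD_LAMBDA_MAX:
        raise ValueError(
            f"unknown visual system {name!r}; available: "
            + ", ".join(sorted(STANDARD_LAMBDA_MAX))
        )
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    peaks = STANDARD_LAMBDA_MAX[name]
    receptors = tuple(
        Photoreceptor(
            rname,
            peak,
            govardovskii_template(peak, grid, include_beta=include_beta),
        )
        for rname, peak in zip(("UV", "B", "G"), peaks)
    )
    ill = ensure_on_grid(illuminant, grid) if illuminant is not None else default_illuminant("flat_quantum", grid)
    bg = ensure_on_grid(background, grid) if background is not None else green_leaf_background(grid=grid)
    return VisualSystem(
        species_label=name,
        receptors=receptors,  # type: ignore[arg-type]
        illuminant=ill,
        background=bg,
        rnl_noise=rnl_noise or RnlNoise(),
    )
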