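"""Colour-hexagon colorimetry for trichromats.

Quantum catches are von Kries adapted to the background, transduced to
receptor excitations ``E = P/(P+1)``, and plotted at hexagon coordinates

    x = (√3/2)·(E_G − E_UV),   y = E_B − (E_UV + E_G)/2.

The adapting background sits at the achromatic centre (0, 0); colour
contrast is Euclidean distance in this plane. Spectral purity of a stimulus
is ``a/(a+b)``: ``a`` the distance from the centre to the stimulus (which is
exactly its colour contrast to the background) and ``b`` the remaining
distance along the same ray to the monochromatic line bounding the space.
That shared ``a`` is the structural reason purity and contrast cannot be
treated as independent variables.

The monochromatic line itself is not unique: the hexagon locus of a
single-wavelength light depends on its intensity (excitations saturate), and
published lines for the same species differ. The construction here makes the
intensity rule explicit — by default each spectral locus is placed at its
maximal possible distance from the centre (the outer envelope), which is
deterministic; a fixed-multiple rule is offered to emulate other published
lines. The gap between the 700-nm and 300-nm ends is closed by stepwise
mixtures of the two terminal lights, a purely conventional segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import trapezoid
from scipy.optimize import minimize_scalar

from .spectra import Spectrum, ensure_on_grid
from .visual import VisualSystem

__all__ = [
    "HexagonLocus",
    "MonochromaticLine",
    "PurityResult",
    "quantum_catch",
    "excitation",
    "hexagon_coordinates",
    "locus_for_stimulus",
    "colour_contrast",
    "green_contrast",
    "monochromatic_line",
    "spectral_purity",
    "circular_boundary_purity",
]

#: Distances below this are treated as "at the achromatic centre": the hue
#: (and hence the purity denominator ray) is undefined there.
CENTRE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Catches, excitations, coordinates


def background_catch_integrals(system: VisualSystem) -> np.ndarray:
    """Per-receptor un-adapted catch of the adapting background,
    ``∫ S_i(λ)·D_b(λ)·I(λ) dλ`` (trapezoidal)."""
    grid = system.grid
    integrand = (
        system.sensitivity_matrix
        * system.background.values[None, :]
        * system.illuminant.values[None, :]
    )
    k = trapezoid(integrand, grid, axis=1)
    if np.any(k <= 0):
        raise ValueError(
            "degenerate adaptation: background quantum catch is zero for "
            f"receptor(s) {[r.name for r, ki in zip(system.receptors, k) if ki <= 0]}"
        )
    return k


def raw_catch(stimulus: Spectrum, system: VisualSystem) -> np.ndarray:
    """Un-adapted quantum catches ``∫ S_i(λ)·D(λ)·I(λ) dλ``."""
    s = ensure_on_grid(stimulus, system.grid)
    integrand = (
        system.sensitivity_matrix
        * s.values[None, :]
        * system.illuminant.values[None, :]
    )
    return trapezoid(integrand, system.grid, axis=1)


def quantum_catch(stimulus: Spectrum, system: VisualSystem) -> np.ndarray:
    """Background-adapted (von Kries) quantum catches P.

    ``P_i = ∫S_i·D·I dλ / ∫S_i·D_b·I dλ``, so the adapting background itself
    maps to P = (1, 1, 1).
    """
    return raw_catch(stimulus, system) / background_catch_integrals(system)


def excitation(P: Sequence[float] | np.ndarray) -> np.ndarray:
    """Receptor excitation ``E = P/(P+1)``, each in [0, 1)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError(f"negative quantum catch: {P}")
    return P / (P + 1.0)


def hexagon_coordinates(E: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Hexagon (x, y) from excitations (E_UV, E_B, E_G)."""
    e_uv, e_b, e_g = np.asarray(E, dtype=float)
    x = (np.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return float(x), float(y)


@dataclass(frozen=True)
class HexagonLocus:
    """Catches, excitations and hexagon position of one stimulus."""

    P: np.ndarray
    E: np.ndarray
    x: float
    y: float
    label: str = ""

    @classmethod
    def from_catches(cls, P: Sequence[float] | np.ndarray, label: str = "") -> "HexagonLocus":
        P = np.asarray(P, dtype=float)
        E = excitation(P)
        x, y = hexagon_coordinates(E)
        return cls(P=P, E=E, x=x, y=y, label=label)

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)

    @property
    def distance_to_centre(self) -> float:
        return float(np.hypot(self.x, self.y))


def locus_for_stimulus(stimulus: Spectrum, system: VisualSystem) -> HexagonLocus:
    """Full hexagon locus of a reflectance spectrum under a visual system."""
    return HexagonLocus.from_catches(
        quantum_catch(stimulus, system), label=stimulus.label
    )


def colour_contrast(p: Sequence[float], q: Sequence[float] = (0.0, 0.0)) -> float:
    """Euclidean distance between two hexagon points (hexagon units).

    With the default second argument this is the contrast to the adapting
    background at the achromatic centre.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.hypot(*(p - q)))


def green_contrast(e_g_stimulus: float, e_g_background: float = 0.5) -> float:
    """Achromatic contrast carried by the green receptor alone,
    ``|E_G − E_G(background)|``; the adapted background has E_G = 0.5."""
    if not (0 <= e_g_stimulus <= 1 and 0 <= e_g_background <= 1):
        raise ValueError("excitations must lie in [0, 1]")
    return abs(e_g_stimulus - e_g_background)


# ---------------------------------------------------------------------------
# Monochromatic line


@dataclass(frozen=True)
class MonochromaticLine:
    """Boundary polyline of the colour space.

    ``spectral_loci`` are (wavelength, locus) pairs for single-wavelength
    lights from λ_start to λ_end; ``closure_loci`` are (α, locus) pairs for
    the conventional mixtures α·light(λ_end) + (1−α)·light(λ_start) closing
    the non-spectral gap. ``options`` records every construction choice.
    """

    spectral_loci: tuple[tuple[float, HexagonLocus], ...]
    closure_loci: tuple[tuple[float, HexagonLocus], ...]
    options: dict = field(default_factory=dict)

    def polyline(self) -> np.ndarray:
        """Closed boundary as an (n, 2) array of vertices (not repeated at
        the end; segments wrap around)."""
        pts = [loc.xy for _, loc in self.spectral_loci]
        pts += [loc.xy for _, loc in self.closure_loci]
        return np.asarray(pts, dtype=float)

    def distances(self) -> np.ndarray:
        """Centre distance of every spectral locus, in wavelength order."""
        return np.asarray(
            [loc.distance_to_centre for _, loc in self.spectral_loci]
        )

    def distance_at(self, wavelength_nm: float) -> float:
        """Centre distance of the spectral locus at exactly this wavelength."""
        for wl, loc in self.spectral_loci:
            if abs(wl - wavelength_nm) < 1e-9:
                return loc.distance_to_centre
        raise KeyError(f"no spectral locus at {wavelength_nm} nm")


def _spike_locus(weights: np.ndarray, k_background: np.ndarray, q: float) -> HexagonLocus:
    """Locus of a (mixture of) monochromatic light(s) at total quantum flux q.

    ``weights`` are the per-receptor sensitivities of the mixture,
    ``S_i(λ0)`` for a single spike; the adapted catch is
    ``P_i = q·weights_i / ∫S_i·D_b·I dλ``.
    """
    return HexagonLocus.from_catches(q * weights / k_background)


def _max_distance_q(weights: np.ndarray, k_background: np.ndarray) -> float:
    """Intensity q maximising the locus distance from the achromatic centre.

    Distance → 0 both as q → 0 (all catches vanish) and as q → ∞ (all
    excitations saturate at 1, which is again the centre), so the maximum is
    interior. Coarse log-spaced scan, then golden-section refinement.
    """

    def neg_dist(log_q: float) -> float:
        return -_spike_locus(weights, k_background, float(np.exp(log_q))).distance_to_centre

    log_qs = np.linspace(np.log(1e-4), np.log(1e7), 120)
    vals = np.array([neg_dist(lq) for lq in log_qs])
    i = int(np.argmin(vals))
    lo = log_qs[max(i - 1, 0)]
    hi = log_qs[min(i + 1, len(log_qs) - 1)]
    res = minimize_scalar(neg_dist, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(np.exp(res.x))


def monochromatic_line(
    system: VisualSystem,
    lambda_start: float = 300.0,
    lambda_end: float = 700.0,
    step: float = 1.0,
    intensity_rule: Literal["max_distance", "fixed_multiple"] = "max_distance",
    fixed_k: float = 1.0,
    closure_steps: int = 100,
) -> MonochromaticLine:
    """Construct the monochromatic line for a visual system.

    Each grid wavelength λ0 in [lambda_start, lambda_end] contributes the
    locus of a single-wavelength light of quantum flux q, with catches
    ``P_i = q·S_i(λ0) / ∫S_i·D_b·I dλ``. Under ``intensity_rule =
    "max_distance"`` q is optimised per wavelength to put the locus at its
    greatest distance from the centre; under ``"fixed_multiple"`` q is
    ``fixed_k`` times the background's total quantum flux. The non-spectral
    gap is closed by ``closure_steps`` stepwise mixtures of the λ_end and
    λ_start lights, with the same intensity rule.

    Wavelengths where every receptor has (numerically) zero sensitivity are
    skipped with a warning and recorded in ``options["skipped_nm"]``.
    """
    grid = system.grid
    if not (grid[0] - 1e-9 <= lambda_start < lambda_end <= grid[-1] + 1e-9):
        raise ValueError(
            f"[{lambda_start}, {lambda_end}] nm must lie within the system "
            f"grid [{grid[0]}, {grid[-1]}] nm"
        )
    if closure_steps < 2:
        raise ValueError("closure_steps must be >= 2")
    k_bg = background_catch_integrals(system)
    S = system.sensitivity_matrix

    wavelengths = np.arange(lambda_start, lambda_end + step / 2, step)
    if intensity_rule == "fixed_multiple":
        bg_flux = trapezoid(
            system.background.values * system.illuminant.values, grid
        )

    def build(weights: np.ndarray, label: str) -> HexagonLocus | None:
        if weights.max() < 1e-12:
            return None
        if intensity_rule == "max_distance":
            q = _max_distance_q(weights, k_bg)
        else:
            q = fixed_k * bg_flux
        loc = _spike_locus(weights, k_bg, q)
        return HexagonLocus(loc.P, loc.E, loc.x, loc.y, label=label)

    spectral: list[tuple[float, HexagonLocus]] = []
    skipped: list[float] = []
    for wl in wavelengths:
        weights = np.array([np.interp(wl, grid, S[i]) for i in range(3)])
        loc = build(weights, f"mono_{wl:g}nm")
        if loc is None:
            skipped.append(float(wl))
            continue
        spectral.append((float(wl), loc))
    if skipped:
        warnings.warn(
            f"{len(skipped)} monochromatic loci skipped (zero sensitivity): "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )

    w_start = np.array([np.interp(lambda_start, grid, S[i]) for i in range(3)])
    w_end = np.array([np.interp(lambda_end, grid, S[i]) for i in range(3)])
    # Descending alpha: the closure runs from the lambda_end locus back to
    # the lambda_start locus, so the closed polyline follows the boundary
    # continuously (spectral loci ++ closure ++ wrap to first locus).
    alphas = np.arange(closure_steps, 0, -1) / (closure_steps + 1)
    closure: list[tuple[float, HexagonLocus]] = []
    for alpha in alphas:
        weights = alpha * w_end + (1 - alpha) * w_start
        loc = build(weights, f"closure_{alpha:.4f}")
        if loc is not None:
            closure.append((float(alpha), loc))

    return MonochromaticLine(
        spectral_loci=tuple(spectral),
        closure_loci=tuple(closure),
        options={
            "lambda_start": lambda_start,
            "lambda_end": lambda_end,
            "step": step,
            "intensity_rule": intensity_rule,
            "fixed_k": fixed_k if intensity_rule == "fixed_multiple" else None,
            "closure_steps": closure_steps,
            "skipped_nm": skipped,
        },
    )


# ---------------------------------------------------------------------------
# Spectral purity


@dataclass(frozen=True)
class PurityResult:
    """Spectral purity ``a/(a+b)`` of one stimulus.

    ``a`` is the distance centre → stimulus (identically the stimulus's
    colour contrast to the background); ``b`` the distance stimulus →
    boundary along the same ray (negative when the stimulus lies beyond the
    boundary). ``defined`` is False for stimuli at the achromatic centre,
    where hue — and with it the ray — does not exist.
    """

    a: float
    b: float
    purity: float
    boundary_point: tuple[float, float]
    defined: bool
    beyond_boundary: bool = False


def _distance_to_polyline(p: np.ndarray, vertices: np.ndarray) -> float:
    """Minimum Euclidean distance from point ``p`` to the closed polygon."""
    p1 = vertices
    seg = np.roll(vertices, -1, axis=0) - p1
    norm2 = (seg * seg).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(((p - p1) * seg).sum(axis=1) / norm2, 0.0, 1.0)
    t = np.where(norm2 > 0, t, 0.0)
    nearest = p1 + t[:, None] * seg
    return float(np.min(np.hypot(*(p - nearest).T)))


def _ray_crossings(direction: np.ndarray, vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All crossings of the ray {t·direction, t > 0} from the origin with the
    closed polygon given by ``vertices``.

    Returns (t values, points), t ascending. Segments collinear with the ray
    (degenerate) contribute their endpoints that lie on the ray.
    """
    p1 = vertices
    p2 = np.roll(vertices, -1, axis=0)
    d = direction
    seg = p2 - p1
    # Solve t*d = p1 + s*seg  =>  [d, -seg] [t, s]^T = p1, per segment, via Cramer.
    det = -d[0] * seg[:, 1] + d[1] * seg[:, 0]
    ok = np.abs(det) > 1e-15
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (-p1[:, 0] * seg[:, 1] + p1[:, 1] * seg[:, 0]) / det
        s = (d[0] * p1[:, 1] - d[1] * p1[:, 0]) / det
    cand = ok & (t > 1e-12) & (s >= -1e-12) & (s <= 1 + 1e-12)
    ts = list(t[cand])
    pts = [p1[i] + np.clip(s[i], 0.0, 1.0) * seg[i] for i in np.where(cand)[0]]
    # Degenerate: segment collinear with the ray — take endpoints on the ray.
    for i in np.where(~ok)[0]:
        for pt in (p1[i], p2[i]):
            proj = float(np.dot(pt, d))
            if proj > 1e-12 and abs(pt[0] * d[1] - pt[1] * d[0]) < 1e-12:
                ts.append(proj)
                pts.append(pt)
    if not ts:
        raise ValueError(
            "purity ray intersects no boundary segment at hue angle "
            f"{np.degrees(np.arctan2(d[1], d[0])):.2f}°; boundary malformed or open"
        )
    order = np.argsort(ts)
    return np.asarray(ts)[order], np.asarray(pts)[order]


def spectral_purity(
    stimulus_xy: Sequence[float], line: MonochromaticLine
) -> PurityResult:
    """Spectral purity ``a/(a+b)`` of a hexagon point against a
    monochromatic line.

    The ray from the achromatic centre through the stimulus is intersected
    with the closed boundary (spectral loci, then closure loci, wrapping
    back to the first spectral locus). The boundary point is the first
    crossing at or beyond the stimulus along the ray: where the beta-band
    hook folds the boundary so that one hue angle crosses it several times,
    this keeps every boundary locus at purity exactly 1 and every interior
    stimulus at purity <= 1. A stimulus at the centre has undefined hue:
    ``defined=False`` and purity NaN. A stimulus beyond every crossing
    yields purity > 1 with ``beyond_boundary=True`` (reported, not an
    error), measured against the outermost crossing.
    """
    p = np.asarray(stimulus_xy, dtype=float)
    a = float(np.hypot(*p))
    if a < CENTRE_TOL:
        return PurityResult(
            a=a, b=np.nan, purity=np.nan, boundary_point=(np.nan, np.nan),
            defined=False,
        )
    vertices = line.polyline()
    if vertices.shape[0] < 3:
        raise ValueError("monochromatic line has fewer than 3 loci")
    # A stimulus lying on the boundary itself is its own boundary point
    # (b = 0, purity 1). Checked directly because ray-segment intersection
    # is ill-conditioned where the boundary runs along the ray.
    if _distance_to_polyline(p, vertices) < 1e-9:
        return PurityResult(
            a=a, b=0.0, purity=1.0, boundary_point=(float(p[0]), float(p[1])),
            defined=True,
        )
    direction = p / a
    ts, points = _ray_crossings(direction, vertices)
    outward = np.where(ts >= a - CENTRE_TOL)[0]
    i = int(outward[0]) if outward.size else int(np.argmax(ts))
    t, boundary = float(ts[i]), points[i]
    b = t - a
    purity = a / (a + b)  # == a / t
    beyond = b < -CENTRE_TOL
    if beyond:
        warnings.warn(
            f"stimulus at distance {a:.4f} lies beyond the boundary "
            f"(t={t:.4f}); purity {purity:.4f} > 1",
            stacklevel=2,
        )
    return PurityResult(
        a=a, b=float(b), purity=float(purity),
        boundary_point=(float(boundary[0]), float(boundary[1])),
        defined=True, beyond_boundary=beyond,
    )


def circular_boundary_purity(stimulus_xy: Sequence[float], radius: float) -> PurityResult:
    """Purity against a hypothetical circular boundary of constant radius.

    With a constant denominator ``a + b = radius``, purity reduces to
    ``a/radius`` — a strictly increasing function of colour contrast alone.
    This is the limiting geometry of the purity–contrast confound: the less
    the boundary distance varies, the more purity is just rescaled contrast.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    p = np.asarray(stimulus_xy, dtype=float)
    a = float(np.hypot(*p))
    if a < CENTRE_TOL:
        return PurityResult(
            a=a, b=np.nan, purity=np.nan, boundary_point=(np.nan, np.nan),
            defined=False,
        )
    direction = p / a
    boundary = direction * radius
    return PurityResult(
        a=a, b=float(radius - a), purity=a / radius,
        boundary_point=(float(boundary[0]), float(boundary[1])),
        defined=True, beyond_boundary=a > radius + CENTRE_TOL,
    )
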