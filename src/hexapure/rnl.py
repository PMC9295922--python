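"""Receptor noise-limited (RNL) chromatic distance.

Discriminability of two stimuli is limited by noise in the receptor
channels. Receptor contrasts are log ratios of un-adapted quantum catches,
and the trichromatic distance in just-noticeable-difference (JND) units is

    ΔS² = [e₁²(Δf₃−Δf₂)² + e₂²(Δf₃−Δf₁)² + e₃²(Δf₁−Δf₂)²]
          / [(e₁e₂)² + (e₁e₃)² + (e₂e₃)²]

with per-channel noise e_i = ω/√η_i (ω the single-receptor Weber fraction,
η_i relative receptor abundance). Only channel *differences* enter, so a
uniform intensity change (Δf shifted by a constant) gives ΔS = 0: the model
measures chromatic contrast only and offers no saturation/purity analogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import Spectrum
from .visual import RnlNoise, VisualSystem
from .hexagon import raw_catch

__all__ = ["RnlNoise", "RnlResult", "receptor_log_contrast", "delta_s", "rnl_contrast"]


@dataclass(frozen=True)
class RnlResult:
    delta_f: np.ndarray  # log receptor contrasts, UV/B/G
    delta_s: float  # chromatic distance in JND


def receptor_log_contrast(
    q_stimulus: Sequence[float] | np.ndarray,
    q_reference: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Log receptor contrasts Δf_i = ln(q_i_stim / q_i_ref).

    Catches are un-adapted integrals ∫S_i·D·I dλ; they must be strictly
    positive (a zero catch means the stimulus reflects nothing within a
    receptor's sensitivity band, and the log contrast is undefined).
    """
    qs = np.asarray(q_stimulus, dtype=float)
    qr = np.asarray(q_reference, dtype=float)
    if np.any(qs <= 0) or np.any(qr <= 0):
        raise ValueError(
            f"quantum catches must be > 0 for log contrast (got {qs}, {qr}); "
            "a zero catch suggests zero reflectance across a receptor's band"
        )
    return np.log(qs / qr)


def delta_s(delta_f: Sequence[float] | np.ndarray, noise: RnlNoise) -> float:
    """Chromatic distance ΔS (JND) from log receptor contrasts."""
    f1, f2, f3 = np.asarray(delta_f, dtype=float)
    e1, e2, e3 = noise.e
    num = (
        e1**2 * (f3 - f2) ** 2
        + e2**2 * (f3 - f1) ** 2
        + e3**2 * (f1 - f2) ** 2
    )
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return float(np.sqrt(num / den))


def rnl_contrast(
    stimulus: Spectrum,
    system: VisualSystem,
    reference: Spectrum | None = None,
) -> RnlResult:
    """RNL chromatic distance between a stimulus and a reference spectrum
    (default: the system's adapting background)."""
    ref = reference if reference is not None else system.background
    df = receptor_log_contrast(raw_catch(stimulus, system), raw_catch(ref, system))
    return RnlResult(delta_f=df, delta_s=delta_s(df, system.rnl_noise))
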