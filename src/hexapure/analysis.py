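"""Metric-correlation study: are "saturation" metrics independent of contrast?

Computes per-stimulus colour metrics (hexagon colour contrast, spectral
purity, green contrast, RNL chromatic contrast, model-independent chroma)
under one or more visual systems, then tests every requested metric pair
with Spearman's rank correlation, Benjamini–Hochberg corrected across all
tests in the run.

Spectral purity shares its numerator with colour contrast — the distance
from the achromatic centre to the stimulus — so whenever the boundary
distance varies little across hues the two metrics are close to a monotone
reparameterisation of each other and their rank correlation approaches 1.
The study makes that confound measurable on any stimulus set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectra import Spectrum
from .visual import VisualSystem
from .hexagon import (
    MonochromaticLine,
    circular_boundary_purity,
    green_contrast,
    locus_for_stimulus,
    monochromatic_line,
    spectral_purity,
)
from .chroma import endler_chroma
from .rnl import rnl_contrast

__all__ = [
    "MIN_STIMULI",
    "DEFAULT_PAIRS",
    "spearman",
    "benjamini_hochberg",
    "compute_metrics",
    "metric_correlation_study",
]

#: Stimulus sets smaller than this are refused, matching the exclusion
#: threshold used when pooling published datasets for this analysis.
MIN_STIMULI = 15

#: Hexagon-only metric pairs tested by default; RNL pairs are appended when
#: the RNL model is enabled.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("contrast_hex", "purity"),
    ("contrast_hex", "chroma_endler"),
    ("purity", "chroma_endler"),
)
RNL_PAIRS: tuple[tuple[str, str], ...] = (
    ("contrast_rnl", "purity"),
    ("contrast_rnl", "chroma_endler"),
)


# ---------------------------------------------------------------------------
# Statistics


def _spearman_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        return math.nan
    return float(xc @ yc) / denom


def _exact_permutation_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: fraction of permutations of y with |rho| >= |rho_obs|.

    Valid with ties (ranks are permuted as given). Enumerates all n!
    permutations, so restricted to small n.
    """
    n = x_ranks.size
    perms = np.array(list(itertools.permutations(y_ranks)), dtype=float)
    xc = x_ranks - x_ranks.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = pc @ xc
    denom = np.sqrt(float(xc @ xc) * (pc * pc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = num / denom
    rhos = rhos[np.isfinite(rhos)]
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    exact_max_n: int = 9,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Pairs with a NaN in either coordinate are dropped. Ties get average
    ranks; rho is the Pearson correlation of the rank vectors. The p-value
    is exact (full permutation distribution) for n <= ``exact_max_n`` and a
    t approximation with n−2 df above; |rho| = 1 never divides by zero (the
    t statistic is taken to its infinite limit, p = 0 under the
    approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs for Spearman, got {n}")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = _spearman_rho(xr, yr)
    if math.isnan(rho):
        return math.nan, math.nan  # zero rank variance: undefined
    if n <= exact_max_n:
        p = _exact_permutation_p(xr, yr, rho)
    else:
        if abs(rho) >= 1.0 - 1e-15:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``p_adj(i) = min over j >= i (by sorted order) of min(1, p(j)·m/j)``.
    NaN entries (undefined tests) are passed through and do not count
    towards the family size m.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Metrics per stimulus


def compute_metrics(
    spectra: Sequence[Spectrum],
    system: VisualSystem,
    line: MonochromaticLine | None = None,
    purity_boundary: MonochromaticLine | float | None = None,
    include_rnl: bool = True,
    chroma_range: tuple[float, float] = (300.0, 700.0),
) -> pd.DataFrame:
    """Per-stimulus metric table under one visual system.

    Columns: label, visual_system, x, y, contrast_hex, green_contrast,
    purity, purity_defined, chroma_endler, and contrast_rnl when
    ``include_rnl``. ``purity_boundary`` may be a MonochromaticLine or a
    positive float (hypothetical circular boundary of that radius); by
    default the system's own monochromatic line is constructed.
    """
    if purity_boundary is None:
        purity_boundary = line if line is not None else monochromatic_line(system)
    rows = []
    for s in spectra:
        loc = locus_for_stimulus(s, system)
        if isinstance(purity_boundary, MonochromaticLine):
            pur = spectral_purity(loc.xy, purity_boundary)
        else:
            pur = circular_boundary_purity(loc.xy, float(purity_boundary))
        row = {
            "label": s.label,
            "visual_system": system.species_label,
            "x": loc.x,
            "y": loc.y,
            "contrast_hex": loc.distance_to_centre,
            "green_contrast": green_contrast(loc.E[2]),
            "purity": pur.purity,
            "purity_defined": pur.defined,
            "chroma_endler": endler_chroma(s, chroma_range).chroma,
        }
        if include_rnl:
            row["contrast_rnl"] = rnl_contrast(s, system).delta_s
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Study


def metric_correlation_study(
    spectra: Sequence[Spectrum],
    systems: VisualSystem | Sequence[VisualSystem],
    pairs: Iterable[tuple[str, str]] | None = None,
    include_rnl: bool = True,
    purity_boundary: MonochromaticLine | float | None = None,
    bh_family: str = "pooled",
    chroma_range: tuple[float, float] = (300.0, 700.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full metric-correlation study.

    For every visual system, computes all metrics per stimulus, then
    Spearman-correlates every requested metric pair and adjusts the p-values
    by Benjamini–Hochberg. ``bh_family="pooled"`` (default) corrects across
    all pairs and systems in one family; ``"per_system"`` corrects within
    each visual system separately.

    Returns ``(metrics_table, correlation_table)``. The correlation table
    has one row per (pair, system) with columns metric_x, metric_y,
    visual_system, n_used, rho, p_raw, p_adjusted.

    Refuses stimulus sets with fewer than ``MIN_STIMULI`` spectra — rank
    correlations on tiny sets are not informative, so small sets are
    excluded outright.
    """
    if isinstance(systems, VisualSystem):
        systems = [systems]
    spectra = list(spectra)
    if len(spectra) < MIN_STIMULI:
        raise ValueError(
            f"{len(spectra)} stimuli provided; studies with fewer than "
            f"{MIN_STIMULI} stimuli are excluded from correlation analysis"
        )
    if pairs is None:
        pairs = DEFAULT_PAIRS + (RNL_PAIRS if include_rnl else ())
    pairs = list(pairs)

    metric_frames = []
    rows = []
    for system in systems:
        m = compute_metrics(
            spectra,
            system,
            purity_boundary=purity_boundary,
            include_rnl=include_rnl,
            chroma_range=chroma_range,
        )
        metric_frames.append(m)
        for mx, my in pairs:
            for name in (mx, my):
                if name not in m.columns:
                    raise ValueError(
                        f"metric {name!r} unavailable "
                        f"(computed: {sorted(set(m.columns) - {'label', 'visual_system'})})"
                    )
            x = m[mx].to_numpy(dtype=float)
            y = m[my].to_numpy(dtype=float)
            n_used = int((np.isfinite(x) & np.isfinite(y)).sum())
            rho, p = spearman(x, y)
            rows.append(
                {
                    "metric_x": mx,
                    "metric_y": my,
                    "visual_system": system.species_label,
                    "n_used": n_used,
                    "rho": rho,
                    "p_raw": p,
                }
            )
    metrics_table = pd.concat(metric_frames, ignore_index=True)
    corr = pd.DataFrame(rows)
    if bh_family == "pooled":
        corr["p_adjusted"] = benjamini_hochberg(corr["p_raw"].to_numpy())
    elif bh_family == "per_system":
        corr["p_adjusted"] = np.nan
        for sysname, idx in corr.groupby("visual_system").groups.items():
            corr.loc[idx, "p_adjusted"] = benjamini_hochberg(
                corr.loc[idx, "p_raw"].to_numpy()
            )
    else:
        raise ValueError("bh_family must be 'pooled' or 'per_system'")
    return metrics_table, corr
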