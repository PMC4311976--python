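"""Morphometric maps: standardization, consensus/CV maps, colour scaling.

A morphometric map is a (sections x 360 degrees) matrix of one
standardized structural property for one individual: cortical thickness
divided by mechanical length (dimensionless), or SMA divided by
body mass times length (mm^3/kg).  Group consensus maps are pixelwise
means, CV maps pixelwise sd/mean; colour anchors can be shared across
groups (interspecific) or per group (intraspecific).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

MAP_SHAPE = (17, 360)


@dataclass
class MorphometricMap:
    """One individual's standardized property map."""

    values: np.ndarray  # (n_sections, 360)
    property: str  # "CBT" or "SMA"
    individual_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map must be 2D (sections x degrees)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if self.property not in ("CBT", "SMA"):
            raise ValueError("property must be 'CBT' or 'SMA'")


def standardize_cbt(thickness_mm: np.ndarray, length_mm: float) -> np.ndarray:
    """Thickness standardized by mechanical length (dimensionless)."""
    if length_mm <= 0:
        raise ValueError("length must be positive")
    return np.asarray(thickness_mm, dtype=float) / length_mm


def standardize_sma(sma_mm4: np.ndarray, mass_kg: float, length_mm: float) -> np.ndarray:
    """SMA standardized by body mass x length (mm^3/kg)."""
    if mass_kg <= 0 or length_mm <= 0:
        raise ValueError("mass and length must be positive")
    return np.asarray(sma_mm4, dtype=float) / (mass_kg * length_mm)


def body_mass(
    metadata: pd.DataFrame,
    regression: Mapping[str, tuple[float, float]] | None = None,
    group_sex_means: bool = True,
) -> pd.Series:
    """Body masses (kg) used for SMA standardization.

    Direct masses in a ``mass_kg`` column pass through; otherwise masses
    are estimated from ``femoral_head_mm`` via user-supplied sex-specific
    linear regressions ``{sex: (intercept, slope)}``.  With
    ``group_sex_means`` (the default) each individual is standardized by
    the mean mass of its (group, sex) cell, mirroring the use of
    sex-specific species means.
    """
    meta = metadata.copy()
    if "mass_kg" in meta.columns and meta["mass_kg"].notna().all():
        mass = meta["mass_kg"].astype(float)
    elif "femoral_head_mm" in meta.columns:
        if regression is None:
            raise ValueError(
                "femoral-head-diameter path requires sex-specific regression "
                "coefficients {sex: (intercept, slope)}"
            )
        def est(row):
            try:
                a, b = regression[row["sex"]]
            except KeyError as exc:
                raise ValueError(f"missing regression coefficients for sex {row['sex']!r}") from exc
            return a + b * row["femoral_head_mm"]

        mass = meta.apply(est, axis=1).astype(float)
    else:
        raise ValueError("metadata needs a 'mass_kg' or 'femoral_head_mm' column")
    if group_sex_means:
        meta["_mass"] = mass
        keys = [k for k in ("group", "sex") if k in meta.columns]
        if keys:
            mass = meta.groupby(keys)["_mass"].transform("mean")
    return mass.rename("mass_kg")


def consensus_map(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise mean map of a group."""
    arrs = [np.asarray(m.values if isinstance(m, MorphometricMap) else m, dtype=float) for m in maps]
    return np.mean(arrs, axis=0)


def cv_map(maps: Sequence[np.ndarray], ddof: int = 1) -> np.ndarray:
    """Pixelwise coefficient of variation (sd/mean, sd with n-1 denominator)."""
    arrs = [np.asarray(m.values if isinstance(m, MorphometricMap) else m, dtype=float) for m in maps]
    if len(arrs) < 2:
        raise ValueError("CV map needs at least 2 individuals")
    stack = np.stack(arrs)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, 0.0)
    return cv


def cv_hotspot_deg(cv_values: np.ndarray, window_deg: int = 21) -> int:
    """Angular position (degrees) of a CV map's dominant hot-spot.

    The section-averaged angular CV profile is smoothed with a circular
    moving average at the expected hot-spot scale before taking the peak,
    so single-pixel estimation noise does not masquerade as a hot-spot.
    """
    col = np.asarray(cv_values, dtype=float).mean(axis=0)
    n = col.size
    kern = np.ones(window_deg) / window_deg
    tiled = np.concatenate([col[-window_deg:], col, col[:window_deg]])
    sm = np.convolve(tiled, kern, mode="same")[window_deg : window_deg + n]
    return int(np.argmax(sm))


def color_scale(
    maps_by_group: Mapping[str, np.ndarray], mode: str = "interspecific"
) -> dict[str, tuple[float, float]]:
    """Colour anchors (min, max) per group map.

    ``interspecific`` and ``cv`` modes share one global (min, max) across
    all group maps; ``intraspecific`` anchors each group to its own range.
    Degenerate anchors (min == max) are flagged with a warning.
    """
    if mode not in ("interspecific", "intraspecific", "cv"):
        raise ValueError("mode must be interspecific, intraspecific or cv")
    out: dict[str, tuple[float, float]] = {}
    if mode in ("interspecific", "cv"):
        lo = min(float(np.min(m)) for m in maps_by_group.values())
        hi = max(float(np.max(m)) for m in maps_by_group.values())
        anchors = (lo, hi)
        if lo == hi:
            warnings.warn("degenerate colour anchors: min == max")
        out = {g: anchors for g in maps_by_group}
    else:
        for g, m in maps_by_group.items():
            lo, hi = float(np.min(m)), float(np.max(m))
            if lo == hi:
                warnings.warn(f"degenerate colour anchors for group {g}: min == max")
            out[g] = (lo, hi)
    return out


def render_map(
    values: np.ndarray,
    anchors: tuple[float, float] | None = None,
    upscale: int = 8,
    cmap: str = "turbo",
) -> np.ndarray:
    """Render a map as an RGB image (uint8); the data matrix is untouched.

    Display resampling is bicubic on a grid that wraps in the degree
    dimension (no seam at 0/360) and is clamped in the section dimension;
    row order is flipped so section 1 sits at the bottom, columns start
    at the 0-degree reference.  ``anchors=None`` scales to the map's own
    range; degenerate anchors render a uniform mid-colour.
    """
    from matplotlib import colormaps

    vals = np.asarray(values, dtype=float)
    nr, nc = vals.shape
    if upscale < 1:
        raise ValueError("upscale must be >= 1")
    rows_out = np.linspace(0, nr - 1, nr * upscale)
    cols_out = np.arange(nc * upscale) / upscale
    mesh_r, mesh_c = np.meshgrid(rows_out, cols_out, indexing="ij")
    # pad columns periodically (no 0/360 seam); rows are clamped
    padded = np.concatenate([vals[:, -4:], vals, vals[:, :4]], axis=1)
    big = ndimage.map_coordinates(
        padded, [mesh_r, mesh_c + 4.0], order=3, mode="nearest"
    )
    if anchors is None:
        anchors = (float(vals.min()), float(vals.max()))
    lo, hi = anchors
    if hi <= lo:
        warnings.warn("degenerate anchors; rendering uniform mid-colour")
        norm = np.full_like(big, 0.5)
    else:
        norm = np.clip((big - lo) / (hi - lo), 0.0, 1.0)
    rgba = colormaps[cmap](norm[::-1, :])  # flip so section 1 is at the bottom
    return (rgba[..., :3] * 255).astype(np.uint8)


def save_map_png(path, values, anchors=None, upscale: int = 8, cmap: str = "turbo") -> None:
    import imageio.v3 as iio

    iio.imwrite(path, render_map(values, anchors, upscale, cmap))


def save_map_csv(path, values: np.ndarray, fractions: Sequence[float] | None = None) -> None:
    """CSV export: header row of degrees, row labels of fraction length."""
    vals = np.asarray(values, dtype=float)
    idx = list(fractions) if fractions is not None else list(range(1, vals.shape[0] + 1))
    df = pd.DataFrame(vals, index=idx, columns=[str(d) for d in range(vals.shape[1])])
    df.index.name = "fraction_pct"
    df.to_csv(path)
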