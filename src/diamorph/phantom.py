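"""Synthetic hollow-diaphysis phantoms with analytic ground truth.

A phantom is a voxelized tube whose outer radius and wall thickness are
arbitrary smooth functions of angular position (degrees, counter-clockwise
from the medial reference direction, viewed from proximal) and of
fractional length along the shaft.  Because the geometry is analytic,
the true 17x360 thickness and second-moment-of-area (SMA) maps are known
exactly, which makes every downstream measurement stage testable without
CT scans of real specimens.

Cohorts of phantoms emulate a three-group comparative sample (two
thick-walled ape-like groups, one of them with a localized
plantar-proximal thickening, and a thin-walled human-like group with a
dorsoplantarly elongated outer contour), with between-individual jitter
and planted group differences whose locations are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .volume import Landmarks, Volume

#: section levels as percent of mechanical length (25% .. 65% in 2.5% steps)
SECTION_FRACTIONS: np.ndarray = np.arange(25.0, 65.0 + 1e-9, 2.5)
N_RAYS = 360

RadialFn = Callable[[np.ndarray, float], np.ndarray]


@dataclass
class PhantomSpec:
    """Analytic description of one hollow-bone phantom.

    ``outer_radius_fn(angle_deg, fraction_length)`` and
    ``wall_thickness_fn(angle_deg, fraction_length)`` must be
    numpy-vectorized in the angle argument and return mm; ``fraction_length``
    runs 0 (proximal) to 1 (distal).  ``roll_offset_deg`` rotates the whole
    tube about its axis; the roll-reference landmark follows, so roll fixing
    can undo it.  ``noise_sd_mm`` adds a smooth random surface perturbation.
    """

    length_mm: float
    outer_radius_fn: RadialFn
    wall_thickness_fn: RadialFn
    voxel_mm: float = 0.3
    roll_offset_deg: float = 0.0
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")


def _validation_grid() -> tuple[np.ndarray, np.ndarray]:
    ang = np.arange(0.0, 360.0, 1.0)
    frac = np.linspace(0.0, 1.0, 41)
    return ang, frac


def _validate_fns(spec: PhantomSpec, outer: RadialFn, wall: RadialFn) -> None:
    ang, fracs = _validation_grid()
    for f in fracs:
        ro = np.asarray(outer(ang, float(f)), dtype=float)
        t = np.asarray(wall(ang, float(f)), dtype=float)
        if np.any(t <= 0):
            raise ValueError("degenerate phantom: wall thickness must be positive everywhere")
        if np.any(t >= ro):
            raise ValueError("wall thickness must be smaller than outer radius everywhere")
        if spec.voxel_mm > np.min(t) / 2 + 1e-12:
            raise ValueError(
                f"voxel_mm={spec.voxel_mm} too coarse: must be <= min wall thickness / 2 "
                f"(= {np.min(t) / 2:.3f} mm)"
            )


def _smooth_field(rng: np.random.Generator, sd: float, max_harmonic: int = 4) -> RadialFn:
    """Zero-mean smooth random field on (angle, fraction) with pointwise sd ~ sd.

    Low-order Fourier series in angle times a quadratic in fraction; the
    coefficient scale is normalized numerically so the field's pointwise
    standard deviation over the shaft is approximately ``sd``.
    """
    ks = np.arange(1, max_harmonic + 1)
    coef = rng.normal(size=(max_harmonic, 2, 3))

    def raw(angle_deg: np.ndarray, frac: float) -> np.ndarray:
        a = np.deg2rad(np.asarray(angle_deg, dtype=float))
        out = np.zeros_like(a)
        for i, k in enumerate(ks):
            trig = (np.cos(k * a), np.sin(k * a))
            for j in range(2):
                poly = coef[i, j, 0] + coef[i, j, 1] * frac + coef[i, j, 2] * frac**2
                out = out + poly * trig[j]
        return out

    ang, fracs = _validation_grid()
    vals = np.stack([raw(ang, float(f)) for f in fracs])
    scale = sd / max(vals.std(), 1e-12)

    def fieldfn(angle_deg: np.ndarray, frac: float) -> np.ndarray:
        return scale * raw(angle_deg, frac)

    return fieldfn


def _effective_fns(spec: PhantomSpec) -> tuple[RadialFn, RadialFn]:
    """Outer-radius / wall functions with the phantom's surface noise baked in."""
    outer, wall = spec.outer_radius_fn, spec.wall_thickness_fn
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        f_out = _smooth_field(rng, spec.noise_sd_mm)
        f_wall = _smooth_field(rng, spec.noise_sd_mm)

        def outer2(a, f, _outer=outer, _f=f_out):
            return np.asarray(_outer(a, f), dtype=float) + _f(a, f)

        def wall2(a, f, _wall=wall, _f=f_wall):
            return np.asarray(_wall(a, f), dtype=float) + _f(a, f)

        return outer2, wall2
    return outer, wall


def _ray_distances(origin: np.ndarray, pts: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Distances from ``origin`` to a closed polygon along each ray direction.

    ``pts`` is (M, 2) polygon vertices (closed implicitly), ``dirs`` (R, 2)
    unit directions.  Returns (R, 2): (min, max) positive intersection
    distance per ray; NaN where the ray misses the polygon.
    """
    a = pts
    b = np.roll(pts, -1, axis=0)
    e = b - a  # (M, 2)
    ao = a - origin  # (M, 2)
    # solve origin + s*d = a + u*e  =>  s = cross(ao, e)/cross(d, e), u = cross(ao, d)/cross(d, e)
    cross_de = dirs[:, 0, None] * e[None, :, 1] - dirs[:, 1, None] * e[None, :, 0]  # (R, M)
    cross_aoe = ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]  # (M,)
    cross_aod = ao[None, :, 0] * dirs[:, 1, None] - ao[None, :, 1] * dirs[:, 0, None]  # (R, M)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cross_aoe[None, :] / cross_de
        u = cross_aod / cross_de
    valid = (u >= 0.0) & (u < 1.0) & (s > 0.0) & np.isfinite(s)
    s = np.where(valid, s, np.nan)
    return np.stack([np.nanmin(s, axis=1), np.nanmax(s, axis=1)], axis=1)


def _section_truth(
    outer: RadialFn,
    wall: RadialFn,
    frac: float,
    n_quad: int = 14400,
    n_poly: int = 1440,
) -> dict:
    """Analytic per-section truth: centroid, radii, thickness, SMA profile.

    Area and moment integrals use dense periodic trapezoid quadrature
    (``n_quad`` boundary samples); thickness follows the measurement
    definition - ray casting from the *section centroid* against the
    polygonized periosteal and endosteal contours.
    """
    # half-step offset keeps integer-degree rays off polygon vertices
    phi = (np.arange(n_quad) + 0.5) * (360.0 / n_quad)
    th = np.deg2rad(phi)
    ro = np.asarray(outer(phi, frac), dtype=float)
    ri = ro - np.asarray(wall(phi, frac), dtype=float)
    dphi = 2 * np.pi / n_quad
    cos, sin = np.cos(th), np.sin(th)
    area = np.sum(ro**2 - ri**2) / 2 * dphi
    sy = np.sum(cos * (ro**3 - ri**3)) / 3 * dphi  # integral of x dA
    sx = np.sum(sin * (ro**3 - ri**3)) / 3 * dphi  # integral of y dA
    ixx0 = np.sum(sin**2 * (ro**4 - ri**4)) / 4 * dphi
    iyy0 = np.sum(cos**2 * (ro**4 - ri**4)) / 4 * dphi
    ixy0 = np.sum(sin * cos * (ro**4 - ri**4)) / 4 * dphi
    cx, cy = sy / area, sx / area
    ixx = ixx0 - area * cy**2
    iyy = iyy0 - area * cx**2
    ixy = ixy0 - area * cx * cy
    theta_half = np.deg2rad(np.arange(N_RAYS // 2))
    sma = np.tile(
        ixx * np.cos(theta_half) ** 2
        + iyy * np.sin(theta_half) ** 2
        - 2 * ixy * np.sin(theta_half) * np.cos(theta_half),
        2,
    )
    theta = np.deg2rad(np.arange(N_RAYS))

    step = n_quad // n_poly
    phi_p, th_p = phi[::step], th[::step]
    ro_p, ri_p = ro[::step], ri[::step]
    outer_pts = np.stack([ro_p * np.cos(th_p), ro_p * np.sin(th_p)], axis=1)
    inner_pts = np.stack([ri_p * np.cos(th_p), ri_p * np.sin(th_p)], axis=1)
    c = np.array([cx, cy])
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    peri = _ray_distances(c, outer_pts, dirs)[:, 1]
    endo = _ray_distances(c, inner_pts, dirs)[:, 0]
    endo = np.where(np.isnan(endo), 0.0, endo)
    return {
        "centroid": c,
        "periosteal_r": peri,
        "endosteal_r": endo,
        "thickness": peri - endo,
        "wall": np.asarray(wall(np.arange(N_RAYS, dtype=float), frac), dtype=float),
        "sma": sma,
        "area": area,
    }


def analytic_truth(outer: RadialFn, wall: RadialFn, fractions: Sequence[float] = SECTION_FRACTIONS) -> dict:
    """Evaluate truth maps on the (sections x 360 rays) grid.

    Returns 17x360 arrays for thickness (centroid-ray definition), the raw
    wall-thickness field, SMA, and periosteal/endosteal radii, plus the
    per-section analytic centroids.
    """
    rows = [_section_truth(outer, wall, float(f) / 100.0) for f in fractions]
    return {
        "fractions": np.asarray(fractions, dtype=float),
        "thickness": np.stack([r["thickness"] for r in rows]),
        "wall": np.stack([r["wall"] for r in rows]),
        "sma": np.stack([r["sma"] for r in rows]),
        "periosteal_r": np.stack([r["periosteal_r"] for r in rows]),
        "endosteal_r": np.stack([r["endosteal_r"] for r in rows]),
        "centroid": np.stack([r["centroid"] for r in rows]),
        "area": np.array([r["area"] for r in rows]),
    }


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Voxelize a phantom and attach its analytic truth maps and landmarks.

    Voxel membership is a center-of-voxel test against the analytic tube
    (binary, no anti-aliasing).  The proximal/distal landmarks sit at the
    tube-axis endpoints; the roll-reference landmark sits at angle
    ``90 + roll_offset_deg`` in the volume frame so that roll fixing
    rotates the 0-degree material direction back onto +X.
    """
    outer, wall = _effective_fns(spec)
    _validate_fns(spec, outer, wall)
    v = spec.voxel_mm
    ang_grid, fr_grid = _validation_grid()
    rmax = max(float(np.max(np.asarray(outer(ang_grid, float(f)), dtype=float))) for f in fr_grid)
    margin_xy = 2.0
    margin_z = 2.0
    half = rmax + margin_xy
    nxy = int(math.ceil(2 * half / v)) + 1
    nz = int(math.ceil((spec.length_mm + 2 * margin_z) / v)) + 1
    c_xy = (nxy - 1) / 2.0 * v
    z_prox = ((nz - 1) * v - spec.length_mm) / 2.0

    xs = np.arange(nxy) * v - c_xy
    yy, xx = np.meshgrid(xs, xs, indexing="ij")
    r = np.hypot(xx, yy)
    ang_vol = np.degrees(np.arctan2(yy, xx)) % 360.0
    ang_canon = (ang_vol - spec.roll_offset_deg) % 360.0

    data = np.zeros((nz, nxy, nxy), dtype=np.uint8)
    zc = np.arange(nz) * v
    fracs = (zc - z_prox) / spec.length_mm
    for iz in range(nz):
        f = fracs[iz]
        if f < 0.0 or f > 1.0:
            continue
        ro = np.asarray(outer(ang_canon, float(f)), dtype=float)
        ri = ro - np.asarray(wall(ang_canon, float(f)), dtype=float)
        data[iz] = ((r <= ro) & (r >= ri)).astype(np.uint8)

    roll_rad = np.deg2rad(90.0 + spec.roll_offset_deg)
    roll_ref = np.array(
        [c_xy + rmax * np.cos(roll_rad), c_xy + rmax * np.sin(roll_rad), z_prox]
    )
    landmarks = Landmarks(
        proximal=np.array([c_xy, c_xy, z_prox]),
        distal=np.array([c_xy, c_xy, z_prox + spec.length_mm]),
        roll_reference=roll_ref,
    )
    truth = analytic_truth(outer, wall)
    return Volume(
        data=data,
        spacing=(v, v, v),
        landmarks=landmarks,
        side="left",
        metadata={
            "length_mm": spec.length_mm,
            "roll_offset_deg": spec.roll_offset_deg,
            "seed": spec.seed,
        },
        truth=truth,
    )


def mirror_volume(volume: Volume) -> Volume:
    """Reflect a volume across the mid X plane (left <-> right antimere)."""
    nz, ny, nx = volume.data.shape
    sx = volume.spacing[2]
    data = volume.data[:, :, ::-1].copy()
    lm = volume.landmarks
    new_lm = None
    if lm is not None:
        def flip(p):
            q = p.copy()
            q[0] = (nx - 1) * sx - q[0]
            return q

        new_lm = Landmarks(
            flip(lm.proximal),
            flip(lm.distal),
            flip(lm.roll_reference) if lm.roll_reference is not None else None,
        )
    side = "right" if volume.side == "left" else "left"
    return Volume(
        data=data,
        spacing=volume.spacing,
        landmarks=new_lm,
        side=side,
        metadata=dict(volume.metadata),
        truth=volume.truth,
    )


# --------------------------------------------------------------------------
# cohorts


@dataclass
class GroupSpec:
    """Archetype and jitter parameters of one phantom group."""

    label: str
    n: int
    outer_medial_mm: float  # outer-contour semi-axis along X (medio-lateral)
    outer_dorsoplantar_mm: float  # semi-axis along Y (dorso-plantar)
    wall_mm: float
    length_mm: float = 60.0
    mass_mean_kg: float = 50.0
    taper: float = 0.2  # outer radius scales by 1 + taper*(0.5 - frac)
    bump_amplitude_mm: float = 0.0  # local wall thickening (Gaussian in angle x length)
    bump_center_deg: float = 270.0
    bump_center_pct: float = 30.0
    bump_sigma_deg: float = 30.0
    bump_sigma_pct: float = 8.0
    wall_jitter_cv: float = 0.08  # multiplicative lognormal on the whole wall
    size_jitter_cv: float = 0.05
    phase_jitter_sd_deg: float = 2.0
    length_jitter_cv: float = 0.04
    mass_jitter_cv: float = 0.08

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2 individuals")


@dataclass
class CohortSpec:
    """A multi-group phantom cohort with planted between-group differences."""

    groups: tuple[GroupSpec, ...]
    voxel_mm: float = 0.3
    noise_sd_mm: float = 0.02
    right_fraction: float = 1.0 / 3.0
    cv_band_center_deg: float = 180.0  # angular band of extra between-individual variance
    cv_band_sigma_deg: float = 20.0
    cv_band_amp: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            if g.n < 2:
                raise ValueError("each group needs n >= 2 individuals")


def default_cohort_spec(seed: int = 0, voxel_mm: float = 0.3) -> CohortSpec:
    """The default 43-individual, three-group cohort (14 + 14 + 15).

    Group A emulates a chimpanzee-like thick-walled shaft, group B a
    gorilla-like thick-walled shaft with a plantar-proximal thickening,
    and group C a human-like thin-walled, dorsoplantarly elongated shaft.
    """
    groups = (
        GroupSpec(
            label="A", n=14, outer_medial_mm=5.8, outer_dorsoplantar_mm=5.4,
            wall_mm=2.3, mass_mean_kg=45.0,
        ),
        GroupSpec(
            label="B", n=14, outer_medial_mm=6.4, outer_dorsoplantar_mm=6.0,
            wall_mm=2.2, mass_mean_kg=120.0, bump_amplitude_mm=1.2,
            bump_center_deg=270.0, bump_center_pct=30.0,
        ),
        GroupSpec(
            label="C", n=15, outer_medial_mm=5.2, outer_dorsoplantar_mm=6.8,
            wall_mm=1.4, mass_mean_kg=65.0,
        ),
    )
    return CohortSpec(groups=groups, voxel_mm=voxel_mm, seed=seed)


def _wrapped_diff(a: np.ndarray, center: float) -> np.ndarray:
    d = (np.asarray(a, dtype=float) - center) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def _individual_fns(
    gs: GroupSpec, cohort: CohortSpec, rng: np.random.Generator
) -> tuple[RadialFn, RadialFn, dict]:
    """Draw one individual's outer/wall functions from the group archetype."""
    # lognormal jitter, truncated at 2.5 sd so the sampling-adequacy
    # invariant (voxel <= min wall / 2) cannot be violated by rare draws
    def tnorm(sd: float) -> float:
        return float(np.clip(rng.normal(0.0, sd), -2.5 * sd, 2.5 * sd)) if sd > 0 else 0.0

    s_wall = math.exp(tnorm(gs.wall_jitter_cv))
    s_size = math.exp(tnorm(gs.size_jitter_cv))
    phase = rng.normal(0.0, gs.phase_jitter_sd_deg)
    band_eps = tnorm(cohort.cv_band_amp)
    a_x = gs.outer_medial_mm * s_size
    b_y = gs.outer_dorsoplantar_mm * s_size

    def outer(angle_deg, frac):
        th = np.deg2rad(np.asarray(angle_deg, dtype=float))
        r = a_x * b_y / np.sqrt((b_y * np.cos(th)) ** 2 + (a_x * np.sin(th)) ** 2)
        return r * (1.0 + gs.taper * (0.5 - frac))

    def wall(angle_deg, frac):
        ang = np.asarray(angle_deg, dtype=float) + phase
        w = np.full_like(np.asarray(ang, dtype=float), gs.wall_mm * s_wall)
        if gs.bump_amplitude_mm:
            da = _wrapped_diff(ang, gs.bump_center_deg)
            df = (frac * 100.0 - gs.bump_center_pct) / gs.bump_sigma_pct
            w = w + gs.bump_amplitude_mm * np.exp(
                -0.5 * (da / gs.bump_sigma_deg) ** 2
            ) * math.exp(-0.5 * df**2)
        db = _wrapped_diff(ang, cohort.cv_band_center_deg)
        w = w * np.exp(band_eps * np.exp(-0.5 * (db / cohort.cv_band_sigma_deg) ** 2))
        return w

    draws = {"s_wall": s_wall, "s_size": s_size, "phase_deg": phase, "band_eps": band_eps}
    return outer, wall, draws


def generate_cohort(spec: CohortSpec) -> tuple[list[Volume], pd.DataFrame]:
    """Generate a cohort of phantoms with per-individual metadata.

    Returns the list of volumes (right-sided individuals are stored
    mirrored, to be un-mirrored by the positioning protocol) and a
    metadata table (id, group, sex, side, mass_kg, length_mm, ...).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    volumes: list[Volume] = []
    rows = []
    idx = 0
    for gs in spec.groups:
        for _ in range(gs.n):
            child_seed = int(rng.integers(2**31 - 1))
            ind_rng = np.random.default_rng(child_seed)
            outer, wall, draws = _individual_fns(gs, spec, ind_rng)
            length = gs.length_mm * math.exp(ind_rng.normal(0.0, gs.length_jitter_cv))
            sex = "M" if ind_rng.random() < 0.5 else "F"
            mass = (
                gs.mass_mean_kg
                * (1.15 if sex == "M" else 0.87)
                * math.exp(ind_rng.normal(0.0, gs.mass_jitter_cv))
            )
            side = "right" if ind_rng.random() < spec.right_fraction else "left"
            roll = float(ind_rng.uniform(0.0, 360.0))
            pspec = PhantomSpec(
                length_mm=length,
                outer_radius_fn=outer,
                wall_thickness_fn=wall,
                voxel_mm=spec.voxel_mm,
                roll_offset_deg=roll,
                noise_sd_mm=spec.noise_sd_mm,
                seed=child_seed,
            )
            vol = generate_phantom(pspec)
            if side == "right":
                vol = mirror_volume(vol)
            ind_id = f"{gs.label}{idx:03d}"
            vol.metadata.update(
                id=ind_id, group=gs.label, sex=sex, side=side,
                mass_kg=mass, length_mm=length,
            )
            volumes.append(vol)
            rows.append(
                dict(
                    id=ind_id, group=gs.label, sex=sex, side=side,
                    mass_kg=mass, length_mm=length, roll_offset_deg=roll,
                    seed=child_seed, **draws,
                )
            )
            idx += 1
    return volumes, pd.DataFrame(rows)


def planted_bump_region(gs: GroupSpec, rel_threshold: float = 0.5) -> np.ndarray:
    """Boolean 17x360 mask of a group's planted local thickening.

    A pixel belongs to the region when the bump contribution exceeds
    ``rel_threshold`` times the bump amplitude.
    """
    if gs.bump_amplitude_mm == 0:
        return np.zeros((len(SECTION_FRACTIONS), N_RAYS), dtype=bool)
    ang = np.arange(N_RAYS, dtype=float)
    da = _wrapped_diff(ang, gs.bump_center_deg)
    out = np.zeros((len(SECTION_FRACTIONS), N_RAYS), dtype=bool)
    for i, frac in enumerate(SECTION_FRACTIONS):
        df = (frac - gs.bump_center_pct) / gs.bump_sigma_pct
        g = np.exp(-0.5 * (da / gs.bump_sigma_deg) ** 2) * math.exp(-0.5 * df**2)
        out[i] = g >= rel_threshold
    return out


def band_contrast_cohort(
    n_per_group: int = 14,
    band_center_deg: float = 90.0,
    band_halfwidth_deg: float = 90.0,
    delta_mm: float = 0.5,
    edge_sigma_deg: float = 10.0,
    seed: int = 0,
    voxel_mm: float = 0.3,
) -> tuple[list[Volume], pd.DataFrame, np.ndarray]:
    """Two-group cohort differing only by a thick angular band.

    Group ``thin`` has a uniform wall; group ``thick`` adds ``delta_mm``
    inside a band of half-width ``band_halfwidth_deg`` around
    ``band_center_deg`` (smooth logistic edges), at all section levels.
    Returns (volumes, metadata, planted 17x360 boolean region).  Used to
    validate that discriminant loading maps localize a planted contrast.
    """

    def band(angle_deg):
        d = np.abs(_wrapped_diff(angle_deg, band_center_deg))
        return 1.0 / (1.0 + np.exp((d - band_halfwidth_deg) / edge_sigma_deg))

    groups = []
    for label, extra in (("thin", 0.0), ("thick", delta_mm)):
        groups.append(
            GroupSpec(
                label=label, n=n_per_group, outer_medial_mm=6.0,
                outer_dorsoplantar_mm=6.0, wall_mm=1.8, mass_mean_kg=60.0,
            )
        )
        groups[-1]._band_extra = extra  # type: ignore[attr-defined]

    spec = CohortSpec(groups=tuple(groups), voxel_mm=voxel_mm, seed=seed, cv_band_amp=0.0)
    rng = np.random.default_rng(seed)
    volumes: list[Volume] = []
    rows = []
    idx = 0
    for gs in spec.groups:
        extra = gs._band_extra  # type: ignore[attr-defined]
        for _ in range(gs.n):
            child_seed = int(rng.integers(2**31 - 1))
            ind_rng = np.random.default_rng(child_seed)
            outer, wall_base, draws = _individual_fns(gs, spec, ind_rng)

            def wall(angle_deg, frac, _wb=wall_base, _extra=extra):
                return _wb(angle_deg, frac) + _extra * band(angle_deg)

            length = gs.length_mm * math.exp(ind_rng.normal(0.0, gs.length_jitter_cv))
            pspec = PhantomSpec(
                length_mm=length, outer_radius_fn=outer, wall_thickness_fn=wall,
                voxel_mm=voxel_mm, roll_offset_deg=0.0,
                noise_sd_mm=spec.noise_sd_mm, seed=child_seed,
            )
            vol = generate_phantom(pspec)
            ind_id = f"{gs.label}{idx:03d}"
            vol.metadata.update(
                id=ind_id, group=gs.label, sex="F", side="left",
                mass_kg=60.0, length_mm=length,
            )
            volumes.append(vol)
            rows.append(dict(id=ind_id, group=gs.label, side="left", mass_kg=60.0,
                             length_mm=length, seed=child_seed))
            idx += 1
    ang = np.arange(N_RAYS, dtype=float)
    region_row = band(ang) >= 0.5
    region = np.tile(region_row, (len(SECTION_FRACTIONS), 1))
    return volumes, pd.DataFrame(rows), region
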