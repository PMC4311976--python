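"""Shared fixtures: phantoms and pipeline runs reused across test modules.

The heavyweight objects (measured cohort, high-resolution recovery
phantom, planted-band discriminant fit) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from diamorph import phantom, pipeline, pda

SEED = 1


def annulus_mask(n: int = 121, r_out: float = 50.0, r_in: float = 30.0,
                 center: tuple[float, float] | None = None) -> np.ndarray:
    """Binary annulus on an n x n pixel grid (pixel-center geometry)."""
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    return (r2 <= r_out**2) & (r2 >= r_in**2)


def constant_fns(r_out: float, wall: float):
    outer = lambda a, f: np.full_like(np.asarray(a, dtype=float), r_out)  # noqa: E731
    thick = lambda a, f: np.full_like(np.asarray(a, dtype=float), wall)  # noqa: E731
    return outer, thick


@pytest.fixture(scope="session")
def annulus_phantom_fine():
    """Noise-free circular tube, R=5, wall=2, L=60, voxelized at 0.1 mm."""
    outer, wall = constant_fns(5.0, 2.0)
    spec = phantom.PhantomSpec(60.0, outer, wall, voxel_mm=0.1, seed=SEED)
    return phantom.generate_phantom(spec)


def asymmetric_fns():
    """Elliptical, tapered tube with a plantar-proximal wall thickening."""

    def outer(a, f):
        th = np.deg2rad(np.asarray(a, dtype=float))
        ax, by = 5.2, 6.8
        r = ax * by / np.sqrt((by * np.cos(th)) ** 2 + (ax * np.sin(th)) ** 2)
        return r * (1 + 0.2 * (0.5 - f))

    def wall(a, f):
        aa = np.asarray(a, dtype=float)
        d = (aa - 270.0) % 360.0
        d = np.where(d > 180, d - 360, d)
        return 1.8 + 1.2 * np.exp(-0.5 * (d / 30.0) ** 2) * np.exp(
            -0.5 * ((f * 100 - 30) / 8.0) ** 2
        )

    return outer, wall


@pytest.fixture(scope="session")
def recovery_measurement():
    """Noise-free asymmetric phantom at 0.1 mm voxels, rolled 137 deg and
    stored right-sided, pushed through the full positioning + measurement
    pipeline.  Returns (volume, measured thickness map, measured SMA map)."""
    outer, wall = asymmetric_fns()
    spec = phantom.PhantomSpec(
        60.0, outer, wall, voxel_mm=0.1, roll_offset_deg=137.0, seed=3
    )
    vol = phantom.mirror_volume(phantom.generate_phantom(spec))
    m = pipeline.measure_volume(vol, pipeline.RunConfig(seed=SEED))
    return vol, m.thickness, m.sma


@pytest.fixture(scope="session")
def cohort_result():
    """Full default-cohort pipeline run (43 phantoms, CBT + SMA, PDA)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pipeline.run_pipeline(pipeline.RunConfig(seed=SEED))


@pytest.fixture(scope="session")
def band_fit():
    """PDA fit on the two-group planted-band cohort; returns
    (model, selection, planted region, X, labels)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        vols, meta, region = phantom.band_contrast_cohort(n_per_group=10, seed=SEED)
        cfg = pipeline.RunConfig(seed=SEED)
        ms = [pipeline.measure_volume(v, cfg) for v in vols]
        mlist = pipeline.build_maps(ms, meta, "CBT")
    x = pda.flatten_maps([m.values for m in mlist])
    labels = np.array([m.group for m in mlist])
    pen = pda.CylinderPenalty((17, 360))
    grid = pda.default_lambda_grid(x, pen)
    sel = pda.select_lambda(
        x, labels, penalty=pen, lambda_grid=grid, n_folds=10, repeats=20, seed=SEED
    )
    model = pda.fit_pda(x, labels, sel.lambda_, penalty=pen)
    return model, sel, region, x, labels
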