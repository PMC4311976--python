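"""Positioning protocol: axis alignment, roll fixing, mirroring, reslicing.

The protocol reproduces standard long-bone positioning: the line through
the proximal and distal articular landmarks is rotated parallel to the
Z axis (proximal at lower Z), the bone is rolled about Z until the
roll-reference direction parallels +Y, and right-sided elements are
mirrored into left antimere form.  Mechanical length is the Z distance
between the two landmarks after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import Landmarks, Volume


@dataclass
class AlignedRendering:
    """A repositioned volume with its landmark axis on Z."""

    volume: Volume
    length_mm: float
    side: str
    roll_fixed: bool = False
    mirrored: bool = False

    @property
    def landmarks(self) -> Landmarks:
        lm = self.volume.landmarks
        if lm is None:
            raise ValueError("rendering has no landmarks")
        return lm


def _rot_zyx(r_xyz: np.ndarray) -> np.ndarray:
    # world rotation in (x, y, z) -> same map expressed on (z, y, x) vectors
    return r_xyz[::-1, ::-1].copy()


def _resample_rigid(
    volume: Volume, r_xyz: np.ndarray, spacing_out: float, order: int = 0
) -> Volume:
    """Apply a world rotation and reslice onto an axis-aligned isotropic grid.

    Binary masks are resampled nearest-neighbour (``order=0``); grayscale
    data may use linear interpolation and should be re-thresholded by the
    caller.  Landmarks are transformed exactly (no interpolation).
    """
    rz = _rot_zyx(r_xyz)
    s_in = np.diag(volume.spacing)
    nz, ny, nx = volume.data.shape
    corners = np.array(
        [[iz, iy, ix] for iz in (0, nz - 1) for iy in (0, ny - 1) for ix in (0, nx - 1)],
        dtype=float,
    )
    w_out = (rz @ (s_in @ corners.T)).T
    lo = w_out.min(axis=0) - spacing_out
    hi = w_out.max(axis=0) + spacing_out
    shape_out = tuple(int(np.floor((hi[i] - lo[i]) / spacing_out)) + 1 for i in range(3))
    # affine_transform maps output index -> input index
    m = np.linalg.inv(s_in) @ rz.T * spacing_out
    off = np.linalg.inv(s_in) @ rz.T @ lo
    data = ndimage.affine_transform(
        volume.data.astype(np.uint8),
        m,
        offset=off,
        output_shape=shape_out,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    if order > 0:
        data = (data >= 0.5).astype(np.uint8)

    lm = volume.landmarks
    new_lm = None
    if lm is not None:
        def tf(p_xyz):
            w = rz @ p_xyz[::-1] - lo  # to output (z, y, x) world
            return w[::-1]

        new_lm = Landmarks(
            tf(lm.proximal),
            tf(lm.distal),
            tf(lm.roll_reference) if lm.roll_reference is not None else None,
        )
    return Volume(
        data=data,
        spacing=(spacing_out,) * 3,
        landmarks=new_lm,
        side=volume.side,
        metadata=dict(volume.metadata),
        truth=volume.truth,
    )


def align_to_axis(volume: Volume, landmarks: Landmarks | None = None) -> AlignedRendering:
    """Rigidly rotate the volume so the landmark axis parallels Z.

    The proximal landmark ends at lower Z; the volume is resliced onto an
    isotropic grid at the finest input spacing.  An already-aligned volume
    on an isotropic grid passes through untouched (identity fast path).
    """
    lm = landmarks if landmarks is not None else volume.landmarks
    if lm is None:
        raise ValueError("landmarks required for alignment")
    u = lm.distal - lm.proximal
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise ValueError("degenerate landmarks: proximal and distal coincide")
    u = u / norm
    isotropic = np.allclose(volume.spacing, volume.spacing[0])
    if np.allclose(u, [0.0, 0.0, 1.0], atol=1e-9) and isotropic:
        out = volume if landmarks is None else volume.copy(landmarks=lm)
        length = float(lm.distal[2] - lm.proximal[2])
        return AlignedRendering(volume=out, length_mm=length, side=volume.side)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [u])
    r = rot.as_matrix()
    spacing_out = float(min(volume.spacing))
    src = volume if landmarks is None else volume.copy(landmarks=lm)
    out = _resample_rigid(src, r, spacing_out)
    new_lm = out.landmarks
    length = float(new_lm.distal[2] - new_lm.proximal[2])
    if length <= 0:
        raise ValueError("alignment failed: proximal landmark not at lower Z")
    return AlignedRendering(volume=out, length_mm=length, side=out.side)


def fix_roll(rendering: AlignedRendering, landmarks: Landmarks | None = None) -> AlignedRendering:
    """Rotate about Z so the roll-reference direction parallels +Y.

    The reference direction is the XY offset of the roll-reference
    landmark from the shaft axis; a reference on the axis is rejected.
    A reference already on +Y (including 360-degree offsets) is a no-op.
    """
    lm = landmarks if landmarks is not None else rendering.landmarks
    if lm.roll_reference is None:
        raise ValueError("roll reference landmark required")
    vxy = lm.roll_reference[:2] - lm.proximal[:2]
    if np.linalg.norm(vxy) < max(rendering.volume.spacing) * 0.5:
        raise ValueError("roll reference lies on the Z axis; roll undefined")
    alpha = np.degrees(np.arctan2(vxy[1], vxy[0]))
    delta = (90.0 - alpha) % 360.0
    if min(delta, 360.0 - delta) < 1e-9:
        return replace(rendering, roll_fixed=True)
    dr = np.deg2rad(delta)
    r = np.array(
        [
            [np.cos(dr), -np.sin(dr), 0.0],
            [np.sin(dr), np.cos(dr), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    src = rendering.volume if landmarks is None else rendering.volume.copy(landmarks=lm)
    out = _resample_rigid(src, r, float(min(rendering.volume.spacing)))
    return AlignedRendering(
        volume=out,
        length_mm=float(out.landmarks.distal[2] - out.landmarks.proximal[2]),
        side=out.side,
        roll_fixed=True,
        mirrored=rendering.mirrored,
    )


def mirror(rendering: AlignedRendering) -> AlignedRendering:
    """Reflect across the mid-X plane (medio-lateral flip); an involution."""
    vol = rendering.volume
    nz, ny, nx = vol.data.shape
    sx = vol.spacing[2]
    data = vol.data[:, :, ::-1].copy()
    lm = vol.landmarks
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
    new_side = "right" if vol.side == "left" else "left"
    out = Volume(
        data=data, spacing=vol.spacing, landmarks=new_lm, side=new_side,
        metadata=dict(vol.metadata), truth=vol.truth,
    )
    return AlignedRendering(
        volume=out, length_mm=rendering.length_mm, side=new_side,
        roll_fixed=rendering.roll_fixed, mirrored=not rendering.mirrored,
    )


def mirror_if_right(rendering: AlignedRendering) -> AlignedRendering:
    """Mirror right-sided elements into left antimere form; leave left alone."""
    if rendering.side == "right":
        return mirror(rendering)
    return rendering


def mechanical_length(rendering: AlignedRendering) -> float:
    """Z distance between proximal and distal landmarks (mm)."""
    lm = rendering.landmarks
    length = float(abs(lm.distal[2] - lm.proximal[2]))
    if length <= 0:
        raise ValueError("zero mechanical length")
    return length


def position_volume(volume: Volume) -> AlignedRendering:
    """Full positioning protocol: align, fix roll, mirror if right-sided."""
    rendering = align_to_axis(volume)
    rendering = fix_roll(rendering)
    return mirror_if_right(rendering)
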