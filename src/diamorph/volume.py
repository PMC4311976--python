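"""Voxel volume container, landmarks, and plain-text volume I/O.

Conventions used throughout the package:

* voxel arrays are indexed ``[z, y, x]`` (slice, row, column);
* physical points are ``(x, y, z)`` in millimetres, where the world
  coordinate of voxel index ``(iz, iy, ix)`` is
  ``(ix * sx, iy * sy, iz * sz)`` (0-based indices);
* the Z axis is the longitudinal (proximal -> distal) axis after
  positioning; X is medio-lateral, Y is dorso-plantar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Landmarks:
    """Positioning landmarks of a long-bone volume.

    ``proximal`` and ``distal`` sit at the centres of the articular
    surfaces; ``roll_reference`` is a point whose direction from the
    shaft axis defines the roll orientation (it is rotated onto +Y).
    All points are ``(x, y, z)`` in mm.
    """

    proximal: np.ndarray
    distal: np.ndarray
    roll_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.roll_reference is not None:
            self.roll_reference = np.asarray(self.roll_reference, dtype=float)
        if self.proximal.shape != (3,) or self.distal.shape != (3,):
            raise ValueError("landmarks must be 3D points (x, y, z) in mm")
        if np.allclose(self.proximal, self.distal):
            raise ValueError("proximal and distal landmarks coincide")


@dataclass
class Volume:
    """A 3D voxel grid with physical spacing and optional landmarks.

    ``data`` is a binary (or thresholdable grayscale) array indexed
    ``[z, y, x]``; ``spacing`` is ``(sz, sy, sx)`` in mm.  ``truth``
    optionally carries analytic ground-truth fields for phantoms.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    landmarks: Landmarks | None = None
    side: str = "left"
    metadata: dict = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, y, x)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> np.ndarray:
        """Physical extent (x, y, z) in mm."""
        nz, ny, nx = self.data.shape
        sz, sy, sx = self.spacing
        return np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz])

    def copy(self, **changes) -> "Volume":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


def _format_point(p: np.ndarray) -> str:
    return " ".join(f"{v:.6f}" for v in p)


def save_volume(volume: Volume, prefix: str | Path) -> tuple[Path, Path]:
    """Export a volume as a multi-page TIFF stack plus a sidecar text file.

    The sidecar holds ``key = value`` lines: spacing, landmarks (x y z in
    mm, 0-based voxel origin), side and any scalar/string metadata.
    Returns the two written paths.
    """
    prefix = Path(prefix)
    tif_path = prefix.with_suffix(".tif")
    txt_path = prefix.with_suffix(".txt")
    tifffile.imwrite(tif_path, volume.data.astype(np.uint8))
    lines = [
        "# diamorph volume sidecar; points are 'x y z' in mm,",
        "# axis order x=column, y=row, z=slice, 0-based voxel origin",
        f"spacing_mm = {volume.spacing[0]} {volume.spacing[1]} {volume.spacing[2]}",
        f"side = {volume.side}",
    ]
    if volume.landmarks is not None:
        lm = volume.landmarks
        lines.append(f"proximal_mm = {_format_point(lm.proximal)}")
        lines.append(f"distal_mm = {_format_point(lm.distal)}")
        if lm.roll_reference is not None:
            lines.append(f"roll_reference_mm = {_format_point(lm.roll_reference)}")
    for key, val in volume.metadata.items():
        if isinstance(val, (str, int, float, np.integer, np.floating)):
            lines.append(f"meta.{key} = {val}")
    txt_path.write_text("\n".join(lines) + "\n")
    return tif_path, txt_path


def load_volume(prefix: str | Path) -> Volume:
    """Load a volume written by :func:`save_volume`."""
    prefix = Path(prefix)
    tif_path = prefix.with_suffix(".tif")
    txt_path = prefix.with_suffix(".txt")
    data = tifffile.imread(tif_path)
    fields: dict[str, str] = {}
    for line in txt_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip()] = val.strip()
    spacing = tuple(float(v) for v in fields["spacing_mm"].split())
    landmarks = None
    if "proximal_mm" in fields:
        roll = None
        if "roll_reference_mm" in fields:
            roll = np.array([float(v) for v in fields["roll_reference_mm"].split()])
        landmarks = Landmarks(
            proximal=np.array([float(v) for v in fields["proximal_mm"].split()]),
            distal=np.array([float(v) for v in fields["distal_mm"].split()]),
            roll_reference=roll,
        )
    metadata = {}
    for key, val in fields.items():
        if key.startswith("meta."):
            try:
                metadata[key[5:]] = float(val) if "." in val or val.lstrip("-").isdigit() else val
            except ValueError:
                metadata[key[5:]] = val
            # keep plain strings as strings
            if isinstance(metadata[key[5:]], float) and val.lstrip("-").isdigit():
                metadata[key[5:]] = int(val)
    return Volume(
        data=data,
        spacing=spacing,  # type: ignore[arg-type]
        landmarks=landmarks,
        side=fields.get("side", "left"),
        metadata=metadata,
    )


def load_landmarks(path: str | Path) -> Landmarks:
    """Read a plain-text landmark file.

    Format: one point per line, ``x y z`` in physical mm (0-based voxel
    origin), in the order proximal, distal, roll reference (the third
    line is optional).  Blank lines and ``#`` comments are ignored.
    """
    pts = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        pts.append(np.array([float(v) for v in line.split()]))
    if len(pts) < 2:
        raise ValueError("landmark file must contain at least proximal and distal points")
    return Landmarks(pts[0], pts[1], pts[2] if len(pts) > 2 else None)
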