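"""Core domain types for SD-OCT fovea detection.

Defines the physical scan geometry of common macular cube protocols, the
in-memory volume container used by every pipeline stage, the final fovea
detection result, and volume/result I/O.

Coordinate convention (used everywhere in this package):

* ``x`` — fast lateral axis within a B-scan (0-based voxel index),
* ``y`` — slow axis across B-scans,
* ``z`` — axial depth, increasing away from the vitreous,

and physical positions refer to voxel *centers*: the voxel with index ``i``
along an axis with spacing ``s`` sits at ``(i + 0.5) * s`` micrometres.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "VendorGeometry",
    "Stage",
    "Appearance",
    "OCTVolume",
    "FoveaResult",
    "vendor_preset",
    "VENDOR_PRESETS",
    "voxel_to_physical",
    "physical_to_voxel",
    "y_spacing_um",
    "load_volume",
    "save_volume",
]

#: Voxel counts (nx, ny, nz) of the macular cube protocols this package
#: understands out of the box.  All cover a nominal 6 x 6 x 2 mm field.
VENDOR_PRESETS: dict[str, tuple[int, int, int]] = {
    "cirrus_200": (200, 200, 1024),
    "cirrus_512": (512, 128, 1024),
    "topcon_256": (256, 256, 885),
    "topcon_512": (512, 128, 885),
    "spectralis_49": (512, 49, 496),
}

DEFAULT_EXTENT_UM = (6000.0, 6000.0, 2000.0)


@dataclass(frozen=True)
class VendorGeometry:
    """Voxel grid dimensions plus physical field of view of an OCT cube.

    Parameters
    ----------
    name
        Free-form label ("cirrus_200", "custom", ...).
    nx, ny, nz
        Voxel counts along the fast lateral, slow (B-scan) and axial axes.
    extent_x_um, extent_y_um, extent_z_um
        Physical field of view in micrometres (default 6000 x 6000 x 2000).
    """

    name: str
    nx: int
    ny: int
    nz: int
    extent_x_um: float = DEFAULT_EXTENT_UM[0]
    extent_y_um: float = DEFAULT_EXTENT_UM[1]
    extent_z_um: float = DEFAULT_EXTENT_UM[2]

    def __post_init__(self) -> None:
        for label, n in (("nx", self.nx), ("ny", self.ny), ("nz", self.nz)):
            if int(n) < 2:
                raise ValueError(f"{label} must be >= 2, got {n}")
        for label, e in (
            ("extent_x_um", self.extent_x_um),
            ("extent_y_um", self.extent_y_um),
            ("extent_z_um", self.extent_z_um),
        ):
            if not e > 0:
                raise ValueError(f"{label} must be > 0, got {e}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def dx_um(self) -> float:
        return self.extent_x_um / self.nx

    @property
    def dy_um(self) -> float:
        return self.extent_y_um / self.ny

    @property
    def dz_um(self) -> float:
        return self.extent_z_um / self.nz

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return (self.dx_um, self.dy_um, self.dz_um)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nx": self.nx,
            "ny": self.ny,
            "nz": self.nz,
            "extent_x_um": self.extent_x_um,
            "extent_y_um": self.extent_y_um,
            "extent_z_um": self.extent_z_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VendorGeometry":
        if "preset" in d:
            return vendor_preset(d["preset"])
        return cls(
            name=d.get("name", "custom"),
            nx=int(d["nx"]),
            ny=int(d["ny"]),
            nz=int(d["nz"]),
            extent_x_um=float(d.get("extent_x_um", DEFAULT_EXTENT_UM[0])),
            extent_y_um=float(d.get("extent_y_um", DEFAULT_EXTENT_UM[1])),
            extent_z_um=float(d.get("extent_z_um", DEFAULT_EXTENT_UM[2])),
        )


def vendor_preset(name: str) -> VendorGeometry:
    """Return the geometry of a named macular cube protocol.

    Raises
    ------
    KeyError
        If ``name`` is not one of :data:`VENDOR_PRESETS`.
    """
    try:
        nx, ny, nz = VENDOR_PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(VENDOR_PRESETS))
        raise KeyError(f"unknown vendor preset {name!r}; valid presets: {valid}") from None
    return VendorGeometry(name=name, nx=nx, ny=ny, nz=nz)


def y_spacing_um(geom: VendorGeometry, fencepost: bool = False) -> float:
    """Slow-axis (B-scan) spacing in micrometres.

    By default the slab pitch ``extent_y / ny`` is returned.  With
    ``fencepost=True`` the inter-B-scan interval ``extent_y / (ny - 1)`` is
    used instead, which is the relevant figure when quantifying how far a
    one-B-scan misalignment moves a landmark on sparse raster protocols
    (e.g. ~125 um on a 49-B-scan raster over 6 mm).
    """
    if fencepost:
        return geom.extent_y_um / (geom.ny - 1)
    return geom.dy_um


class Stage(enum.Enum):
    """Pipeline state of a volume: raw, motion/tilt corrected, speckle
    denoised, segmented, or cropped to the foveal cylinder."""

    RAW = "raw"
    MOTION_CORRECTED = "motion_corrected"
    DENOISED = "denoised"
    SEGMENTED = "segmented"
    MASKED = "masked"

    @property
    def order(self) -> int:
        return list(Stage).index(self)


class Appearance(enum.Enum):
    """Foveal appearance class: normal, minor, or absent foveal depression."""

    NFD = "NFD"
    MFD = "MFD"
    AFD = "AFD"


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid together with its physical geometry.

    ``voxels`` is indexed ``(x, y, z)`` with intensities in ``[0, 1]``.
    ``stage`` tracks where the volume sits in the processing chain; a
    MASKED volume must carry the 2D ``(x, y)`` boolean ``mask`` and be
    zero everywhere outside it.
    """

    voxels: np.ndarray
    geometry: VendorGeometry
    stage: Stage = Stage.RAW
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != self.geometry.shape:
            raise ValueError(
                f"voxel grid shape {self.voxels.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be non-negative")
        if self.stage is Stage.MASKED:
            if self.mask is None:
                raise ValueError("MASKED volume requires a mask")
            if self.mask.shape != (self.geometry.nx, self.geometry.ny):
                raise ValueError("mask shape must be (nx, ny)")
            outside = self.voxels[~self.mask, :]
            if outside.size and float(np.abs(outside).max()) > 0:
                raise ValueError("MASKED volume has nonzero voxels outside the mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def bscan(self, y: int) -> np.ndarray:
        """The B-scan at slow-axis index ``y`` as an ``(x, z)`` array."""
        return self.voxels[:, y, :]

    def with_voxels(self, voxels: np.ndarray, stage: Stage,
                    mask: Optional[np.ndarray] = None) -> "OCTVolume":
        return OCTVolume(voxels=voxels, geometry=self.geometry, stage=stage,
                         mask=self.mask if mask is None else mask)

    def require_stage(self, *allowed: Stage) -> None:
        if self.stage not in allowed:
            names = "/".join(s.name for s in allowed)
            raise ValueError(f"expected a {names} volume, got {self.stage.name}")


@dataclass
class FoveaResult:
    """Final detection output: appearance class plus fovea position.

    The position is reported both as voxel indices and in physical
    micrometres; ``z_um`` is the inner limiting membrane height at
    ``(x, y)``.  ``candidate_count`` is the number of tied candidate
    points merged by the centre-of-mass rule, and ``provenance`` names
    the detection branch that produced the result.
    """

    appearance: Appearance
    x_vox: int
    y_vox: int
    x_um: float
    y_um: float
    z_um: float
    candidate_count: int
    provenance: str
    low_confidence: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.candidate_count < 1:
            raise ValueError("candidate_count must be >= 1")

    def to_dict(self) -> dict:
        return {
            "appearance": self.appearance.value,
            "x_vox": int(self.x_vox),
            "y_vox": int(self.y_vox),
            "x_um": float(self.x_um),
            "y_um": float(self.y_um),
            "z_um": float(self.z_um),
            "candidate_count": int(self.candidate_count),
            "provenance": self.provenance,
            "low_confidence": bool(self.low_confidence),
            "version": 1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoveaResult":
        return cls(
            appearance=Appearance(d["appearance"]),
            x_vox=int(d["x_vox"]),
            y_vox=int(d["y_vox"]),
            x_um=float(d["x_um"]),
            y_um=float(d["y_um"]),
            z_um=float(d["z_um"]),
            candidate_count=int(d["candidate_count"]),
            provenance=d["provenance"],
            low_confidence=bool(d.get("low_confidence", False)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FoveaResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Coordinate conversion


def voxel_to_physical(x_vox: int, y_vox: int, z_vox: int,
                      geom: VendorGeometry) -> tuple[float, float, float]:
    """Physical voxel-centre coordinates ``(i + 0.5) * spacing`` in um."""
    idx = (int(x_vox), int(y_vox), int(z_vox))
    for i, n, label in zip(idx, geom.shape, "xyz"):
        if not 0 <= i < n:
            raise IndexError(f"{label} index {i} out of range [0, {n})")
    return (
        (idx[0] + 0.5) * geom.dx_um,
        (idx[1] + 0.5) * geom.dy_um,
        (idx[2] + 0.5) * geom.dz_um,
    )


def physical_to_voxel(x_um: float, y_um: float, z_um: float,
                      geom: VendorGeometry) -> tuple[int, int, int]:
    """Inverse of :func:`voxel_to_physical`: the voxel whose cell contains
    the physical point (indices clipped to the grid)."""
    spac = geom.spacing_um
    out = []
    for v, s, n in zip((x_um, y_um, z_um), spac, geom.shape):
        i = int(np.floor(v / s))
        out.append(min(max(i, 0), n - 1))
    return tuple(out)


# ---------------------------------------------------------------------------
# Volume I/O


def _read_stack(path: Path) -> np.ndarray:
    """Read a TIFF or NIfTI image stack into an ``(x, y, z)`` float array
    with intensities rescaled to [0, 1]."""
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)  # stored (x, y, z)
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        pages = tifffile.imread(str(path))  # (y, z, x) — one page per B-scan
        if pages.ndim == 2:
            pages = pages[None]
        arr = np.transpose(pages, (2, 0, 1))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float32) / float(info.max)
    else:
        arr = arr.astype(np.float32)
    return arr


def load_volume(path: str | Path, sidecar: str | Path) -> OCTVolume:
    """Load an OCT volume from an image stack plus its JSON sidecar.

    The stack is a multi-page TIFF (one ``(z, x)`` page per B-scan, page
    index = y) or a NIfTI file stored ``(x, y, z)``.  The sidecar declares
    the grid geometry, either as ``{"geometry": {"preset": name}}`` or with
    explicit counts/extents, and optionally the pipeline ``stage``.
    Integer intensities are rescaled to [0, 1] by the dtype maximum.
    """
    path = Path(path)
    meta = json.loads(Path(sidecar).read_text())
    geom = VendorGeometry.from_dict(meta["geometry"])
    arr = _read_stack(path)
    if arr.shape != geom.shape:
        raise ValueError(
            f"stack shape {arr.shape} does not match declared geometry {geom.shape}"
        )
    stage = Stage(meta.get("stage", "raw"))
    mask = None
    if "mask" in meta:
        mask = np.asarray(meta["mask"], dtype=bool)
    return OCTVolume(voxels=arr, geometry=geom, stage=stage, mask=mask)


def save_volume(vol: OCTVolume, path: str | Path, sidecar: str | Path) -> None:
    """Write a volume as float32 TIFF/NIfTI plus a JSON geometry sidecar."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        spac = vol.geometry.spacing_um
        affine = np.diag([spac[0] / 1000.0, spac[1] / 1000.0, spac[2] / 1000.0, 1.0])
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        pages = np.transpose(vol.voxels.astype(np.float32), (1, 2, 0))  # (y, z, x)
        tifffile.imwrite(str(path), pages)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    meta: dict = {"geometry": vol.geometry.to_dict(), "stage": vol.stage.value}
    if vol.mask is not None:
        meta["mask"] = vol.mask.astype(bool).tolist()
    Path(sidecar).write_text(json.dumps(meta))
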