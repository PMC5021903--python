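"""Fovea position detection and pipeline orchestration.

Given the foveal appearance class, the fovea position is computed by one
of two branches:

* **NFD** — at a normal fovea the retinal nerve fiber layer thins to
  zero, so the fovea is the centre of mass of all near-zero points of the
  RNFL thickness map inside the foveal mask.
* **MFD / AFD** — edema deforms the retina and layer segmentation is
  unreliable, so instead the point on the ILM surface closest to the
  boundary of the underlying intraretinal fluid is taken: squared
  pairwise Euclidean distances ``d^2 = (p_ILM - p_IRF)(p_ILM - p_IRF)'``
  are evaluated per B-scan, exact zeros (anatomically impossible) are
  discarded, and the global minimum picks the B-scan and ILM point.  When
  several B-scans tie, the centre of mass of their argmin points is used.

``detect_fovea`` chains preprocessing, masking, segmentation,
classification and the branch detectors into the full pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .classify import ClassifierConfig, classify_appearance
from .core import Appearance, FoveaResult, OCTVolume, physical_to_voxel
from .preprocess import (apply_mask, build_fovea_mask, correct_axial_motion,
                         correct_tilt, denoise_speckle)
from .segment import (IRFRegion, SurfaceMap, ThicknessMap, delineate_ilm,
                      extract_irf_regions, segment_layers_nfd,
                      thickness_between)

__all__ = [
    "DistanceResult",
    "NoZeroThicknessError",
    "NoIRFError",
    "PipelineConfig",
    "pairwise_ilm_irf_distances",
    "center_of_mass",
    "detect_fovea_nfd",
    "detect_fovea_mfd_afd",
    "detect_fovea",
]

log = logging.getLogger(__name__)


class NoZeroThicknessError(RuntimeError):
    """The thickness map has no point at or below the zero tolerance."""


class NoIRFError(RuntimeError):
    """No intraretinal fluid region is available for the MFD/AFD branch."""


@dataclass
class DistanceResult:
    """Outcome of a pairwise ILM-IRF distance computation.

    ``d_um`` holds, sorted ascending, each ILM point's distance to its
    nearest IRF boundary point (exact-zero pairs excluded beforehand);
    its first entry is the global minimum pairwise distance.
    """

    d_um: np.ndarray
    min_distance_um: float
    argmin_ilm_point: np.ndarray
    tied_points: np.ndarray

    def __post_init__(self) -> None:
        if self.min_distance_um <= 0:
            raise ValueError("minimum distance must be positive after zero exclusion")


def pairwise_ilm_irf_distances(p_ilm: np.ndarray, p_irf: np.ndarray,
                               tie_tol: float = 1e-6) -> DistanceResult:
    """All-pairs Euclidean distances between ILM surface points and IRF
    boundary points (physical um), with exact zeros discarded.

    Returns the minimum distance, the ILM point attaining it, and every
    ILM point whose nearest-IRF distance lies within ``tie_tol`` of the
    minimum.
    """
    a = np.atleast_2d(np.asarray(p_ilm, dtype=float))
    b = np.atleast_2d(np.asarray(p_irf, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both point sets must be non-empty")
    d = cdist(a, b)
    d[d == 0.0] = np.inf  # anatomically impossible contact
    per_point = d.min(axis=1)
    finite = np.isfinite(per_point)
    if not finite.any():
        raise ValueError("all pairwise distances are zero; nothing to minimise")
    order = np.argsort(per_point[finite], kind="stable")
    pts = a[finite][order]
    dists = per_point[finite][order]
    tied = pts[dists <= dists[0] + tie_tol]
    return DistanceResult(d_um=dists, min_distance_um=float(dists[0]),
                          argmin_ilm_point=pts[0], tied_points=tied)


def center_of_mass(points: Sequence[Sequence[float]]) -> tuple[float, ...]:
    """Unweighted arithmetic mean of a non-empty set of coordinates."""
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.size == 0:
        raise ValueError("empty point set")
    return tuple(arr.mean(axis=0))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class MotionConfig:
    max_shift_vox: Optional[int] = None


@dataclass
class DenoiseConfig:
    method: str = "nlm"
    strength: float = 1.0


@dataclass
class MaskConfig:
    axis_scale: float = 0.5


@dataclass
class SegmentConfig:
    #: Potts boundary weight for clean two-region segmentation.
    smoothness: float = 0.6
    #: Factor relaxing the smoothing constraint for ILM delineation so the
    #: surface boundary is followed as closely as possible.
    relax_factor: float = 0.25
    #: Hard smoothness bound of the dynamic-programming surface search.
    s_max: int = 2
    #: Minimum connected-component size of a fluid region, in voxels.
    min_volume_vox: int = 50
    #: Minimum in-plane tissue component size kept during ILM extraction.
    min_component_px: int = 30

    @property
    def ilm_smoothness(self) -> float:
        return self.smoothness * self.relax_factor


@dataclass
class DetectConfig:
    #: B-scans whose minimum distances differ by less than this many axial
    #: voxel spacings are treated as tied ("identical" minima).
    tie_tol_dz: float = 0.5


@dataclass
class PipelineConfig:
    motion: MotionConfig = field(default_factory=MotionConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    classify: ClassifierConfig = field(default_factory=ClassifierConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            motion=MotionConfig(**d.get("motion", {})),
            denoise=DenoiseConfig(**d.get("denoise", {})),
            mask=MaskConfig(**d.get("mask", {})),
            segment=SegmentConfig(**d.get("segment", {})),
            classify=ClassifierConfig(**d.get("classify", {})),
            detect=DetectConfig(**d.get("detect", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import json

        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Branch detectors


def _z_from_ilm(ilm: SurfaceMap, x_um: float, y_um: float) -> tuple[float, int, int]:
    """ILM height at the valid grid point nearest to (x_um, y_um)."""
    g = ilm.geometry
    xs, ys = np.nonzero(ilm.valid)
    px = (xs + 0.5) * g.dx_um
    py = (ys + 0.5) * g.dy_um
    i = int(np.argmin((px - x_um) ** 2 + (py - y_um) ** 2))
    return float(ilm.z_um[xs[i], ys[i]]), int(xs[i]), int(ys[i])


def detect_fovea_nfd(thickness: ThicknessMap, ilm: SurfaceMap,
                     cfg: PipelineConfig = PipelineConfig(),
                     mask: Optional[np.ndarray] = None) -> FoveaResult:
    """NFD branch: centre of mass of all near-zero RNFL thickness points.

    Raises :class:`NoZeroThicknessError` when no masked point falls at or
    below the zero-thickness tolerance, so the caller can fall back to
    the fluid-distance branch.
    """
    g = ilm.geometry
    tol = cfg.classify.thickness_tol(g)
    zero = thickness.valid & (thickness.t_um <= tol)
    if mask is not None:
        zero &= mask
    xs, ys = np.nonzero(zero)
    if xs.size == 0:
        raise NoZeroThicknessError(
            f"no thickness point at or below {tol:.2f} um inside the mask")
    x_um, y_um = center_of_mass(np.column_stack([
        (xs + 0.5) * g.dx_um, (ys + 0.5) * g.dy_um]))
    z_um, _, _ = _z_from_ilm(ilm, x_um, y_um)
    x_vox, y_vox, _ = physical_to_voxel(x_um, y_um, z_um, g)
    return FoveaResult(appearance=Appearance.NFD, x_vox=x_vox, y_vox=y_vox,
                       x_um=x_um, y_um=y_um, z_um=z_um,
                       candidate_count=int(xs.size),
                       provenance="nfd-zero-rnfl-com")


def detect_fovea_mfd_afd(ilm: SurfaceMap, irf: Optional[IRFRegion],
                         appearance: Appearance,
                         cfg: PipelineConfig = PipelineConfig()) -> FoveaResult:
    """MFD/AFD branch: minimum ILM-IRF boundary distance, per B-scan.

    For every B-scan crossing the mask the minimum pairwise distance from
    that B-scan's ILM points to all IRF boundary points is computed; the
    B-scan(s) attaining the global minimum (ties within ``tie_tol_dz``
    axial spacings) contribute their argmin ILM points, merged by centre
    of mass.

    When no IRF region is available, :class:`NoIRFError` semantics apply:
    the global ILM elevation maximum is returned instead, flagged
    low-confidence with provenance ``"ilm-minimum-fallback"``.
    """
    g = ilm.geometry
    if irf is None:
        xs, ys = np.nonzero(ilm.valid)
        if xs.size == 0:
            raise NoIRFError("no IRF region and no valid ILM surface")
        elev = ilm.elevation_um()[xs, ys]
        i = int(np.argmax(elev))
        x_vox, y_vox = int(xs[i]), int(ys[i])
        return FoveaResult(
            appearance=appearance, x_vox=x_vox, y_vox=y_vox,
            x_um=(x_vox + 0.5) * g.dx_um, y_um=(y_vox + 0.5) * g.dy_um,
            z_um=float(ilm.z_um[x_vox, y_vox]), candidate_count=1,
            provenance="ilm-minimum-fallback", low_confidence=True)

    tie_tol = cfg.detect.tie_tol_dz * g.dz_um
    per_bscan: list[tuple[int, float, np.ndarray]] = []
    for y in np.nonzero(ilm.valid.any(axis=0))[0]:
        cols = np.nonzero(ilm.valid[:, y])[0]
        pts = np.column_stack([
            (cols + 0.5) * g.dx_um,
            np.full(cols.size, (y + 0.5) * g.dy_um),
            ilm.z_um[cols, y],
        ])
        try:
            res = pairwise_ilm_irf_distances(pts, irf.boundary_points_um,
                                             tie_tol=1e-6)
        except ValueError:
            continue
        per_bscan.append((int(y), res.min_distance_um, res.argmin_ilm_point))
    if not per_bscan:
        raise NoIRFError("distance computation failed on every B-scan")

    dmin = min(d for _, d, _ in per_bscan)
    tied = [(y, p) for y, d, p in per_bscan if d <= dmin + tie_tol]
    x_um, y_um, _ = center_of_mass([p for _, p in tied])
    z_um, _, _ = _z_from_ilm(ilm, x_um, y_um)
    x_vox, y_vox, _ = physical_to_voxel(x_um, y_um, z_um, g)
    return FoveaResult(appearance=appearance, x_vox=x_vox, y_vox=y_vox,
                       x_um=x_um, y_um=y_um, z_um=z_um,
                       candidate_count=len(tied),
                       provenance="mfd-afd-min-ilm-irf-distance")


def _select_irf_region(regions: list[IRFRegion], mask: np.ndarray
                       ) -> Optional[IRFRegion]:
    """The lowest-mean-intensity fluid region whose centroid column lies
    inside the foveal mask (regions arrive sorted darkest first)."""
    nx, ny = mask.shape
    for r in regions:
        cx, cy = int(round(r.centroid_vox[0])), int(round(r.centroid_vox[1]))
        if 0 <= cx < nx and 0 <= cy < ny and mask[cx, cy]:
            return r
    return None


# ---------------------------------------------------------------------------
# Full pipeline


def detect_fovea(vol: OCTVolume,
                 cfg: PipelineConfig = PipelineConfig()) -> FoveaResult:
    """Run the full detection chain on a raw volume.

    Stages: axial motion correction -> tilt correction -> speckle
    denoising -> foveal masking -> ILM delineation -> (two-surface layer
    segmentation for the NFD test) -> appearance classification ->
    appearance-specific position detection.  Deterministic for a fixed
    volume and configuration.
    """
    g = vol.geometry
    corrected, _profile = correct_axial_motion(vol, cfg.motion.max_shift_vox)
    corrected, _slopes = correct_tilt(corrected)
    denoised = denoise_speckle(corrected, strength=cfg.denoise.strength,
                               method=cfg.denoise.method)
    fmask = build_fovea_mask(g, axis_scale=cfg.mask.axis_scale)
    masked = apply_mask(denoised, fmask)

    ilm = delineate_ilm(masked, smoothness=cfg.segment.ilm_smoothness,
                        min_component_px=cfg.segment.min_component_px)

    thickness: Optional[ThicknessMap] = None
    try:
        ilm_dp, rnfl_dp = segment_layers_nfd(masked, s_max=cfg.segment.s_max)
        thickness = thickness_between(ilm_dp, rnfl_dp)
    except Exception as exc:  # layer search may fail on pathological scans
        log.warning("two-surface segmentation unavailable: %s", exc)

    appearance, diag = classify_appearance(ilm, thickness, g, cfg.classify,
                                           mask=fmask.grid)

    if appearance is Appearance.NFD and thickness is not None:
        try:
            result = detect_fovea_nfd(thickness, ilm, cfg, mask=fmask.grid)
            result.diagnostics = diag
            return result
        except NoZeroThicknessError:
            log.warning("NFD branch found no zero-thickness point; "
                        "falling back to the fluid-distance branch")

    regions = extract_irf_regions(masked, ilm,
                                  min_volume_vox=cfg.segment.min_volume_vox)
    region = _select_irf_region(regions, fmask.grid)
    result = detect_fovea_mfd_afd(ilm, region, appearance, cfg)
    result.diagnostics = diag
    if diag.get("low_confidence"):
        result.low_confidence = True
    return result
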