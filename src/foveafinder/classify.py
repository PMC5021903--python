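"""Foveal appearance classification: normal (NFD), minor (MFD), or absent
(AFD) foveal depression.

The ILM elevation profile of each B-scan crossing the foveal mask is
analysed as a curve.  A *peak* is a data point strictly larger than both
of its neighbours.  The MFD signature is a two-peak curve (a residual
depression elevated by underlying edema, global maximum among the peaks);
the AFD signature is a single conical/parabolic dome; the NFD signature
is a central depression.  A shape only counts when it persists across a
contiguous slow-axis distance of 150 um — a physical distance rather than
a number of B-scans, because slice spacing varies several-fold between
vendor protocols (the mean fovea centralis diameter is ~1.5 mm).

The final decision also consults the retinal nerve fiber layer (RNFL)
thickness: at a normal fovea the RNFL thins to zero, so the NFD test
requires a near-zero thickness point inside the mask.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import peak_prominences
from scipy.ndimage import median_filter, uniform_filter1d

from .core import Appearance, VendorGeometry
from .segment import SurfaceMap, ThicknessMap

__all__ = [
    "ProfileShape",
    "ProfileAnalysis",
    "ClassifierConfig",
    "find_curve_peaks",
    "analyze_bscan_profile",
    "confirm_contiguity",
    "classify_appearance",
    "UnclassifiableError",
]

log = logging.getLogger(__name__)


class UnclassifiableError(RuntimeError):
    """Raised when the ILM surface is entirely invalid."""


class ProfileShape(enum.Enum):
    DEPRESSION = "depression"
    TWO_PEAK = "two_peak"
    SINGLE_PEAK = "single_peak"
    FLAT = "flat"


@dataclass
class ProfileAnalysis:
    """Shape analysis of one B-scan's ILM elevation profile."""

    y_index: int
    peaks: list[int]
    global_max_x: Optional[int]
    shape: ProfileShape


@dataclass
class ClassifierConfig:
    """Tunables of the appearance classifier.

    contiguity_um
        Minimum contiguous slow-axis extent over which a profile shape
        must persist (default 150, about a tenth of the mean fovea
        centralis diameter).
    fovea_diameter_um
        Reference fovea centralis diameter (1500).
    zero_thickness_tol_um
        RNFL thickness below which a point counts as "zero thickness";
        None (default) means one axial voxel of the scan at hand.
    min_prominence_um
        Elevation prominence a peak (or the central depression) must
        reach to count; guards the strict peak definition against
        residual surface noise.
    smooth_window
        Moving-average window (columns) applied to the elevation profile
        before shape analysis.
    """

    contiguity_um: float = 150.0
    fovea_diameter_um: float = 1500.0
    zero_thickness_tol_um: Optional[float] = None
    min_prominence_um: float = 20.0
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.contiguity_um <= self.fovea_diameter_um:
            raise ValueError("contiguity_um must lie in (0, fovea_diameter_um]")

    def thickness_tol(self, geom: VendorGeometry) -> float:
        return self.zero_thickness_tol_um if self.zero_thickness_tol_um is not None \
            else geom.dz_um


def find_curve_peaks(elevation: Sequence[float]) -> list[int]:
    """Indices of curve peaks: data points strictly larger than both
    neighbouring data points.

    A plateau run of equal values is not a peak unless the whole run is
    strictly above both flanking values, in which case the run's centre
    index is returned.  Profiles with fewer than 3 points have no peaks.
    """
    e = np.asarray(elevation, dtype=float)
    n = len(e)
    if n < 3:
        return []
    peaks: list[int] = []
    i = 1
    while i < n - 1:
        if e[i] > e[i - 1]:
            j = i
            while j + 1 < n and e[j + 1] == e[i]:
                j += 1
            if j < n - 1 and e[j + 1] < e[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def _smooth(profile: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(profile) < 3:
        return profile
    med = median_filter(profile, size=3, mode="nearest")
    return uniform_filter1d(med, size=min(window, len(profile)), mode="nearest")


def _prominent_peaks(profile: np.ndarray, peaks: list[int],
                     min_prom: float) -> list[int]:
    if not peaks:
        return []
    proms = peak_prominences(profile, np.asarray(peaks))[0]
    return [p for p, pr in zip(peaks, proms) if pr >= min_prom]


def _is_unimodal(profile: np.ndarray, peak: int, tol: float) -> bool:
    """Non-increasing away from ``peak`` after 3-point median smoothing,
    up to ``tol`` of allowed backsliding."""
    sm = median_filter(profile, size=3, mode="nearest")
    left = sm[: peak + 1]
    right = sm[peak:]
    up_violation = float(np.maximum(np.diff(left[::-1]), 0).max(initial=0.0))
    down_violation = float(np.maximum(np.diff(right), 0).max(initial=0.0))
    return max(up_violation, down_violation) <= tol


def _central_depression(profile: np.ndarray, min_prom: float) -> bool:
    """True when the centre of the masked region is a local elevation
    minimum flanked on both sides by values at least ``min_prom`` higher."""
    n = len(profile)
    lo, hi = n // 4, max(n // 4 + 1, (3 * n) // 4)
    centre = profile[lo:hi]
    i_min = lo + int(np.argmin(centre))
    v = profile[i_min]
    left_rise = float(profile[:i_min].max(initial=-np.inf)) - v
    right_rise = float(profile[i_min + 1:].max(initial=-np.inf)) - v
    return min(left_rise, right_rise) >= min_prom


def analyze_bscan_profile(ilm: SurfaceMap, y: int,
                          cfg: ClassifierConfig = ClassifierConfig()
                          ) -> ProfileAnalysis:
    """Classify the shape of the ILM elevation profile of B-scan ``y``.

    TWO_PEAK when at least two prominent peaks exist and the global
    elevation maximum is one of them; SINGLE_PEAK when exactly one
    prominent peak exists, is the global maximum, and the profile is
    unimodal; DEPRESSION when the masked-region centre is a prominent
    local minimum; FLAT otherwise (including too few valid columns).
    """
    valid_cols = np.nonzero(ilm.valid[:, y])[0]
    if valid_cols.size < 3:
        log.warning("B-scan %d has <3 valid ILM columns; shape FLAT", y)
        return ProfileAnalysis(y_index=y, peaks=[], global_max_x=None,
                               shape=ProfileShape.FLAT)
    elev = ilm.elevation_um()[valid_cols, y]
    sm = _smooth(elev, cfg.smooth_window)

    raw_peaks = find_curve_peaks(sm)
    peaks = _prominent_peaks(sm, raw_peaks, cfg.min_prominence_um)
    gmax_local = int(np.argmax(sm))
    global_max_x = int(valid_cols[gmax_local])
    peaks_global = [int(valid_cols[p]) for p in peaks]

    near_tol = max(2, len(sm) // 25)
    gmax_is_peak = any(abs(p - gmax_local) <= near_tol for p in peaks)

    if len(peaks) >= 2 and gmax_is_peak:
        shape = ProfileShape.TWO_PEAK
    elif len(peaks) == 1 and gmax_is_peak and _is_unimodal(
            sm, peaks[0], tol=cfg.min_prominence_um / 2):
        shape = ProfileShape.SINGLE_PEAK
    elif _central_depression(sm, cfg.min_prominence_um):
        shape = ProfileShape.DEPRESSION
    else:
        shape = ProfileShape.FLAT
    return ProfileAnalysis(y_index=y, peaks=peaks_global,
                           global_max_x=global_max_x, shape=shape)


def confirm_contiguity(shapes: Sequence[ProfileShape], target: ProfileShape,
                       geom: VendorGeometry,
                       cfg: ClassifierConfig = ClassifierConfig()) -> bool:
    """True iff some run of consecutive B-scans labelled ``target`` spans
    at least ``contiguity_um`` of slow-axis distance.

    Each B-scan is counted as a slab of thickness dy, i.e. a run of k
    B-scans covers k * dy um — so a single B-scan of a wide-pitch raster
    can satisfy the criterion on its own.
    """
    dy = geom.dy_um
    run = 0
    for s in shapes:
        run = run + 1 if s is target else 0
        if run * dy >= cfg.contiguity_um:
            return True
    return False


def classify_appearance(ilm: SurfaceMap,
                        thickness: Optional[ThicknessMap],
                        geom: VendorGeometry,
                        cfg: ClassifierConfig = ClassifierConfig(),
                        mask: Optional[np.ndarray] = None
                        ) -> tuple[Appearance, dict]:
    """Decide the foveal appearance class of a masked volume.

    Decision order (most specific first):

    1. NFD — the RNFL thickness map has a point at or below the
       zero-thickness tolerance inside the mask, and the DEPRESSION
       profile shape persists over the contiguity distance;
    2. MFD — the TWO_PEAK shape persists over the contiguity distance;
    3. AFD — the SINGLE_PEAK shape persists over the contiguity distance;
    4. otherwise AFD with a low-confidence flag (the most pathological
       appearance, whose detection branch is the most generally
       applicable).

    Returns the class and a diagnostics dict (per-B-scan shapes, the
    triggering rule, low-confidence flag).
    """
    if not ilm.valid.any():
        raise UnclassifiableError("ILM surface entirely invalid")
    region = ilm.valid if mask is None else (ilm.valid & mask)
    ys = np.nonzero(region.any(axis=0))[0]
    analyses = [analyze_bscan_profile(ilm, int(y), cfg) for y in ys]
    shapes = [a.shape for a in analyses]
    diag: dict = {
        "bscan_shapes": {int(y): a.shape.value for y, a in zip(ys, analyses)},
        "low_confidence": False,
    }

    if thickness is not None and thickness.valid.any():
        tol = cfg.thickness_tol(geom)
        zero_pts = thickness.valid & (thickness.t_um <= tol)
        if mask is not None:
            zero_pts &= mask
        if zero_pts.any() and confirm_contiguity(shapes, ProfileShape.DEPRESSION,
                                                 geom, cfg):
            diag["rule"] = "nfd-zero-rnfl-thickness"
            return Appearance.NFD, diag

    if confirm_contiguity(shapes, ProfileShape.TWO_PEAK, geom, cfg):
        diag["rule"] = "mfd-two-peak"
        return Appearance.MFD, diag
    if confirm_contiguity(shapes, ProfileShape.SINGLE_PEAK, geom, cfg):
        diag["rule"] = "afd-single-peak"
        return Appearance.AFD, diag
    diag["rule"] = "fallback-no-contiguous-shape"
    diag["low_confidence"] = True
    return Appearance.AFD, diag
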