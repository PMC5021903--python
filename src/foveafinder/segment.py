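"""Segmentation: kernel graph-cut tissue/background labelling, inner
limiting membrane (ILM) delineation, two-surface (ILM + RNFL-bottom)
search for near-normal volumes, intraretinal-fluid (IRF) region
extraction, and layer thickness maps.

The kernel graph cut labels each B-scan by minimising::

    E(l) = sum_p (1 - K(I_p, mu_{l_p}))  +  lambda * sum_{(p,q)} [l_p != l_q]

where ``K`` is a radial-basis kernel on intensity with bandwidth set from
the B-scan's median absolute deviation, ``mu_l`` are per-region
representatives in the kernel-induced feature space, and the pairwise term
penalises boundary length on the 4-connected pixel grid.  For two regions
the minimisation is solved exactly by a single min-cut; representatives
and cut are alternated until the labelling stabilises.

The two-surface search replaces a full multi-surface graph search with a
per-column dynamic program: each surface minimises a gradient-based cost
subject to a hard smoothness bound of ``s_max`` voxels between adjacent
columns, and the lower surface is constrained to lie below the upper one.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage.filters import threshold_otsu

from .core import OCTVolume, Stage, VendorGeometry

__all__ = [
    "SurfaceKind",
    "SurfaceMap",
    "IRFRegion",
    "ThicknessMap",
    "kernel_graphcut_segment",
    "graphcut_energy",
    "delineate_ilm",
    "segment_layers_nfd",
    "extract_irf_regions",
    "thickness_between",
]

log = logging.getLogger(__name__)

_CAP_SCALE = 10_000  # float -> integer capacity scaling for min-cut


class SurfaceKind(enum.Enum):
    ILM = "ILM"
    RNFL_BOTTOM = "RNFL_BOTTOM"


@dataclass
class SurfaceMap:
    """Per-(x, y) axial elevation of one retinal surface.

    ``z_um[x, y]`` is the surface depth in micrometres from the top of the
    scan; ``valid`` is False where delineation failed or the column lies
    outside the foveal mask.
    """

    z_um: np.ndarray
    valid: np.ndarray
    kind: SurfaceKind
    geometry: VendorGeometry

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z_um.shape != self.valid.shape:
            raise ValueError("z_um and valid must share a shape")
        zv = self.z_um[self.valid]
        if zv.size and (zv.min() < 0 or zv.max() > self.geometry.extent_z_um):
            raise ValueError("surface depth outside the axial extent")

    @property
    def z_vox(self) -> np.ndarray:
        """Surface position as (fractional) voxel indices along z."""
        return self.z_um / self.geometry.dz_um - 0.5

    def elevation_um(self) -> np.ndarray:
        """Elevation E = extent_z - z: larger where the retina bulges
        toward the vitreous."""
        return self.geometry.extent_z_um - self.z_um

    def points_um(self) -> np.ndarray:
        """Valid surface points as an (N, 3) array of (x, y, z) in um."""
        xs, ys = np.nonzero(self.valid)
        g = self.geometry
        return np.column_stack([
            (xs + 0.5) * g.dx_um,
            (ys + 0.5) * g.dy_um,
            self.z_um[xs, ys],
        ])


@dataclass
class IRFRegion:
    """A labelled hyporeflective (fluid) region inside the retina."""

    label_id: int
    boundary_points_um: np.ndarray  # (N, 3) physical coordinates
    volume_vox: int
    mean_intensity: float
    centroid_vox: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.boundary_points_um = np.asarray(self.boundary_points_um, dtype=float)
        if self.boundary_points_um.size == 0:
            raise ValueError("IRF region must have boundary points")


@dataclass
class ThicknessMap:
    """Per-(x, y) layer thickness in micrometres."""

    t_um: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_um = np.asarray(self.t_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        tv = self.t_um[self.valid]
        if tv.size and tv.min() < -1e-9:
            raise ValueError("negative thickness: surfaces cross")


# ---------------------------------------------------------------------------
# Kernel graph cut


def _rbf(x: np.ndarray, mu: float, h: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * h * h))


def _bandwidth(img: np.ndarray) -> float:
    mad = np.median(np.abs(img - np.median(img)))
    return max(1.4826 * float(mad), 0.02)


def _update_representative(vals: np.ndarray, mu: float, h: float,
                           n_iter: int = 3) -> float:
    """Fixed-point update of a region representative under the RBF kernel
    (kernel-weighted mean of the member intensities)."""
    for _ in range(n_iter):
        w = _rbf(vals, mu, h)
        s = w.sum()
        if s <= 1e-12:
            return float(vals.mean())
        mu = float((w * vals).sum() / s)
    return mu


def _data_term(img: np.ndarray, mus: tuple[float, float], h: float) -> np.ndarray:
    """Per-pixel cost of each label: distance to the region representative
    in the kernel-induced feature space, shape (2, *img.shape)."""
    return np.stack([1.0 - _rbf(img, mus[0], h), 1.0 - _rbf(img, mus[1], h)])


def _min_cut_labels(d0: np.ndarray, d1: np.ndarray, lam: float) -> np.ndarray:
    """Exact binary labelling minimising data + Potts boundary cost on the
    4-connected grid, via integer max-flow/min-cut.

    Label 0 is charged ``d0``, label 1 is charged ``d1``; each unlike
    neighbour pair is charged ``lam``.
    """
    h, w = d0.shape
    n = h * w
    src, snk = n, n + 1
    idx = np.arange(n).reshape(h, w)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    caps: list[np.ndarray] = []

    # t-links: cap(s->p) = D_p(1), cap(p->t) = D_p(0)
    rows.append(np.full(n, src)); cols.append(idx.ravel()); caps.append(d1.ravel())
    rows.append(idx.ravel()); cols.append(np.full(n, snk)); caps.append(d0.ravel())

    # n-links (both directions)
    if lam > 0:
        right_a, right_b = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        down_a, down_b = idx[:-1, :].ravel(), idx[1:, :].ravel()
        for a, b in ((right_a, right_b), (down_a, down_b)):
            lamv = np.full(a.size, lam)
            rows.extend([a, b]); cols.extend([b, a]); caps.extend([lamv, lamv])

    cap = np.rint(np.concatenate(caps) * _CAP_SCALE).astype(np.int64)
    graph = sparse.csr_matrix(
        (cap, (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
    )
    # symmetrise the sparsity pattern so every arc has a residual slot
    graph = graph + graph.T.multiply(0)
    graph = sparse.csr_matrix(graph)
    graph.data = graph.data.astype(np.int64)

    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = np.where(residual.data > 0, residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, src, directed=True,
                                return_predecessors=False)
    labels = np.ones(n, dtype=np.int8)  # sink side -> label 1
    reach_px = reach[(reach >= 0) & (reach < n)]
    labels[reach_px] = 0
    return labels.reshape(h, w)


def graphcut_energy(img: np.ndarray, labels: np.ndarray,
                    mus: tuple[float, float], h: float,
                    smoothness: float) -> float:
    """Evaluate the kernel graph-cut energy of an arbitrary labelling.

    Used both internally and as the explicit evaluator for oracle tests.
    """
    d = _data_term(img, mus, h)
    data = float(np.where(labels == 0, d[0], d[1]).sum())
    pair = float((labels[:, :-1] != labels[:, 1:]).sum()
                 + (labels[:-1, :] != labels[1:, :]).sum())
    return data + smoothness * pair


def kernel_graphcut_segment(bscan: np.ndarray, n_regions: int = 2,
                            smoothness: float = 0.15, max_iter: int = 10,
                            return_info: bool = False):
    """Two-region kernel graph-cut segmentation of a B-scan.

    Parameters
    ----------
    bscan
        2D intensity grid in [0, 1] (any axis order; labels match input).
    n_regions
        Number of regions; only 2 is supported.
    smoothness
        Potts boundary weight ``lambda``.  Smaller values relax the
        smoothing constraint and follow fine surface detail more closely.
    return_info
        If True also return a dict with the region representatives,
        kernel bandwidth, final energy and a ``degenerate`` flag.

    Returns
    -------
    labels : 2D int array, 1 = bright/tissue region, 0 = background.
    """
    if n_regions != 2:
        raise ValueError("only two-region segmentation is supported")
    img = np.asarray(bscan, dtype=float)
    if img.ndim != 2:
        raise ValueError("bscan must be 2D")
    if img.min() < 0 or img.max() > 1 + 1e-6:
        raise ValueError("bscan intensities must lie in [0, 1]")

    info: dict = {"degenerate": False, "iterations": 0}
    if float(img.max()) - float(img.min()) < 1e-6:
        log.warning("uniform B-scan: single-region result")
        info["degenerate"] = True
        labels = np.zeros(img.shape, dtype=np.int8)
        info.update(mus=(float(img.mean()), float(img.mean())),
                    bandwidth=_bandwidth(img), energy=0.0)
        return (labels, info) if return_info else labels

    h = _bandwidth(img)
    try:
        thr = threshold_otsu(img)
    except ValueError:
        thr = float(img.mean())
    lo, hi = img[img <= thr], img[img > thr]
    mu0 = float(lo.mean()) if lo.size else float(img.min())
    mu1 = float(hi.mean()) if hi.size else float(img.max())

    labels = (img > thr).astype(np.int8)
    for it in range(max_iter):
        d = _data_term(img, (mu0, mu1), h)
        new = _min_cut_labels(d[0], d[1], smoothness)
        # keep label 1 the brighter region
        m0 = img[new == 0].mean() if (new == 0).any() else -np.inf
        m1 = img[new == 1].mean() if (new == 1).any() else np.inf
        if m0 > m1:
            new = 1 - new
        info["iterations"] = it + 1
        changed = int((new != labels).sum())
        labels = new
        if (labels == 0).all() or (labels == 1).all():
            info["degenerate"] = True
            break
        mu0 = _update_representative(img[labels == 0], mu0, h)
        mu1 = _update_representative(img[labels == 1], mu1, h)
        if changed == 0:
            break

    info.update(mus=(mu0, mu1), bandwidth=h,
                energy=graphcut_energy(img, labels, (mu0, mu1), h, smoothness))
    return (labels, info) if return_info else labels


# ---------------------------------------------------------------------------
# ILM delineation


def _first_tissue_per_column(labels: np.ndarray, min_component_px: int = 30
                             ) -> np.ndarray:
    """First tissue z index per column (labels indexed (x, z)); NaN where
    the column holds no tissue.  Small isolated tissue specks are removed
    first so floaters above the retina cannot masquerade as the surface."""
    tissue = labels.astype(bool)
    if min_component_px > 1:
        lab, nlab = ndimage.label(tissue)
        if nlab > 1:
            sizes = np.bincount(lab.ravel())
            small = sizes < min_component_px
            small[0] = False
            tissue[small[lab]] = False
    has = tissue.any(axis=1)
    first = np.argmax(tissue, axis=1).astype(float)
    first[~has] = np.nan
    return first


def _fill_single_gaps(z: np.ndarray) -> np.ndarray:
    """Linearly interpolate isolated single-column NaN gaps."""
    out = z.copy()
    for x in range(1, len(z) - 1):
        if np.isnan(out[x]) and np.isfinite(out[x - 1]) and np.isfinite(out[x + 1]):
            out[x] = 0.5 * (out[x - 1] + out[x + 1])
    return out


def delineate_ilm(vol: OCTVolume, smoothness: float = 0.15,
                  min_component_px: int = 30) -> SurfaceMap:
    """Delineate the inner limiting membrane of every B-scan.

    Each B-scan is segmented with the kernel graph cut (relaxed
    smoothness so the surface boundary stays sharp); per column the
    smallest tissue-labelled z is taken as the ILM, single-column gaps are
    interpolated, and columns with no tissue are marked invalid.
    """
    vol.require_stage(Stage.DENOISED, Stage.MASKED, Stage.SEGMENTED)
    g = vol.geometry
    z_um = np.full((g.nx, g.ny), np.nan)
    valid = np.zeros((g.nx, g.ny), dtype=bool)
    for y in range(g.ny):
        bscan = vol.voxels[:, y, :]
        active = np.nonzero(bscan.max(axis=1) > 0)[0]
        if active.size < 3:
            continue
        x0, x1 = active[0], active[-1] + 1
        crop = bscan[x0:x1]
        labels = kernel_graphcut_segment(crop, smoothness=smoothness)
        first = _first_tissue_per_column(labels, min_component_px)
        first = _fill_single_gaps(first)
        good = np.isfinite(first)
        cols = np.arange(x0, x1)[good]
        z_um[cols, y] = (first[good] + 0.5) * g.dz_um
        valid[cols, y] = True
    if vol.mask is not None:
        valid &= vol.mask
    z_um[~valid] = np.nan
    if not valid.any():
        log.warning("ILM delineation found no tissue anywhere")
    return SurfaceMap(z_um=np.where(valid, z_um, 0.0), valid=valid,
                      kind=SurfaceKind.ILM, geometry=g)


# ---------------------------------------------------------------------------
# Dynamic-programming surface search (two-surface, near-normal volumes)


def dp_surface(cost: np.ndarray, s_max: int = 2,
               feasible: np.ndarray | None = None) -> np.ndarray | None:
    """Minimal-cost single-valued surface through a (x, z) cost grid.

    Finds ``z(x)`` minimising ``sum_x cost[x, z(x)]`` subject to
    ``|z(x) - z(x-1)| <= s_max``.  ``feasible`` (boolean, same shape)
    restricts the allowed states.  Returns the z index per column, or
    None when no feasible path exists.
    """
    nx, nz = cost.shape
    big = np.inf
    c = np.where(feasible, cost, big) if feasible is not None else cost.astype(float)
    acc = np.empty_like(c)
    acc[0] = c[0]
    # no predecessor bookkeeping: backtrack by re-evaluating transitions
    for x in range(1, nx):
        prev_min = ndimage.minimum_filter1d(acc[x - 1], size=2 * s_max + 1,
                                            mode="constant", cval=big)
        acc[x] = c[x] + prev_min
    if not np.isfinite(acc[-1]).any():
        return None
    z = np.empty(nx, dtype=int)
    z[-1] = int(np.argmin(acc[-1]))
    for x in range(nx - 2, -1, -1):
        lo = max(0, z[x + 1] - s_max)
        hi = min(nz, z[x + 1] + s_max + 1)
        z[x] = lo + int(np.argmin(acc[x, lo:hi]))
    return z


def dp_surface_cost(cost: np.ndarray, z: np.ndarray) -> float:
    """Total cost of a candidate surface (for oracle comparisons)."""
    return float(cost[np.arange(len(z)), z].sum())


def _axial_gradient(bscan: np.ndarray) -> np.ndarray:
    """Central-difference intensity gradient along z, indexed (x, z)."""
    return np.gradient(bscan.astype(float), axis=1)


def _box_derivative(img: np.ndarray, w: int) -> np.ndarray:
    """Box-filtered axial derivative per column:
    ``D(z) = mean(I[z:z+w]) - mean(I[z-w:z])`` with edge replication.

    Averaging ``w`` voxels on each side makes the edge response robust to
    residual speckle while keeping its minimum centred on the edge.
    """
    nx_, nz = img.shape
    ext = np.concatenate([np.repeat(img[:, :1], w, axis=1), img,
                          np.repeat(img[:, -1:], w, axis=1)], axis=1)
    s = np.concatenate([np.zeros((nx_, 1)), np.cumsum(ext, axis=1)], axis=1)
    z = np.arange(nz) + w
    return (s[:, z + w] - s[:, z]) / w - (s[:, z] - s[:, z - w]) / w


def segment_layers_nfd(vol: OCTVolume, s_max: int = 2,
                       max_rnfl_um: float = 160.0,
                       hug_bias: float = 2e-3,
                       edge_window_vox: int = 8,
                       lateral_sigma: float = 2.0
                       ) -> tuple[SurfaceMap, SurfaceMap]:
    """Delineate the ILM and the RNFL posterior boundary of a near-normal
    volume by per-column dynamic programming.

    Each B-scan is lightly smoothed laterally (``lateral_sigma`` columns).
    The ILM minimises a dark-to-bright gradient cost.  The RNFL bottom
    minimises a box-filtered bright-to-dark derivative (window
    ``edge_window_vox`` voxels each side, with the region above the ILM
    padded by the ILM intensity so the vitreous cannot contaminate the
    window) inside a corridor from the ILM down to ``max_rnfl_um``, and
    additionally guarded away from the posterior bright band (RPE proxy:
    last bright voxel per column) whose much stronger edge would
    otherwise capture the search.  A small ``hug_bias`` per voxel of
    separation makes the surface collapse onto the ILM where no
    posterior edge exists — at the foveal pit, where the nerve fiber
    layer vanishes, so the thickness map correctly reaches zero.
    Surfaces never cross.
    """
    vol.require_stage(Stage.DENOISED, Stage.MASKED)
    g = vol.geometry
    max_rnfl_vox = max(2, int(round(max_rnfl_um / g.dz_um)))
    w = edge_window_vox
    shape = (g.nx, g.ny)
    z_ilm = np.zeros(shape)
    z_rnfl = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    for y in range(g.ny):
        bscan = vol.voxels[:, y, :]
        active = np.nonzero(bscan.max(axis=1) > 0)[0]
        if active.size < 3:
            continue
        x0, x1 = active[0], active[-1] + 1
        crop = bscan[x0:x1].astype(float)
        if lateral_sigma > 0 and crop.shape[0] > 4:
            crop = ndimage.gaussian_filter1d(crop, sigma=lateral_sigma, axis=0)
        grad = _axial_gradient(crop)

        ilm = dp_surface(-grad, s_max=s_max)
        if ilm is None:
            log.warning("no feasible ILM surface in B-scan %d", y)
            continue

        nz = crop.shape[1]
        zz = np.arange(nz)[None, :]
        padded = crop.copy()
        for xi in range(crop.shape[0]):
            padded[xi, :ilm[xi]] = crop[xi, ilm[xi]]
        d_box = _box_derivative(padded, w)

        try:
            thr = threshold_otsu(crop)
        except ValueError:
            thr = float(crop.mean())
        bright = crop > thr
        last_bright = nz - 1 - np.argmax(bright[:, ::-1], axis=1)
        guard = last_bright - (w + 2)
        hi = np.maximum(np.minimum(np.minimum(ilm + max_rnfl_vox, guard), nz - 1),
                        ilm)
        window = (zz >= ilm[:, None]) & (zz <= hi[:, None])
        rnfl_cost = np.minimum(d_box, 0.0) + hug_bias * (zz - ilm[:, None])
        rnfl = dp_surface(rnfl_cost, s_max=s_max, feasible=window)
        if rnfl is None:
            log.warning("no feasible RNFL-bottom surface in B-scan %d", y)
            continue
        rnfl = np.maximum(rnfl, ilm)  # ordering is already enforced; belt & braces

        cols = np.arange(x0, x1)
        z_ilm[cols, y] = (ilm + 0.5) * g.dz_um
        z_rnfl[cols, y] = (rnfl + 0.5) * g.dz_um
        valid[cols, y] = True

    if vol.mask is not None:
        valid &= vol.mask
    ilm_map = SurfaceMap(z_um=np.where(valid, z_ilm, 0.0), valid=valid,
                         kind=SurfaceKind.ILM, geometry=g)
    rnfl_map = SurfaceMap(z_um=np.where(valid, z_rnfl, 0.0), valid=valid.copy(),
                          kind=SurfaceKind.RNFL_BOTTOM, geometry=g)
    return ilm_map, rnfl_map


# ---------------------------------------------------------------------------
# IRF extraction


def extract_irf_regions(vol: OCTVolume, ilm: SurfaceMap,
                        min_volume_vox: int = 50) -> list[IRFRegion]:
    """Extract candidate intraretinal-fluid regions from a masked volume.

    The retina is bounded above by the ILM and below by the last bright
    voxel of each column (an RPE proxy).  Voxels inside this slab darker
    than the two-class intensity split are 6-connectivity labelled in 3D;
    components smaller than ``min_volume_vox`` are discarded and the rest
    are returned ordered by ascending mean intensity (darkest, most
    fluid-like, first).
    """
    vol.require_stage(Stage.MASKED, Stage.DENOISED)
    g = vol.geometry
    vox = vol.voxels
    nz = g.nz

    inside = ilm.valid
    if not inside.any():
        return []
    nonzero = vox[vox > 0]
    if nonzero.size < 16:
        return []
    try:
        bright_thr = threshold_otsu(nonzero)
    except ValueError:
        return []

    zz = np.arange(nz)
    ilm_vox = np.clip(np.rint(ilm.z_vox), 0, nz - 1).astype(int)
    bright = vox > bright_thr
    has_bright = bright.any(axis=2)
    last_bright = nz - 1 - np.argmax(bright[:, :, ::-1], axis=2)

    slab = (
        inside[:, :, None]
        & has_bright[:, :, None]
        & (zz[None, None, :] > ilm_vox[:, :, None])
        & (zz[None, None, :] < last_bright[:, :, None])
    )
    retina_vals = vox[slab]
    if retina_vals.size < 16 or float(retina_vals.max()) - float(retina_vals.min()) < 1e-6:
        return []
    try:
        dark_thr = threshold_otsu(retina_vals)
    except ValueError:
        return []
    tissue_mean = float(retina_vals[retina_vals > dark_thr].mean()) \
        if (retina_vals > dark_thr).any() else float(retina_vals.mean())

    dark = slab & (vox < dark_thr)
    labels, nlab = ndimage.label(dark)  # default structure = 6-connectivity
    if nlab == 0:
        return []

    regions: list[IRFRegion] = []
    struct = ndimage.generate_binary_structure(3, 1)
    objects = ndimage.find_objects(labels)
    for lab_id in range(1, nlab + 1):
        sl = objects[lab_id - 1]
        comp = labels[sl] == lab_id
        n_vox = int(comp.sum())
        if n_vox < min_volume_vox:
            continue
        mean_int = float(vox[sl][comp].mean())
        # fluid is hyporeflective: well below the tissue mean, not merely on
        # the darker side of the two-class split (which would also admit
        # ordinary inner-retina tissue lying below a bright fiber layer)
        if mean_int >= 0.5 * tissue_mean:
            continue
        interior = ndimage.binary_erosion(comp, structure=struct)
        bnd = comp & ~interior
        bx, by, bz = np.nonzero(bnd)
        bx = bx + sl[0].start
        by = by + sl[1].start
        bz = bz + sl[2].start
        pts = np.column_stack([
            (bx + 0.5) * g.dx_um,
            (by + 0.5) * g.dy_um,
            (bz + 0.5) * g.dz_um,
        ])
        cx, cy, cz = ndimage.center_of_mass(comp)
        regions.append(IRFRegion(
            label_id=lab_id,
            boundary_points_um=pts,
            volume_vox=n_vox,
            mean_intensity=mean_int,
            centroid_vox=(cx + sl[0].start, cy + sl[1].start, cz + sl[2].start),
        ))
    regions.sort(key=lambda r: r.mean_intensity)
    return regions


def thickness_between(upper: SurfaceMap, lower: SurfaceMap) -> ThicknessMap:
    """Thickness map ``z_lower - z_upper`` in um, valid where both inputs
    are.  Crossing surfaces signal an upstream failure and are rejected."""
    if upper.z_um.shape != lower.z_um.shape:
        raise ValueError("surfaces must share a grid")
    valid = upper.valid & lower.valid
    t = np.where(valid, lower.z_um - upper.z_um, 0.0)
    if valid.any() and float(t[valid].min()) < -1e-9:
        raise ValueError("surfaces cross: negative thickness")
    return ThicknessMap(t_um=t, valid=valid)
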