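"""Synthetic macular SD-OCT phantoms with planted ground truth.

Every pipeline stage is testable without clinical data: a phantom plants
a smooth ILM surface carrying one of the three foveal appearances, a
retinal nerve fiber layer whose thickness vanishes at a normal fovea,
hyporeflective intraretinal cyst ellipsoids, multiplicative speckle, and
per-B-scan axial jitter and tilt.  The planted fovea position, surfaces,
cyst masks and applied artefacts are returned as ground truth.

Appearance geometry:

* **NFD** — a difference-of-Gaussians pit dent of full depth (default
  diameter 1.5 mm, the mean fovea centralis diameter); no edema.
* **MFD** — a smaller, sharper residual pit at 40% depth, elevated by a
  flat-topped (super-Gaussian) edema dome fed by an underlying cyst.
* **AFD** — no pit at all: a dome over the cyst.

For MFD and AFD specs the cyst is placed directly beneath the planted
fovea with its surface curving away faster than the ILM, so the
geometric minimum ILM-to-cyst-boundary gap is attained at the planted
fovea by construction (verified by a brute-force oracle in the tests).

Intensity model (arbitrary units chosen for contrast realism, not
clinical claims): vitreous 0.05, retinal tissue 0.70, nerve fiber layer
0.85, cyst fluid 0.10, sub-RPE 0.20.  Speckle is multiplicative
gamma-distributed noise of unit mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Appearance, OCTVolume, Stage, VendorGeometry
from .segment import SurfaceKind, SurfaceMap

__all__ = [
    "INTENSITY",
    "REDUCED_GEOMETRY",
    "CystSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_spec",
    "generate_phantom",
    "generate_ensemble",
]

#: Rendering intensities (documented constants, not clinical claims).
INTENSITY = {
    "vitreous": 0.05,
    "retina": 0.70,
    "rnfl": 0.85,
    "cyst": 0.10,
    "sub_rpe": 0.20,
}

#: Down-sampled grid used for ensemble studies: same 6 x 6 x 2 mm field
#: as the clinical protocols at a quarter of the voxel budget.
REDUCED_GEOMETRY = VendorGeometry(name="reduced_128", nx=128, ny=49, nz=256)


@dataclass(frozen=True)
class CystSpec:
    """An ellipsoidal hyporeflective fluid pocket."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    intensity: float = INTENSITY["cyst"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic volume.

    All positions and lengths are physical micrometres.  ``seed`` makes
    the phantom fully deterministic.
    """

    geometry: VendorGeometry
    appearance: Appearance
    fovea_x_um: float
    fovea_y_um: float
    pit_depth_um: float = 150.0
    pit_radius_um: float = 750.0
    pit_attenuation: float = 0.4     # residual pit depth fraction in MFD
    dome_height_um: float = 250.0
    dome_sigma_um: float = 1000.0
    cysts: tuple[CystSpec, ...] = ()
    rnfl_max_um: float = 120.0
    rnfl_sigma_um: float = 500.0
    rnfl_floor_um: float = 40.0      # minimum RNFL thickness off the NFD case
    ilm_base_depth_um: float = 800.0
    retina_thickness_um: float = 340.0
    speckle_sigma: float = 0.0
    jitter_max_vox: int = 0
    tilt_slope: float = 0.0          # z voxels per x voxel, sheared into B-scans
    seed: int = 0

    def __post_init__(self) -> None:
        g = self.geometry
        cx, cy = g.extent_x_um / 2, g.extent_y_um / 2
        # planted fovea must lie inside the elliptical foveal mask
        # (semi-axes extent/4 about the scan centre)
        r2 = ((self.fovea_x_um - cx) / (g.extent_x_um / 4)) ** 2 \
            + ((self.fovea_y_um - cy) / (g.extent_y_um / 4)) ** 2
        if r2 > 1.0:
            raise ValueError("planted fovea lies outside the foveal mask")
        if self.appearance in (Appearance.MFD, Appearance.AFD) and not self.cysts:
            raise ValueError(f"{self.appearance.value} spec requires >= 1 cyst")
        if self.pit_depth_um >= self.retina_thickness_um:
            raise ValueError("pit depth must be smaller than the retinal thickness")


@dataclass
class PhantomTruth:
    """Planted ground truth of a generated phantom."""

    fovea_um: tuple[float, float, float]
    appearance: Appearance
    ilm_surface: SurfaceMap
    rnfl_surface: SurfaceMap
    cyst_masks: list[np.ndarray]
    applied_jitter_vox: np.ndarray
    applied_tilt_slope: float
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Surface models


def _pit_dent_um(r_um: np.ndarray, depth: float, radius: float) -> np.ndarray:
    """Difference-of-Gaussians pit dent (positive values push the surface
    deeper).  The centre value equals ``depth`` and a slight rim forms
    where the wider negative lobe dominates."""
    sigma = radius / 2.0
    return depth * (1.2 * np.exp(-r_um**2 / (2 * sigma**2))
                    - 0.2 * np.exp(-r_um**2 / (8 * sigma**2)))


def _surfaces(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted ILM depth, RNFL thickness and RPE depth grids (nx, ny) um."""
    g = spec.geometry
    x = (np.arange(g.nx) + 0.5) * g.dx_um
    y = (np.arange(g.ny) + 0.5) * g.dy_um
    r = np.sqrt((x[:, None] - spec.fovea_x_um) ** 2
                + (y[None, :] - spec.fovea_y_um) ** 2)

    # the edema dome is a flat-topped super-Gaussian: cystoid edema lifts a
    # broad plateau of retina, so a residual depression (MFD) survives on
    # top of it instead of being cancelled by the dome's own curvature
    dent = np.zeros_like(r)
    dome = np.zeros_like(r)
    if spec.appearance is Appearance.NFD:
        dent = _pit_dent_um(r, spec.pit_depth_um, spec.pit_radius_um)
    elif spec.appearance is Appearance.MFD:
        dent = _pit_dent_um(r, spec.pit_attenuation * spec.pit_depth_um,
                            spec.pit_radius_um)
        dome = spec.dome_height_um * np.exp(-(r / spec.dome_sigma_um) ** 4 / 2)
    else:  # AFD: no residual depression, dome only
        dome = spec.dome_height_um * np.exp(-(r / spec.dome_sigma_um) ** 4 / 2)

    z_ilm = spec.ilm_base_depth_um + dent - dome
    rnfl = spec.rnfl_max_um * (1.0 - np.exp(-r**2 / (2 * spec.rnfl_sigma_um**2)))
    if spec.appearance is not Appearance.NFD:
        rnfl = np.maximum(rnfl, spec.rnfl_floor_um)
    z_rpe = np.full_like(z_ilm, spec.ilm_base_depth_um + spec.retina_thickness_um)
    return z_ilm, rnfl, z_rpe


# ---------------------------------------------------------------------------
# Generation


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Render a phantom volume and its ground truth.

    The clean volume is rendered from the planted surfaces and cysts,
    multiplicative speckle is applied, then per-B-scan tilt shear and
    axial jitter.  Fully deterministic given ``spec.seed``.  A cyst that
    would pierce the ILM surface rejects the spec.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    z_ilm, rnfl_t, z_rpe = _surfaces(spec)

    zc = (np.arange(g.nz) + 0.5) * g.dz_um  # voxel-centre depths
    Z = zc[None, None, :]
    ilm3 = z_ilm[:, :, None]
    rpe3 = z_rpe[:, :, None]

    vox = np.full(g.shape, INTENSITY["vitreous"], dtype=np.float32)
    in_retina = (Z >= ilm3) & (Z < rpe3)
    vox[in_retina] = INTENSITY["retina"]
    in_rnfl = (Z >= ilm3) & (Z < ilm3 + rnfl_t[:, :, None])
    vox[in_rnfl] = INTENSITY["rnfl"]
    vox[Z >= rpe3] = INTENSITY["sub_rpe"]

    x_um = (np.arange(g.nx) + 0.5) * g.dx_um
    y_um = (np.arange(g.ny) + 0.5) * g.dy_um
    cyst_masks: list[np.ndarray] = []
    for cyst in spec.cysts:
        cx, cy, cz = cyst.center_um
        ax, ay, az = cyst.semi_axes_um
        ell = (((x_um[:, None, None] - cx) / ax) ** 2
               + ((y_um[None, :, None] - cy) / ay) ** 2
               + ((Z - cz) / az) ** 2) <= 1.0
        if np.any(ell & (Z <= ilm3 + g.dz_um)):
            raise ValueError("cyst overlaps or pierces the ILM surface")
        ell &= in_retina
        vox[ell] = cyst.intensity
        cyst_masks.append(ell)

    if spec.speckle_sigma > 0:
        k = 1.0 / (spec.speckle_sigma ** 2)
        vox *= rng.gamma(shape=k, scale=1.0 / k, size=g.shape).astype(np.float32)
        np.clip(vox, 0.0, 1.0, out=vox)

    if abs(spec.tilt_slope) > 0:
        shift = np.rint(spec.tilt_slope
                        * (np.arange(g.nx) - (g.nx - 1) / 2.0)).astype(int)
        for xi in range(g.nx):
            s = shift[xi]
            if s:
                vox[xi] = _roll_plane(vox[xi], s)

    jitter = np.zeros(g.ny, dtype=int)
    if spec.jitter_max_vox > 0:
        jitter = rng.integers(-spec.jitter_max_vox, spec.jitter_max_vox + 1,
                              size=g.ny)
        jitter -= int(np.median(jitter))
        np.clip(jitter, -spec.jitter_max_vox, spec.jitter_max_vox, out=jitter)
        for yi in range(g.ny):
            if jitter[yi]:
                vox[:, yi, :] = _roll_plane(vox[:, yi, :], int(jitter[yi]))

    valid = np.ones((g.nx, g.ny), dtype=bool)
    ilm_map = SurfaceMap(z_um=z_ilm, valid=valid, kind=SurfaceKind.ILM, geometry=g)
    rnfl_map = SurfaceMap(z_um=z_ilm + rnfl_t, valid=valid.copy(),
                          kind=SurfaceKind.RNFL_BOTTOM, geometry=g)
    fx, fy = spec.fovea_x_um, spec.fovea_y_um
    ix = int(np.clip(round(fx / g.dx_um - 0.5), 0, g.nx - 1))
    iy = int(np.clip(round(fy / g.dy_um - 0.5), 0, g.ny - 1))
    truth = PhantomTruth(
        fovea_um=(fx, fy, float(z_ilm[ix, iy])),
        appearance=spec.appearance,
        ilm_surface=ilm_map,
        rnfl_surface=rnfl_map,
        cyst_masks=cyst_masks,
        applied_jitter_vox=jitter,
        applied_tilt_slope=spec.tilt_slope,
        spec=spec,
    )
    vol = OCTVolume(voxels=vox, geometry=g, stage=Stage.RAW)
    return vol, truth


def _roll_plane(plane: np.ndarray, shift: int) -> np.ndarray:
    """Shift a 2D (first-axis x last-axis z) plane along z, zero fill."""
    out = np.zeros_like(plane)
    if shift > 0:
        out[..., shift:] = plane[..., : plane.shape[-1] - shift]
    elif shift < 0:
        out[..., :shift] = plane[..., -shift:]
    else:
        out[...] = plane
    return out


# ---------------------------------------------------------------------------
# Spec construction


NOISE_LEVELS = {
    "none": {"speckle_sigma": 0.0, "jitter_max_vox": 0, "tilt": 0.0},
    "default": {"speckle_sigma": 0.5, "jitter_max_vox": 8, "tilt": 0.03},
}


def make_spec(appearance: Appearance,
              geometry: VendorGeometry = REDUCED_GEOMETRY,
              seed: int = 0,
              noise_level: str = "none",
              rng: Optional[np.random.Generator] = None) -> PhantomSpec:
    """Build a randomized but seeded spec of the requested appearance.

    Pit, dome, cyst and fovea-offset parameters are drawn from documented
    ranges around their defaults; the planted fovea is jittered by up to
    ~500 um from the scan centre.  ``noise_level`` is "none" (clean) or
    "default" (speckle sigma 0.5, axial jitter up to 8 voxels, tilt up to
    +/-0.03 z-voxels per x-voxel).
    """
    if noise_level not in NOISE_LEVELS:
        raise ValueError(f"unknown noise level {noise_level!r}")
    nl = NOISE_LEVELS[noise_level]
    if rng is None:
        rng = np.random.default_rng(seed)
    g = geometry
    cx, cy = g.extent_x_um / 2, g.extent_y_um / 2
    theta = rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0, 500.0)
    fx = cx + rad * np.cos(theta)
    fy = cy + rad * np.sin(theta)

    pit_depth = rng.uniform(120.0, 180.0)
    # the MFD residual depression is smaller and sharper than a normal
    # pit, so it survives on top of the edema plateau
    pit_radius = rng.uniform(350.0, 500.0) if appearance is Appearance.MFD \
        else rng.uniform(650.0, 850.0)
    # the dome is kept broad relative to the cyst so the cyst surface
    # curves away from the ILM faster than the dome does: the minimum
    # ILM-cyst gap then sits at the planted fovea with a sharp margin
    dome_height = rng.uniform(220.0, 280.0)
    dome_sigma = rng.uniform(1100.0, 1300.0)
    rnfl_max = rng.uniform(100.0, 140.0)
    tilt = rng.uniform(-nl["tilt"], nl["tilt"]) if nl["tilt"] > 0 else 0.0

    base_depth = 800.0
    cysts: tuple[CystSpec, ...] = ()
    if appearance in (Appearance.MFD, Appearance.AFD):
        gap = rng.uniform(50.0, 80.0)
        if appearance is Appearance.MFD:
            semi = (rng.uniform(800.0, 1000.0), rng.uniform(800.0, 1000.0),
                    rng.uniform(130.0, 170.0))
            dent_centre = 0.4 * pit_depth
        else:
            semi = (rng.uniform(420.0, 520.0), rng.uniform(420.0, 520.0),
                    rng.uniform(150.0, 180.0))
            dent_centre = 0.0
        z_ilm_f = base_depth + dent_centre - dome_height
        cz = z_ilm_f + gap + semi[2]
        cysts = (CystSpec(center_um=(fx, fy, cz), semi_axes_um=semi),)

    return PhantomSpec(
        geometry=g, appearance=appearance,
        fovea_x_um=float(fx), fovea_y_um=float(fy),
        pit_depth_um=pit_depth, pit_radius_um=pit_radius,
        dome_height_um=dome_height, dome_sigma_um=dome_sigma,
        cysts=cysts, rnfl_max_um=rnfl_max,
        ilm_base_depth_um=base_depth,
        speckle_sigma=nl["speckle_sigma"],
        jitter_max_vox=nl["jitter_max_vox"],
        tilt_slope=float(tilt),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_ensemble(n_per_class: int,
                      geometry: VendorGeometry = REDUCED_GEOMETRY,
                      noise_level: str = "none",
                      base_seed: int = 0
                      ) -> list[tuple[OCTVolume, PhantomTruth]]:
    """Generate a class-stratified phantom ensemble.

    Returns ``3 * n_per_class`` phantoms, ``n_per_class`` of each
    appearance, with seeded randomized parameters; two ensembles built
    from the same ``base_seed`` are identical.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out = []
    for i in range(n_per_class):
        for j, app in enumerate((Appearance.NFD, Appearance.MFD, Appearance.AFD)):
            ss = np.random.SeedSequence([base_seed, i, j])
            rng = np.random.default_rng(ss)
            spec = make_spec(app, geometry=geometry, noise_level=noise_level,
                             rng=rng)
            out.append(generate_phantom(spec))
    return out
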