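from dataclasses import replace
from itertools import product

import numpy as np
import pytest

from foveafinder.core import Appearance, OCTVolume, Stage, VendorGeometry
from foveafinder.segment import (SurfaceKind, SurfaceMap, _data_term,
                                 _min_cut_labels, delineate_ilm, dp_surface,
                                 dp_surface_cost, extract_irf_regions,
                                 graphcut_energy, kernel_graphcut_segment,
                                 segment_layers_nfd, thickness_between)
from foveafinder.synthetic import CystSpec, generate_phantom, make_spec


def _two_band_bscan(nx=48, nz=96, z0=30, z1=60, lo=0.05, hi=0.7):
    img = np.full((nx, nz), lo)
    img[:, z0:z1] = hi
    return img


class TestKernelGraphCut:
    def test_clean_two_band_exact(self):
        img = _two_band_bscan()
        labels = kernel_graphcut_segment(img)
        np.testing.assert_array_equal(labels, (img > 0.3).astype(labels.dtype))

    def test_speckled_two_band_agreement(self):
        rng = np.random.default_rng(7)
        img = _two_band_bscan()
        noisy = np.clip(img * rng.gamma(4.0, 0.25, img.shape), 0, 1)
        labels = kernel_graphcut_segment(noisy)
        truth = (img > 0.3).astype(labels.dtype)
        assert (labels == truth).mean() >= 0.99

    def test_result_energy_not_above_generating_labels(self):
        rng = np.random.default_rng(3)
        img = _two_band_bscan(nx=24, nz=48)
        noisy = np.clip(img * rng.gamma(6.0, 1 / 6.0, img.shape), 0, 1)
        labels, info = kernel_graphcut_segment(noisy, return_info=True)
        truth = (img > 0.3).astype(labels.dtype)
        e_truth = graphcut_energy(noisy, truth, info["mus"], info["bandwidth"],
                                  0.15)
        assert info["energy"] <= e_truth + 1e-9

    def test_min_cut_is_exhaustive_optimum(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            h, w = rng.integers(2, 4, 2)
            img = rng.random((h, w))
            mus = (float(rng.random()), float(rng.random()))
            lam = float(rng.random() * 0.3)
            d = _data_term(img, mus, 0.2)
            labels = _min_cut_labels(d[0], d[1], lam)
            e = graphcut_energy(img, labels, mus, 0.2, lam)
            best = min(
                graphcut_energy(img, np.array(c).reshape(h, w), mus, 0.2, lam)
                for c in product([0, 1], repeat=h * w))
            assert e <= best + 1e-3  # capacity quantisation slack

    def test_uniform_image_flagged_degenerate(self):
        labels, info = kernel_graphcut_segment(np.full((8, 8), 0.5),
                                               return_info=True)
        assert info["degenerate"]
        assert len(np.unique(labels)) == 1

    def test_only_two_regions_supported(self):
        with pytest.raises(ValueError):
            kernel_graphcut_segment(np.zeros((4, 4)), n_regions=3)


class TestDPSurface:
    @staticmethod
    def _brute_force(cost, s_max):
        nx, nz = cost.shape
        best = None
        for path in product(range(nz), repeat=nx):
            if any(abs(path[i + 1] - path[i]) > s_max for i in range(nx - 1)):
                continue
            c = sum(cost[i, z] for i, z in enumerate(path))
            if best is None or c < best:
                best = c
        return best

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cost = rng.normal(size=(6, 6))
            for s_max in (1, 2):
                z = dp_surface(cost, s_max=s_max)
                assert dp_surface_cost(cost, z) == pytest.approx(
                    self._brute_force(cost, s_max))

    def test_smoothness_bound_respected(self):
        rng = np.random.default_rng(6)
        cost = rng.normal(size=(20, 15))
        z = dp_surface(cost, s_max=2)
        assert np.abs(np.diff(z)).max() <= 2

    def test_infeasible_returns_none(self):
        cost = np.zeros((3, 5))
        feasible = np.zeros((3, 5), dtype=bool)
        feasible[0, 0] = feasible[1, 4] = feasible[2, 0] = True
        assert dp_surface(cost, s_max=1, feasible=feasible) is None


class TestDelineateILM:
    def test_clean_phantom_surface_within_one_voxel(self, preprocessed):
        data = preprocessed[Appearance.NFD]
        ilm = delineate_ilm(data["masked"])
        truth = data["truth"].ilm_surface
        dz = data["masked"].geometry.dz_um
        err = np.abs(ilm.z_um - truth.z_um)[ilm.valid]
        assert (err <= dz).mean() >= 0.99

    def test_valid_only_inside_mask(self, preprocessed):
        data = preprocessed[Appearance.NFD]
        ilm = delineate_ilm(data["masked"])
        assert not ilm.valid[~data["mask"].grid].any()

    def test_speckled_mfd_preserves_both_peaks(self):
        spec = make_spec(Appearance.MFD, seed=9, noise_level="default")
        vol, truth = generate_phantom(replace(spec, jitter_max_vox=0,
                                              tilt_slope=0.0))
        from foveafinder.preprocess import (apply_mask, build_fovea_mask,
                                            correct_axial_motion,
                                            denoise_speckle)
        corrected, _ = correct_axial_motion(vol)
        masked = apply_mask(denoise_speckle(corrected),
                            build_fovea_mask(vol.geometry))
        ilm = delineate_ilm(masked)
        g = vol.geometry
        iy = int(truth.fovea_um[1] / g.dy_um)
        cols = np.nonzero(ilm.valid[:, iy])[0]
        elev = ilm.elevation_um()[cols, iy]
        x_um = (cols + 0.5) * g.dx_um
        centre = np.abs(x_um - truth.fovea_um[0]) < 200
        flank = (np.abs(x_um - truth.fovea_um[0]) > 350) & \
                (np.abs(x_um - truth.fovea_um[0]) < 900)
        assert elev[flank].max() > elev[centre].min() + 20

    def test_intensity_scale_invariance(self, preprocessed):
        data = preprocessed[Appearance.NFD]
        masked = data["masked"]
        ref = delineate_ilm(masked)
        dz = masked.geometry.dz_um
        for c in (0.5, 1.4):
            scaled = OCTVolume(np.clip(masked.voxels * c, 0, 1),
                               masked.geometry, Stage.MASKED, masked.mask)
            ilm = delineate_ilm(scaled)
            both = ref.valid & ilm.valid
            rms = np.sqrt(np.mean((ilm.z_um - ref.z_um)[both] ** 2)) / dz
            assert rms <= 1.0


class TestLayerSegmentation:
    def test_clean_nfd_surfaces_recovered(self, preprocessed):
        data = preprocessed[Appearance.NFD]
        masked = data["masked"]
        truth = data["truth"]
        g = masked.geometry
        ilm, rnfl = segment_layers_nfd(masked)
        assert ilm.valid.any()
        ilm_rms = np.sqrt(np.mean(
            ((ilm.z_um - truth.ilm_surface.z_um)[ilm.valid] / g.dz_um) ** 2))
        assert ilm_rms <= 1.0
        # the box-window cost resolves the posterior edge where the layer is
        # thicker than the window; assert recovery there
        t_true = truth.rnfl_surface.z_um - truth.ilm_surface.z_um
        thick = rnfl.valid & (t_true >= 70.0)
        rnfl_rms = np.sqrt(np.mean(
            ((rnfl.z_um - truth.rnfl_surface.z_um)[thick] / g.dz_um) ** 2))
        assert rnfl_rms <= 1.0

    def test_surfaces_never_cross(self, preprocessed):
        for app in (Appearance.NFD, Appearance.MFD):
            masked = preprocessed[app]["masked"]
            ilm, rnfl = segment_layers_nfd(masked)
            both = ilm.valid & rnfl.valid
            assert (rnfl.z_um - ilm.z_um)[both].min() >= 0

    def test_pit_thickness_reaches_zero(self, preprocessed):
        data = preprocessed[Appearance.NFD]
        masked = data["masked"]
        g = masked.geometry
        ilm, rnfl = segment_layers_nfd(masked)
        t = thickness_between(ilm, rnfl)
        fx, fy = data["truth"].fovea_um[:2]
        ix, iy = int(fx / g.dx_um), int(fy / g.dy_um)
        near = t.t_um[max(ix - 3, 0):ix + 4, max(iy - 1, 0):iy + 2]
        nearv = t.valid[max(ix - 3, 0):ix + 4, max(iy - 1, 0):iy + 2]
        assert near[nearv].min() <= g.dz_um


class TestIRFExtraction:
    def test_single_planted_cyst_recovered(self, preprocessed):
        data = preprocessed[Appearance.AFD]
        masked = data["masked"]
        ilm = delineate_ilm(masked)
        regions = extract_irf_regions(masked, ilm)
        assert len(regions) == 1
        g = masked.geometry
        cyst = data["truth"].spec.cysts[0]
        cx = cyst.center_um[0] / g.dx_um - 0.5
        cy = cyst.center_um[1] / g.dy_um - 0.5
        got = regions[0].centroid_vox
        assert abs(got[0] - cx) <= 2 and abs(got[1] - cy) <= 2

    def test_no_cyst_yields_empty_list(self, preprocessed):
        data = preprocessed[Appearance.NFD]
        ilm = delineate_ilm(data["masked"])
        assert extract_irf_regions(data["masked"], ilm) == []

    def test_darker_cyst_ranked_first(self):
        spec = make_spec(Appearance.AFD, seed=2, noise_level="none")
        g = spec.geometry
        c0 = spec.cysts[0]
        bright = CystSpec(
            center_um=(c0.center_um[0] - 900, c0.center_um[1],
                       c0.center_um[2] + 120),
            semi_axes_um=(300, 300, 90), intensity=0.30)
        vol, truth = generate_phantom(replace(spec, cysts=(c0, bright)))
        from foveafinder.preprocess import (apply_mask, build_fovea_mask,
                                            correct_axial_motion,
                                            denoise_speckle)
        corrected, _ = correct_axial_motion(vol)
        masked = apply_mask(denoise_speckle(corrected), build_fovea_mask(g))
        ilm = delineate_ilm(masked)
        regions = extract_irf_regions(masked, ilm)
        assert len(regions) >= 2
        assert regions[0].mean_intensity < regions[1].mean_intensity


class TestThickness:
    def _surface(self, z, valid, g, kind=SurfaceKind.ILM):
        return SurfaceMap(z_um=z, valid=valid, kind=kind, geometry=g)

    def test_identical_surfaces_zero_map(self):
        g = VendorGeometry("tiny", nx=4, ny=4, nz=16)
        z = np.full((4, 4), 100.0)
        v = np.ones((4, 4), dtype=bool)
        t = thickness_between(self._surface(z, v, g),
                              self._surface(z.copy(), v.copy(), g,
                                            SurfaceKind.RNFL_BOTTOM))
        assert np.all(t.t_um[t.valid] == 0)

    def test_constant_offset(self):
        g = VendorGeometry("tiny", nx=4, ny=4, nz=16)
        z = np.full((4, 4), 100.0)
        v = np.ones((4, 4), dtype=bool)
        t = thickness_between(self._surface(z, v, g),
                              self._surface(z + 30.0, v.copy(), g,
                                            SurfaceKind.RNFL_BOTTOM))
        assert np.all(t.t_um[t.valid] == pytest.approx(30.0))

    def test_crossing_surfaces_rejected(self):
        g = VendorGeometry("tiny", nx=4, ny=4, nz=16)
        z = np.full((4, 4), 100.0)
        v = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="cross"):
            thickness_between(self._surface(z, v, g),
                              self._surface(z - 10.0, v.copy(), g,
                                            SurfaceKind.RNFL_BOTTOM))
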