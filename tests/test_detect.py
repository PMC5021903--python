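from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foveafinder.core import Appearance, VendorGeometry
from foveafinder.detect import (NoZeroThicknessError, PipelineConfig,
                                center_of_mass, detect_fovea,
                                detect_fovea_mfd_afd, detect_fovea_nfd,
                                pairwise_ilm_irf_distances)
from foveafinder.segment import IRFRegion, SurfaceKind, SurfaceMap, ThicknessMap
from foveafinder.synthetic import generate_phantom, make_spec


class TestPairwiseDistances:
    def test_single_pair(self):
        res = pairwise_ilm_irf_distances([(0, 0, 10)], [(0, 0, 4)])
        assert res.min_distance_um == pytest.approx(6.0)

    def test_exact_zero_excluded_then_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            pairwise_ilm_irf_distances([(0, 0, 10)], [(0, 0, 10)])

    def test_zero_excluded_but_other_pairs_remain(self):
        res = pairwise_ilm_irf_distances([(0, 0, 10), (3, 4, 10)],
                                         [(0, 0, 10)])
        assert res.min_distance_um == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        a = rng.random((50, 3)) * 1000
        b = rng.random((40, 3)) * 1000
        res = pairwise_ilm_irf_distances(a, b)
        brute = min(np.sqrt(((p - q) ** 2).sum()) for p in a for q in b)
        assert res.min_distance_um == brute

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            pairwise_ilm_irf_distances(np.empty((0, 3)), [(0, 0, 1)])


class TestCenterOfMass:
    def test_singleton(self):
        assert center_of_mass([(10, 10)]) == (10, 10)

    def test_two_points(self):
        assert center_of_mass([(10, 10), (20, 20)]) == (15, 15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=1, max_size=20))
    def test_within_bounding_box(self, pts):
        cx, cy = center_of_mass(pts)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        assert min(xs) - 1e-6 <= cx <= max(xs) + 1e-6
        assert min(ys) - 1e-6 <= cy <= max(ys) + 1e-6


def _flat_ilm(geom, depth=800.0):
    return SurfaceMap(z_um=np.full((geom.nx, geom.ny), depth),
                      valid=np.ones((geom.nx, geom.ny), dtype=bool),
                      kind=SurfaceKind.ILM, geometry=geom)


class TestNFDBranch:
    def setup_method(self):
        self.geom = VendorGeometry("toy", nx=40, ny=20, nz=64)
        self.ilm = _flat_ilm(self.geom)

    def _thickness(self, t):
        return ThicknessMap(t_um=t, valid=np.ones_like(t, dtype=bool))

    def test_single_zero_point(self):
        t = np.full((40, 20), 50.0)
        t[12, 7] = 0.0
        res = detect_fovea_nfd(self._thickness(t), self.ilm)
        assert (res.x_vox, res.y_vox) == (12, 7)
        assert res.candidate_count == 1

    def test_symmetric_zero_disk_centre_of_mass(self):
        t = np.full((40, 20), 50.0)
        xx, yy = np.meshgrid(np.arange(40), np.arange(20), indexing="ij")
        t[(xx - 20) ** 2 + (yy - 10) ** 2 <= 9] = 0.0
        res = detect_fovea_nfd(self._thickness(t), self.ilm)
        g = self.geom
        assert res.x_um == pytest.approx((20 + 0.5) * g.dx_um, abs=g.dx_um)
        assert res.y_um == pytest.approx((10 + 0.5) * g.dy_um, abs=g.dy_um)

    def test_all_positive_thickness_raises(self):
        t = np.full((40, 20), 50.0)
        with pytest.raises(NoZeroThicknessError):
            detect_fovea_nfd(self._thickness(t), self.ilm)


class TestMFDAFDBranch:
    def setup_method(self):
        self.geom = VendorGeometry("toy", nx=40, ny=20, nz=64)

    def _region(self, points):
        return IRFRegion(label_id=1, boundary_points_um=np.asarray(points),
                         volume_vox=100, mean_intensity=0.1,
                         centroid_vox=(20, 10, 40))

    def test_minimum_gap_bscan_selected(self):
        g = self.geom
        z = np.full((g.nx, g.ny), 800.0)
        z[15, 8] = 840.0  # locally deepest ILM point: closest to the fluid
        ilm = SurfaceMap(z_um=z, valid=np.ones_like(z, dtype=bool),
                         kind=SurfaceKind.ILM, geometry=g)
        irf = self._region([[(15 + 0.5) * g.dx_um, (8 + 0.5) * g.dy_um, 900.0]])
        res = detect_fovea_mfd_afd(ilm, irf, Appearance.MFD)
        assert (res.x_vox, res.y_vox) == (15, 8)
        assert res.appearance is Appearance.MFD

    def test_tied_bscans_merged_by_centre_of_mass(self):
        g = self.geom
        z = np.full((g.nx, g.ny), 800.0)
        z[15, 6] = 840.0
        z[15, 12] = 840.0  # identical minimum on two B-scans
        ilm = SurfaceMap(z_um=z, valid=np.ones_like(z, dtype=bool),
                         kind=SurfaceKind.ILM, geometry=g)
        pts = [[(15 + 0.5) * g.dx_um, (6 + 0.5) * g.dy_um, 900.0],
               [(15 + 0.5) * g.dx_um, (12 + 0.5) * g.dy_um, 900.0]]
        res = detect_fovea_mfd_afd(ilm, self._region(pts), Appearance.AFD)
        assert res.candidate_count == 2
        assert res.y_um == pytest.approx((9 + 0.5) * g.dy_um)

    def test_no_irf_falls_back_to_elevation_maximum(self):
        g = self.geom
        z = np.full((g.nx, g.ny), 800.0)
        z[22, 9] = 700.0  # highest elevation
        ilm = SurfaceMap(z_um=z, valid=np.ones_like(z, dtype=bool),
                         kind=SurfaceKind.ILM, geometry=g)
        res = detect_fovea_mfd_afd(ilm, None, Appearance.AFD)
        assert (res.x_vox, res.y_vox) == (22, 9)
        assert res.low_confidence
        assert res.provenance == "ilm-minimum-fallback"


class TestEndToEnd:
    def test_clean_nfd_recovered_within_30um(self, clean_phantoms):
        vol, truth = clean_phantoms[Appearance.NFD]
        res = detect_fovea(vol)
        assert res.appearance is Appearance.NFD
        err = np.hypot(res.x_um - truth.fovea_um[0],
                       res.y_um - truth.fovea_um[1])
        assert err <= 30.0

    def test_clean_afd_recovered_within_one_bscan_pitch(self, clean_phantoms):
        vol, truth = clean_phantoms[Appearance.AFD]
        res = detect_fovea(vol)
        assert res.appearance is Appearance.AFD
        assert abs(res.y_um - truth.fovea_um[1]) <= vol.geometry.dy_um

    def test_clean_mfd_recovered(self, clean_phantoms):
        vol, truth = clean_phantoms[Appearance.MFD]
        res = detect_fovea(vol)
        assert res.appearance is Appearance.MFD
        err = np.hypot(res.x_um - truth.fovea_um[0],
                       res.y_um - truth.fovea_um[1])
        assert err <= 150.0

    def test_result_inside_mask(self, clean_phantoms):
        from foveafinder.preprocess import build_fovea_mask

        for app, (vol, _) in clean_phantoms.items():
            res = detect_fovea(vol)
            mask = build_fovea_mask(vol.geometry)
            assert mask.grid[res.x_vox, res.y_vox]

    def test_deterministic(self, clean_phantoms):
        vol, _ = clean_phantoms[Appearance.MFD]
        a = detect_fovea(vol).to_dict()
        b = detect_fovea(vol).to_dict()
        assert a == b

    def test_cyst_scale_monotonicity(self):
        """Symmetrically enlarging the planted cyst must not move the
        detected MFD/AFD fovea by more than one voxel."""
        spec = make_spec(Appearance.AFD, seed=4, noise_level="none")
        c0 = spec.cysts[0]
        results = []
        for scale in (0.85, 1.0, 1.1):
            cyst = replace(c0, semi_axes_um=tuple(s * scale
                                                  for s in c0.semi_axes_um))
            vol, _ = generate_phantom(replace(spec, cysts=(cyst,)))
            results.append(detect_fovea(vol))
        for a, b in zip(results, results[1:]):
            assert abs(a.x_vox - b.x_vox) <= 1
            assert abs(a.y_vox - b.y_vox) <= 1


def test_pipeline_config_from_dict_roundtrip():
    cfg = PipelineConfig.from_dict({
        "denoise": {"method": "median", "strength": 0.5},
        "mask": {"axis_scale": 0.4},
        "segment": {"s_max": 3},
        "classify": {"contiguity_um": 200.0},
    })
    assert cfg.denoise.method == "median"
    assert cfg.mask.axis_scale == 0.4
    assert cfg.segment.s_max == 3
    assert cfg.classify.contiguity_um == 200.0
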