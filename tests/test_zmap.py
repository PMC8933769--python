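import numpy as np
import pytest
from scipy import ndimage

from amypet.volumes import Mask, Volume
from amypet.zmap import (NormativeDB, ZMap, build_analysis_mask,
                         build_normative_db, compute_zmap,
                         load_normative_db, normalize_by_reference,
                         prepare_subject, regional_positivity, render_overlay,
                         save_normative_db, threshold_clusters)
from tests.conftest import centered_grid


def toy_zmap(z_data, grid, mask_data=None):
    """ZMap wrapper around a hand-crafted Z array (unit-SD toy database)."""
    if mask_data is None:
        mask_data = np.ones(grid.dims, dtype=bool)
    db = NormativeDB(
        tracer="PiB", reference="WhlCbl",
        mean_volume=Volume(grid=grid, data=np.zeros(grid.dims)),
        sd_volume=Volume(grid=grid, data=np.ones(grid.dims)),
        n_controls=2,
        analysis_mask=Mask(grid=grid, data=mask_data, name="analysis"),
    )
    return ZMap(z=Volume(grid=grid, data=z_data), db=db)


def tagged(grid, data, db):
    return Volume(grid=grid, data=data,
                  meta={"fwhm_mm": db.fwhm_mm, "reference": db.reference})


@pytest.fixture(scope="module")
def small_db(small_gen):
    return small_gen.normative_db(8)


class TestNormalize:
    def test_constant_volume_becomes_one(self, small_vs):
        v = Volume(grid=small_vs.grid, data=np.full(small_vs.grid.dims, 3.0))
        out = normalize_by_reference(v, small_vs, "WhlCbl")
        np.testing.assert_allclose(out.data, 1.0)

    def test_reference_mean_is_one(self, small_vs, rng):
        from amypet.voi import mask_mean
        v = Volume(grid=small_vs.grid, data=rng.random(small_vs.grid.dims) + 0.5)
        out = normalize_by_reference(v, small_vs, "Pons")
        assert mask_mean(out, small_vs.reference_masks["Pons"]) == \
            pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, small_vs, rng):
        v = Volume(grid=small_vs.grid, data=rng.random(small_vs.grid.dims) + 0.5)
        once = normalize_by_reference(v, small_vs, "WhlCbl")
        twice = normalize_by_reference(once, small_vs, "WhlCbl")
        np.testing.assert_allclose(twice.data, once.data, rtol=1e-12)


class TestAnalysisMask:
    def test_none_wm_returns_target(self, small_vs):
        m = build_analysis_mask(small_vs, None)
        np.testing.assert_array_equal(m.data, small_vs.target_mask.data)

    def test_disjoint_wm_leaves_target(self, small_vs):
        wm = Mask(grid=small_vs.grid,
                  data=~small_vs.target_mask.data, name="wm")
        m = build_analysis_mask(small_vs, wm)
        np.testing.assert_array_equal(m.data, small_vs.target_mask.data)

    def test_covering_wm_rejected(self, small_vs):
        wm = Mask(grid=small_vs.grid,
                  data=np.ones(small_vs.grid.dims, dtype=bool), name="wm")
        with pytest.raises(ValueError, match="empty analysis mask"):
            build_analysis_mask(small_vs, wm)


class TestBuildNormativeDB:
    def _controls(self, small_vs, rng, cls, n=3):
        out = []
        for cl in cls:
            data = rng.random(small_vs.grid.dims) + 0.5
            out.append((Volume(grid=small_vs.grid, data=data), cl))
        return out

    def test_cl_filter_excludes_and_logs(self, small_vs, rng):
        controls = self._controls(small_vs, rng, [3.0, 7.0, 12.0])
        db = build_normative_db(controls, small_vs, "PiB", "WhlCbl",
                                cl_threshold=10.0)
        assert db.n_controls == 2
        assert db.excluded == [{"index": 2, "cl": 12.0}]

    def test_fewer_than_two_survivors_rejected(self, small_vs, rng):
        controls = self._controls(small_vs, rng, [3.0, 11.0, 12.0])
        with pytest.raises(ValueError, match="need >= 2"):
            build_normative_db(controls, small_vs, "PiB", "WhlCbl")

    def test_identical_controls_have_zero_sd(self, small_vs, rng):
        data = rng.random(small_vs.grid.dims) + 0.5
        controls = [(Volume(grid=small_vs.grid, data=data.copy()), 0.0)
                    for _ in range(2)]
        db = build_normative_db(controls, small_vs, "PiB", "WhlCbl")
        np.testing.assert_allclose(db.sd_volume.data, 0.0, atol=1e-12)

    def test_mean_sd_match_per_voxel_oracle(self, small_vs, rng):
        from amypet.volumes import gaussian_smooth
        controls = self._controls(small_vs, rng, [0.0] * 10)
        fwhm = 8.0
        db = build_normative_db(controls, small_vs, "PiB", "WhlCbl",
                                fwhm_mm=fwhm)
        processed = [
            normalize_by_reference(gaussian_smooth(v, fwhm), small_vs, "WhlCbl")
            for v, _ in controls
        ]
        coords = rng.integers(0, np.array(small_vs.grid.dims), size=(100, 3))
        for i, j, k in coords:
            vals = [p.data[i, j, k] for p in processed]
            mean = sum(vals) / len(vals)
            var = sum((x - mean) ** 2 for x in vals) / (len(vals) - 1)
            assert db.mean_volume.data[i, j, k] == pytest.approx(mean, abs=1e-9)
            assert db.sd_volume.data[i, j, k] == pytest.approx(var ** 0.5, abs=1e-9)

    def test_save_load_round_trip(self, small_db, tmp_path):
        save_normative_db(small_db, tmp_path / "db")
        back = load_normative_db(tmp_path / "db")
        assert back.tracer == small_db.tracer
        assert back.n_controls == small_db.n_controls
        assert back.fwhm_mm == small_db.fwhm_mm
        np.testing.assert_allclose(back.mean_volume.data,
                                   small_db.mean_volume.data, atol=1e-12)
        np.testing.assert_array_equal(back.analysis_mask.data,
                                      small_db.analysis_mask.data)


class TestComputeZmap:
    def test_subject_equal_to_mean_gives_zero(self, small_db):
        grid = small_db.mean_volume.grid
        subject = tagged(grid, small_db.mean_volume.data.copy(), small_db)
        zm = compute_zmap(subject, small_db)
        assert np.abs(zm.z.data[zm.analysis_mask.data]).max() == 0.0

    def test_mean_plus_sd_gives_one(self, small_db):
        grid = small_db.mean_volume.grid
        subject = tagged(grid, small_db.mean_volume.data +
                         small_db.sd_volume.data, small_db)
        zm = compute_zmap(subject, small_db)
        inside = zm.z.data[zm.analysis_mask.data]
        np.testing.assert_allclose(inside, 1.0, atol=1e-9)

    def test_matches_loop_oracle(self, small_db, rng):
        grid = small_db.mean_volume.grid
        subject = tagged(grid, rng.random(grid.dims) + 0.5, small_db)
        zm = compute_zmap(subject, small_db)
        mask = zm.analysis_mask.data
        coords = np.argwhere(mask)[rng.permutation(int(mask.sum()))[:200]]
        for i, j, k in coords:
            expected = (subject.data[i, j, k]
                        - small_db.mean_volume.data[i, j, k]) \
                / small_db.sd_volume.data[i, j, k]
            assert zm.z.data[i, j, k] == pytest.approx(expected, abs=1e-9)

    def test_provenance_mismatch_rejected(self, small_db, rng):
        grid = small_db.mean_volume.grid
        raw = Volume(grid=grid, data=rng.random(grid.dims) + 0.5)
        with pytest.raises(ValueError, match="provenance"):
            compute_zmap(raw, small_db)
        wrong_fwhm = Volume(grid=grid, data=raw.data,
                            meta={"fwhm_mm": 2.0, "reference": small_db.reference})
        with pytest.raises(ValueError, match="provenance"):
            compute_zmap(wrong_fwhm, small_db)

    def test_zero_sd_voxels_excluded_not_clamped(self, small_vs, rng):
        # controls identical inside the striatum -> SD exactly 0 there;
        # those voxels must leave the mask, not produce infinite Z
        base = rng.random(small_vs.grid.dims) + 0.5
        pinned = small_vs.region_masks["striatum"].data | \
            small_vs.reference_masks["WhlCbl"].data
        controls = []
        for _ in range(3):
            data = rng.random(small_vs.grid.dims) + 0.5
            # identical striatum *and* reference region, so the
            # reference-normalized striatum is identical across controls
            data[pinned] = base[pinned]
            controls.append((Volume(grid=small_vs.grid, data=data), 0.0))
        db = build_normative_db(controls, small_vs, "PiB", "WhlCbl", fwhm_mm=0.0)
        subject = tagged(small_vs.grid, rng.random(small_vs.grid.dims) + 0.5, db)
        zm = compute_zmap(subject, db)
        assert zm.n_sd_excluded >= small_vs.region_masks["striatum"].n_voxels
        assert np.all(np.isfinite(zm.z.data))

    def test_global_rescale_leaves_zmap_unchanged(self, small_gen, small_db, rng):
        raw, _ = small_gen.draw_control(np.random.default_rng(77))
        z1 = compute_zmap(prepare_subject(raw, small_gen.vs, small_db), small_db)
        scaled = raw.with_data(raw.data * 13.7)
        z2 = compute_zmap(prepare_subject(scaled, small_gen.vs, small_db),
                          small_db)
        np.testing.assert_allclose(z2.z.data, z1.z.data, atol=1e-8)


class TestThresholdClusters:
    def test_subminimal_blob_dropped(self):
        grid = centered_grid((24, 24, 24), 2.0)
        z = np.zeros(grid.dims)
        z[2:12, 2:12, 2:5] = 5.0  # 10*10*3 = 300 voxels
        z[2, 2, 2] = 0.0          # -> 299
        cs = threshold_clusters(toy_zmap(z, grid), min_voxels=300)
        assert len(cs) == 0

    def test_minimal_blob_survives(self):
        grid = centered_grid((24, 24, 24), 2.0)
        z = np.zeros(grid.dims)
        z[2:12, 2:12, 2:5] = 5.0
        cs = threshold_clusters(toy_zmap(z, grid), min_voxels=300)
        assert len(cs) == 1
        assert cs.clusters[0].size == 300
        assert cs.clusters[0].peak_z == 5.0

    @pytest.mark.parametrize("connectivity,expected", [(6, 2), (18, 1), (26, 1)])
    def test_diagonal_touching_blobs(self, connectivity, expected):
        grid = centered_grid((24, 24, 24), 2.0)
        z = np.zeros(grid.dims)
        z[0:10, 0:10, 0:3] = 3.0
        z[10:20, 10:20, 0:3] = 3.0  # touches the first only edge-diagonally
        cs = threshold_clusters(toy_zmap(z, grid), min_voxels=300,
                                connectivity=connectivity)
        assert len(cs) == expected

    def test_sorted_by_size_descending(self):
        grid = centered_grid((30, 30, 30), 2.0)
        z = np.zeros(grid.dims)
        z[0:10, 0:10, 0:4] = 3.0    # 400
        z[20:30, 20:30, 20:23] = 9.0  # 300
        cs = threshold_clusters(toy_zmap(z, grid), min_voxels=300)
        assert [c.size for c in cs.clusters] == [400, 300]

    def test_respects_analysis_mask(self):
        grid = centered_grid((24, 24, 24), 2.0)
        z = np.full(grid.dims, 5.0)
        mask = np.zeros(grid.dims, dtype=bool)
        mask[0:10, 0:10, 0:2] = True  # 200 voxels only
        cs = threshold_clusters(toy_zmap(z, grid, mask), min_voxels=300)
        assert len(cs) == 0

    def test_invalid_parameters(self):
        grid = centered_grid((10, 10, 10), 2.0)
        zm = toy_zmap(np.zeros(grid.dims), grid)
        with pytest.raises(ValueError):
            threshold_clusters(zm, z_threshold=-1.0)
        with pytest.raises(ValueError):
            threshold_clusters(zm, connectivity=4)


class TestRegionalPositivity:
    def _blob(self, small_vs, region, n):
        mask = small_vs.region_masks[region].data
        vox = np.argwhere(mask)
        centroid = vox.mean(axis=0)
        d = np.linalg.norm(vox - centroid, axis=1)
        return vox[np.argsort(d)[:n]]

    def test_empty_clusterset_all_negative(self, small_vs):
        grid = small_vs.grid
        cs = threshold_clusters(toy_zmap(np.zeros(grid.dims), grid),
                                min_voxels=100)
        calls = regional_positivity(cs, small_vs)
        assert calls.positive_regions() == []

    def test_cluster_inside_frontal_only(self, small_vs):
        z = np.zeros(small_vs.grid.dims)
        z[tuple(self._blob(small_vs, "frontal", 300).T)] = 4.0
        cs = threshold_clusters(toy_zmap(z, small_vs.grid), min_voxels=100)
        calls = regional_positivity(cs, small_vs)
        assert calls.positive_regions() == ["frontal"]
        assert calls.overlap_voxels["frontal"] == 300

    def test_cluster_straddling_two_regions(self, small_vs):
        frontal = small_vs.region_masks["frontal"].data
        parietal = small_vs.region_masks["parietal"].data
        touching = parietal & ndimage.binary_dilation(
            frontal, ndimage.generate_binary_structure(3, 3))
        assert touching.any(), "fixture regions must share a boundary"
        seed = np.argwhere(touching)[0]
        both = np.argwhere(frontal | parietal)
        d = np.linalg.norm(both - seed, axis=1)
        blob = both[np.argsort(d)[:200]]
        z = np.zeros(small_vs.grid.dims)
        z[tuple(blob.T)] = 4.0
        cs = threshold_clusters(toy_zmap(z, small_vs.grid), min_voxels=100)
        calls = regional_positivity(cs, small_vs)
        assert set(calls.positive_regions()) == {"frontal", "parietal"}


class TestRenderOverlay:
    def test_zero_zmap_writes_anatomy_slices(self, small_vs, tmp_path):
        grid = small_vs.grid
        zm = toy_zmap(np.zeros(grid.dims), grid)
        anatomy = Volume(grid=grid, data=np.ones(grid.dims))
        paths = render_overlay(zm, anatomy, small_vs, tmp_path, n_slices=2)
        assert len(paths) == 3 * 2
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)

    def test_invalid_window_rejected(self, small_vs, tmp_path):
        grid = small_vs.grid
        zm = toy_zmap(np.zeros(grid.dims), grid)
        anatomy = Volume(grid=grid, data=np.ones(grid.dims))
        with pytest.raises(ValueError, match="z_low"):
            render_overlay(zm, anatomy, small_vs, tmp_path, z_low=7.0, z_high=2.6)
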