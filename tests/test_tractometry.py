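"""Tractometry: resampling, segmentation vs brute force, cleaning,
profiles, laterality, and I/O round trips."""

import numpy as np
import pytest

from spelltract.synth import simulate_bundle, toy_bundle_geometries
from spelltract.tractometry import (
    CleaningError,
    CleaningParams,
    NiftiFASampler,
    Tract,
    TractDefinition,
    Tractogram,
    WaypointROI,
    clean_tract,
    constant_fa,
    gaussian_core_weights,
    lateralization_index,
    load_definitions,
    load_tractogram,
    resample_streamline,
    save_definitions,
    save_tractogram,
    segment_tract,
    streamline_length,
    toy_tract_definitions,
    tract_core,
    weighted_fa_profile,
)


# --- resampling ----------------------------------------------------------

class TestResample:
    def test_straight_segment_uniform_spacing(self):
        s = np.array([[0, 0, 0], [0, 0, 99.0]])
        r = resample_streamline(s, 100)
        spacing = np.linalg.norm(np.diff(r, axis=0), axis=1)
        assert np.allclose(spacing, 1.0)
        assert np.allclose(r[0], s[0]) and np.allclose(r[-1], s[-1])

    def test_idempotent_on_smooth_curve(self):
        t = np.linspace(0, np.pi, 400)
        pts = np.column_stack([20 * np.cos(t), 20 * np.sin(t), t])
        once = resample_streamline(pts, 100)
        twice = resample_streamline(once, 100)
        assert np.allclose(once, twice, atol=1e-3)

    def test_helix_length_preserved(self):
        t = np.linspace(0, 4 * np.pi, 2000)
        helix = np.column_stack([np.cos(t), np.sin(t), t / 4])
        analytic = 4 * np.pi * np.sqrt(1 + 1 / 16)
        r = resample_streamline(helix, 100)
        assert streamline_length(r) == pytest.approx(analytic, rel=0.01)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            resample_streamline(np.zeros((5, 3)), 1)


# --- segmentation --------------------------------------------------------

def brute_force_membership(tractogram, definition):
    """Independent oracle: dense point-in-region scan on upsampled
    streamlines (no segment-crossing logic needed at high density)."""
    kept = []
    for i, s in enumerate(tractogram):
        dense = resample_streamline(s, 2000)
        ok = True
        for roi in definition.and_rois:
            if not roi.contains(dense).any():
                ok = False
                break
        if ok:
            for roi in definition.not_rois:
                if roi.contains(dense).any():
                    ok = False
                    break
        if ok:
            kept.append(i)
    return kept


class TestSegmentation:
    def _mixed_fixture(self, seed=3):
        geoms = toy_bundle_geometries()
        sls = []
        for g in geoms.values():
            sls += simulate_bundle(g, 60, seed=seed).streamlines
        return Tractogram(sls)

    @pytest.mark.parametrize("tract_name", ["SLF-I", "SLF-II", "SLF-III", "Arcuate", "ILF"])
    def test_counts_match_brute_force_scan(self, tract_name):
        tg = self._mixed_fixture()
        for hemi in ("L", "R"):
            definition = toy_tract_definitions(hemi)[tract_name]
            tract = segment_tract(tg, definition)
            oracle = brute_force_membership(tg, definition)
            assert len(tract) == len(oracle)

    def test_not_roi_excludes(self):
        # straight frontoparietal line that also dips through the NOT box
        d = toy_tract_definitions("R")["SLF-III"]
        good = np.column_stack(
            [np.full(50, 25.0), np.linspace(30, -30, 50), np.full(50, 3.0)]
        )
        bad = good.copy()
        bad[:, 2] = np.where(np.abs(bad[:, 1]) < 10, -8.0, 3.0)  # dips below Sylvian proxy
        tract = segment_tract(Tractogram([good, bad]), d)
        assert len(tract) == 1

    def test_streamlines_reoriented_frontal_to_parietal(self):
        d = toy_tract_definitions("R")["SLF-III"]
        fwd = np.column_stack(
            [np.full(50, 25.0), np.linspace(30, -30, 50), np.full(50, 3.0)]
        )
        rev = fwd[::-1].copy()
        tract = segment_tract(Tractogram([fwd, rev]), d)
        assert len(tract) == 2
        for s in tract:
            assert s[0, 1] > s[-1, 1]  # runs anterior -> posterior

    def test_empty_tractogram_rejected_and_empty_result_flagged(self):
        d = toy_tract_definitions("R")["SLF-III"]
        with pytest.raises(ValueError):
            segment_tract(Tractogram([]), d)
        far = np.column_stack(
            [np.full(10, 25.0), np.linspace(30, -30, 10), np.full(10, -30.0)]
        )
        with pytest.warns(UserWarning, match="no streamlines"):
            tract = segment_tract(Tractogram([far]), d)
        assert tract.metadata["empty"]


# --- cleaning ------------------------------------------------------------

def _parallel_bundle(n=20, jitter=0.0, rng=None):
    sls = []
    for i in range(n):
        y = np.linspace(30, -30, 40)
        x = np.full(40, 25.0) + (i - n / 2) * 0.1
        z = np.full(40, 3.0)
        if rng is not None and jitter:
            x = x + rng.normal(0, jitter, 40)
        sls.append(np.column_stack([x, y, z]))
    return sls


class TestCleaning:
    def _tract(self, sls):
        d = toy_tract_definitions("R")["SLF-III"]
        return Tract(d, sls)

    def test_injected_double_length_streamline_removed(self, rng):
        sls = _parallel_bundle(20, jitter=0.05, rng=rng)
        long = np.column_stack(
            [np.full(80, 25.0), np.linspace(60, -60, 80), np.full(80, 3.0)]
        )
        tract = self._tract(sls + [long])
        cleaned = clean_tract(tract, CleaningParams(length_sd=3, spatial_sd=4))
        assert len(cleaned) == 20
        assert all(streamline_length(s) < 100 for s in cleaned)

    def test_homogeneous_bundle_untouched(self, rng):
        sls = _parallel_bundle(20, jitter=0.02, rng=rng)
        cleaned = clean_tract(self._tract(sls), CleaningParams(length_sd=3, spatial_sd=4))
        assert len(cleaned) == 20

    def test_spatial_outlier_removed(self, rng):
        sls = _parallel_bundle(20, jitter=0.05, rng=rng)
        stray = sls[0].copy()
        stray[:, 0] += 15.0
        cleaned = clean_tract(
            self._tract(sls + [stray]), CleaningParams(length_sd=3, spatial_sd=4)
        )
        assert len(cleaned) == 20

    def test_order_independent(self, rng):
        sls = _parallel_bundle(15, jitter=0.3, rng=rng)
        long = np.column_stack(
            [np.full(80, 25.0), np.linspace(60, -60, 80), np.full(80, 3.0)]
        )
        sls = sls + [long]
        a = clean_tract(self._tract(sls), CleaningParams(length_sd=2, spatial_sd=3))
        perm = [sls[i] for i in np.random.default_rng(0).permutation(len(sls))]
        b = clean_tract(self._tract(perm), CleaningParams(length_sd=2, spatial_sd=3))
        key = lambda t: sorted(round(float(s[:, 0].sum()), 6) for s in t)
        assert key(a) == key(b)

    def test_too_few_streamlines_rejected(self):
        with pytest.raises(ValueError):
            clean_tract(self._tract(_parallel_bundle(2)))

    def test_slf_preset_uses_one_sd_length_rule(self):
        assert toy_tract_definitions("L")["SLF-III"].cleaning.length_sd == 1.0
        assert toy_tract_definitions("L")["Arcuate"].cleaning.length_sd == 3.0
        assert toy_tract_definitions("L")["ILF"].cleaning.spatial_sd == 4.0


class TestCore:
    def test_parallel_lines_average(self):
        a = np.column_stack([np.full(10, -1.0), np.linspace(0, 9, 10), np.zeros(10)])
        b = a.copy()
        b[:, 0] = 1.0
        core = tract_core([a, b])
        assert np.allclose(core[:, 0], 0.0)

    def test_single_streamline_is_its_own_core(self, rng):
        s = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        assert np.allclose(tract_core([s]), s)

    def test_unresampled_input_rejected(self):
        with pytest.raises(ValueError, match="common node count"):
            tract_core([np.zeros((5, 3)), np.zeros((7, 3))])

    def test_core_near_generating_centerline(self):
        geom = toy_bundle_geometries()["SLF-III"]
        tg = simulate_bundle(geom, 80, seed=9)
        right = [s for s, h in zip(tg.streamlines, tg.metadata["hemisphere"]) if h == "R"]
        stack = [resample_streamline(s, 100) for s in right]
        core = tract_core(stack)
        center = resample_streamline(geom.control_points, 100)
        # within the lateral offset SD of the generator
        assert np.abs(core - center).max() < 2 * geom.spread


# --- profiles ------------------------------------------------------------

class TestProfile:
    def _segmented(self, seed=5, n=60):
        geom = toy_bundle_geometries()["SLF-III"]
        tg = simulate_bundle(geom, n, seed=seed)
        return segment_tract(tg, toy_tract_definitions("R")["SLF-III"])

    def test_constant_field_gives_constant_profile(self):
        prof = weighted_fa_profile(self._segmented(), constant_fa(0.5))
        assert np.allclose(prof.node_fa, 0.5)
        assert prof.tract_fa == pytest.approx(0.5)

    def test_weights_sum_to_one_per_node(self):
        tract = self._segmented()
        stack = np.stack([resample_streamline(s, 100) for s in tract])
        w, _, _ = gaussian_core_weights(stack)
        assert np.allclose(w.sum(axis=0), 1.0)
        assert (w >= 0).all()

    def test_identical_streamlines_profile_equals_path_fa(self):
        s = np.column_stack(
            [np.full(60, 25.0), np.linspace(30, -30, 60), np.full(60, 3.0)]
        )
        d = toy_tract_definitions("R")["SLF-III"]
        tract = Tract(d, [s.copy() for _ in range(5)])

        def fa(points):
            return 0.3 + 0.004 * np.abs(points[:, 1])  # varies along y

        with pytest.warns(UserWarning, match="singular"):
            prof = weighted_fa_profile(tract, fa, clip_to_rois=False)
        expected = fa(resample_streamline(s, 100))
        assert np.allclose(prof.node_fa, expected, atol=1e-9)

    def test_planted_fa_bump_recovered_at_right_nodes(self):
        tract = self._segmented()

        def fa(points):
            # bump between the ROIs in the middle third of y in [-15, 15]
            y = points[:, 1]
            return 0.4 + 0.2 * ((y > -5) & (y < 5))

        prof = weighted_fa_profile(tract, fa)
        mid = prof.node_fa[45:55]
        ends = np.concatenate([prof.node_fa[:20], prof.node_fa[-20:]])
        assert mid.mean() > 0.55
        assert ends.mean() < 0.45

    def test_profile_invariant_under_rigid_translation(self):
        tract = self._segmented()
        shift = np.array([10.0, -5.0, 7.0])

        def fa(points):
            return 0.3 + 0.01 * np.cos(points[:, 1] / 5)

        prof = weighted_fa_profile(tract, fa, clip_to_rois=False)
        moved = Tract(tract.definition, [s + shift for s in tract.streamlines])

        def fa_moved(points):
            return fa(points - shift)

        prof2 = weighted_fa_profile(moved, fa_moved, clip_to_rois=False)
        assert np.allclose(prof.node_fa, prof2.node_fa, atol=1e-9)

    def test_empty_tract_rejected(self):
        d = toy_tract_definitions("R")["SLF-III"]
        with pytest.raises(ValueError):
            weighted_fa_profile(Tract(d, []), constant_fa(0.5))


# --- laterality ----------------------------------------------------------

class TestLaterality:
    @pytest.mark.parametrize(
        "r,l,expected",
        [(620, 380, 0.24), (100, 100, 0.0), (7, 0, 1.0), (0, 7, -1.0)],
    )
    def test_identities(self, r, l, expected):
        assert lateralization_index(r, l) == pytest.approx(expected)

    def test_undefined_for_zero_counts(self):
        with pytest.raises(ValueError):
            lateralization_index(0, 0)

    def test_bundle_generator_hits_li_target_exactly(self):
        tg = simulate_bundle(toy_bundle_geometries()["SLF-III"], 1000, asymmetry=0.24, seed=1)
        assert tg.metadata["n_right"] == 620
        assert tg.metadata["n_left"] == 380
        assert lateralization_index(620, 380) == pytest.approx(0.24)


# --- I/O -----------------------------------------------------------------

class TestIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        sls = [np.cumsum(rng.normal(size=(12, 3)), axis=0) for _ in range(4)]
        path = tmp_path / "bundle.csv"
        save_tractogram(Tractogram(sls), path)
        back = load_tractogram(path)
        assert len(back) == 4
        for a, b in zip(sls, back):
            assert np.allclose(a, b)

    def test_tck_roundtrip(self, tmp_path, rng):
        sls = [np.cumsum(rng.normal(size=(12, 3)), axis=0).astype(np.float32) for _ in range(3)]
        path = tmp_path / "bundle.tck"
        save_tractogram(Tractogram([s.astype(float) for s in sls]), path)
        back = load_tractogram(path)
        assert len(back) == 3
        for a, b in zip(sls, back):
            assert np.allclose(a, b, atol=1e-4)

    def test_definitions_json_roundtrip(self, tmp_path):
        defs = toy_tract_definitions("L")
        path = tmp_path / "rois.json"
        save_definitions(defs, path)
        back = load_definitions(path)
        assert set(back) == set(defs)
        assert back["SLF-III"].cleaning.length_sd == 1.0
        assert back["SLF-III"].and_rois[0].coord == defs["SLF-III"].and_rois[0].coord

    def test_nifti_fa_sampler_trilinear(self, tmp_path):
        import nibabel as nib

        data = np.zeros((10, 10, 10))
        data[:, :, :] = np.arange(10)[None, None, :] / 10.0  # FA ramps along z
        affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm voxels
        img = nib.Nifti1Image(data, affine)
        sampler = NiftiFASampler(img)
        pts = np.array([[4.0, 4.0, 4.0], [4.0, 4.0, 5.0]])  # voxel z=2 and z=2.5
        vals = sampler(pts)
        assert vals[0] == pytest.approx(0.2)
        assert vals[1] == pytest.approx(0.25)

    def test_bad_coordinate_table_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="columns"):
            load_tractogram(p)
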