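import numpy as np
import pytest

from aneukit import VortexCoreSpec, make_flow_series
from aneukit.core import FlowSeries
from aneukit.texture import (
    FEATURE_NAMES,
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    GrayVolume,
    encode_direction,
    estimate_jet_direction,
    extract_all,
    first_order_features,
    glcm_features,
    glcm_matrices,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    quantize,
)

from oracles import texture_features_loop


def gv_from(gray, mask=None, n_levels=None):
    gray = np.asarray(gray, np.int64)
    if mask is None:
        mask = np.ones(gray.shape, bool)
    gv = GrayVolume(gray=gray, mask=mask)
    if n_levels:
        gv = quantize(gv, n_levels)
    return gv


class TestJetEstimation:
    def test_uniform_jet_recovered(self, small_domain):
        fs = make_flow_series(small_domain, n_frames=3,
                              jet_spec=(np.array([0, 0, 1.0]), 100.0),
                              noise_sd=0.0, seed=0)
        assert np.allclose(estimate_jet_direction(fs, small_domain), [0, 0, 1], atol=1e-9)

    def test_reversed_field_negates_direction(self, small_domain):
        fs = make_flow_series(small_domain, n_frames=3,
                              jet_spec=(np.array([0, 0, 1.0]), 100.0),
                              noise_sd=0.0, seed=0)
        rev = FlowSeries(frames=-fs.frames, times=fs.times,
                         domain=small_domain, period=fs.period)
        assert np.allclose(estimate_jet_direction(rev, small_domain), [0, 0, -1])

    def test_noisy_jet_within_5_degrees(self, small_domain):
        fs = make_flow_series(small_domain, n_frames=3,
                              jet_spec=(np.array([0, 0, 1.0]), 100.0),
                              noise_sd=5.0, seed=4)
        d = estimate_jet_direction(fs, small_domain)
        assert np.degrees(np.arccos(d @ [0, 0, 1])) < 5.0

    def test_zero_velocity_rejected(self, small_domain):
        frames = np.zeros((2,) + small_domain.sac_mask.shape + (3,))
        fs = FlowSeries(frames=frames, times=np.array([0.0, 0.5]),
                        domain=small_domain, period=1.0)
        with pytest.raises(ValueError):
            estimate_jet_direction(fs, small_domain)


class TestEncoding:
    @pytest.fixture()
    def aligned_series(self, small_domain):
        return make_flow_series(small_domain, n_frames=2,
                                jet_spec=(np.array([0, 0, 1.0]), 100.0),
                                noise_sd=0.0, seed=0)

    def test_parallel_gray_zero(self, aligned_series):
        gv = encode_direction(aligned_series, np.array([0, 0, 1.0]))
        assert np.all(gv.gray[gv.mask] == 0)

    def test_antiparallel_gray_255(self, aligned_series):
        gv = encode_direction(aligned_series, np.array([0, 0, -1.0]))
        assert np.all(gv.gray[gv.mask] == 255)

    def test_perpendicular_gray_128(self, aligned_series):
        gv = encode_direction(aligned_series, np.array([1.0, 0, 0]))
        assert np.all(gv.gray[gv.mask] == 128)   # round-half-up of 127.5

    def test_stagnant_field_rejected(self, small_domain, aligned_series):
        with pytest.raises(ValueError):
            encode_direction(aligned_series, np.array([0, 0, 1.0]), v_floor=1e9)

    def test_non_unit_jet_rejected(self, aligned_series):
        with pytest.raises(ValueError):
            encode_direction(aligned_series, np.array([0, 0, 2.0]))


class TestQuantize:
    def test_boundary_levels(self):
        gv = gv_from(np.array([[[0, 255, 128, 127]]]))
        q = quantize(gv, 16)
        assert q.levels.ravel().tolist() == [1, 16, 9, 8]

    def test_identity_at_256_levels(self, rng):
        gray = rng.integers(0, 256, (4, 4, 4))
        q = quantize(gv_from(gray), 256)
        assert np.array_equal(q.levels, gray + 1)

    def test_uniform_grays_fill_levels_evenly(self, rng):
        gray = rng.integers(0, 256, (12, 12, 12))
        q = quantize(gv_from(gray), 8)
        counts = np.bincount(q.levels[q.mask], minlength=9)[1:]
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 0.001

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize(gv_from(np.zeros((2, 2, 2))), 1)


class TestFamilyIdentities:
    def test_constant_volume_first_order(self):
        gv = gv_from(np.full((3, 3, 3), 7))
        f = first_order_features(gv)
        assert f["FirstOrder.Mean"] == 7
        assert f["FirstOrder.Range"] == 0
        assert f["FirstOrder.Entropy"] == 0
        assert f["FirstOrder.Uniformity"] == 1
        assert f["FirstOrder.Skewness"] == 0

    def test_bimodal_symmetry(self):
        gray = np.zeros((2, 5, 2), np.int64)
        gray[:, :, 1] = 255
        f = first_order_features(gv_from(gray))
        assert f["FirstOrder.Mean"] == pytest.approx(127.5)
        assert f["FirstOrder.Skewness"] == pytest.approx(0.0)

    def test_constant_volume_glcm(self):
        gv = gv_from(np.full((3, 3, 3), 40), n_levels=16)
        f = glcm_features(gv)
        assert f["GLCM.JointEnergy"] == pytest.approx(1.0)
        assert f["GLCM.JointEntropy"] == pytest.approx(0.0)
        assert f["GLCM.DifferenceAverage"] == pytest.approx(0.0)

    def test_glcm_checkerboard_hand_counts(self):
        # 2x2x1 checkerboard of quantized levels {1, 2}
        gray = np.array([[[0], [255]], [[255], [0]]])
        gv = gv_from(gray, n_levels=2)
        mats = glcm_matrices(gv)
        # along x: pairs (1,2) and (2,1) twice each -> off-diagonal only
        assert np.allclose(mats[0], [[0, 0.5], [0.5, 0]])
        # diagonal (1,1,0): the single pair joins the two level-1 corners
        assert np.allclose(mats[3], [[1.0, 0], [0, 0]])
        # anti-diagonal (1,-1,0): joins the two level-2 corners
        assert np.allclose(mats[4], [[0, 0], [0, 1.0]])
        for m in mats:
            if m.sum():
                assert m.sum() == pytest.approx(1.0)
                assert np.allclose(m, m.T)

    def test_single_line_long_run_emphasis(self):
        gray = np.zeros((6, 1, 1), np.int64)
        gv = gv_from(gray, n_levels=4)
        mat = glrlm_matrix(gv, (1, 0, 0))
        assert mat[0, 5] == 1 and mat.sum() == 1
        f = glrlm_features(gv)   # only x-direction has a 6-run; others runs of 1
        assert f["GLRLM.LongRunEmphasis"] == pytest.approx((36 + 12 * 1) / 13)

    def test_alternating_levels_short_runs(self):
        gray = np.zeros((8, 1, 1), np.int64)
        gray[1::2] = 255
        gv = gv_from(gray, n_levels=2)
        mat = glrlm_matrix(gv, (1, 0, 0))
        assert mat.shape[1] == 1   # all runs have length 1
        f = glrlm_features(gv)
        assert f["GLRLM.ShortRunEmphasis"] == pytest.approx(1.0)

    def test_glszm_zone_counting(self):
        gray = np.zeros((3, 3, 3), np.int64)
        gv = gv_from(gray, n_levels=16)
        mat = glszm_matrix(gv)
        assert mat[0, 26] == 1 and mat.sum() == 1   # one 27-voxel zone
        f = glszm_features(gv)
        assert f["GLSZM.ZonePercentage"] == pytest.approx(1 / 27)

    def test_two_blobs_two_zones(self):
        gray = np.zeros((7, 3, 3), np.int64)
        mask = np.zeros((7, 3, 3), bool)
        mask[:3] = True
        mask[4:] = True   # gap at x=3 separates the blobs
        gv = quantize(GrayVolume(gray=gray, mask=mask), 16)
        assert glszm_matrix(gv).sum() == 2


class TestFeatureCardinality:
    def test_family_partition(self):
        assert len(FIRST_ORDER_NAMES) == 18
        assert len(GLCM_NAMES) == 24
        assert len(GLRLM_NAMES) == 16
        assert len(GLSZM_NAMES) == 16
        assert len(FEATURE_NAMES) == 74
        assert len(set(FEATURE_NAMES)) == 74


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_features_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 6, 3))
        gray = rng.integers(0, 256, shape)
        mask = rng.random(shape) > 0.2
        if mask.sum() < 10:
            mask[:] = True
        n_levels = int(rng.choice([4, 8, 16]))
        gv = quantize(GrayVolume(gray=gray, mask=mask), n_levels)
        got = {}
        got.update(first_order_features(gv))
        got.update(glcm_features(gv))
        got.update(glrlm_features(gv))
        got.update(glszm_features(gv))
        want = texture_features_loop(gray, mask, n_levels)
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-9), name


class TestExtractAll:
    @pytest.fixture()
    def flow(self, small_domain):
        core = VortexCoreSpec(center=np.array([0.5, 0, 1.0]), radius=1.5,
                              circulation=900.0)
        return make_flow_series(small_domain, n_frames=4, vortex_spec=[core],
                                jet_spec=(np.array([0, 0, 1.0]), 80.0),
                                noise_sd=1.0, seed=3)

    def test_full_vector(self, small_domain, flow):
        feats = extract_all(flow, small_domain, n_levels=16)
        assert list(feats) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in feats.values())

    def test_determinism(self, small_domain, flow):
        a = extract_all(flow, small_domain)
        b = extract_all(flow, small_domain)
        assert a == b

    def test_corotation_invariance(self, small_domain, flow):
        # rotate field and jet together by 90 degrees about z
        feats = extract_all(flow, small_domain, jet=np.array([0, 0, 1.0]))
        rot = np.rot90(flow.frames, axes=(1, 2)).copy()
        vx, vy = rot[..., 0].copy(), rot[..., 1].copy()
        rot[..., 0], rot[..., 1] = -vy, vx
        # domain mask is axisymmetric about z, so the rotated series is valid
        rot_series = FlowSeries(frames=rot, times=flow.times,
                                domain=small_domain, period=flow.period)
        feats_rot = extract_all(rot_series, small_domain, jet=np.array([0, 0, 1.0]))
        for k in FEATURE_NAMES:
            assert feats_rot[k] == pytest.approx(feats[k], rel=1e-9), k

    def test_per_frame_mode(self, small_domain, flow):
        feats = extract_all(flow, small_domain, frame_mode="per-frame")
        assert len(feats) == 74
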