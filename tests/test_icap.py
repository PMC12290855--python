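"""Deconvolution, innovation-frame selection, and frame clustering."""
import numpy as np
import pytest
from scipy.optimize import lsq_linear

from cordmap import icap, synth
from cordmap.errors import ContractError, EmptySelectionError
from cordmap.types import BoldImage
from tests.conftest import make_bold

TR = 1.55


def _single_voxel(y):
    return BoldImage(np.asarray(y, float).reshape(1, 1, 1, -1), TR), \
        np.ones((1, 1, 1), bool)


class TestTvProx:
    @pytest.mark.parametrize("lam", [0.05, 0.3, 1.0, 5.0])
    def test_matches_bounded_least_squares_dual(self, lam):
        # the TV prox equals y - D^T u* where u* solves the
        # box-constrained dual; lsq_linear is an independent solver
        rng = np.random.default_rng(int(lam * 100))
        y = rng.normal(size=35)
        x = icap.tv_prox_1d(y, lam)
        D = np.diff(np.eye(len(y)), axis=0)
        dual = lsq_linear(D.T, y, bounds=(-lam, lam), tol=1e-14)
        np.testing.assert_allclose(x, y - D.T @ dual.x, atol=1e-9)

    def test_zero_lambda_identity(self):
        y = np.random.default_rng(0).normal(size=20)
        np.testing.assert_allclose(icap.tv_prox_1d(y, 0.0), y, atol=1e-12)

    def test_large_lambda_gives_mean(self):
        y = np.random.default_rng(1).normal(size=20)
        np.testing.assert_allclose(icap.tv_prox_1d(y, 1e6),
                                   np.full_like(y, y.mean()), atol=1e-9)


class TestDeconvolve:
    def test_step_recovered_at_right_location(self):
        T = 100
        h = synth.hrf_kernel(TR)
        a_true = np.zeros(T)
        a_true[40:] = 1.0
        y = np.convolve(a_true, h)[:T]
        img, mask = _single_voxel(y)
        act = icap.deconvolve(img, mask, lam=0.01, max_iter=500)
        jump = np.abs(np.diff(act.signals[0])).argmax()
        assert abs(jump - 39) <= 1

    def test_constant_input_no_transient(self):
        img, mask = _single_voxel(np.full(50, 3.0))
        act = icap.deconvolve(img, mask, lam=0.1, max_iter=500)
        assert np.abs(np.diff(act.signals[0])).max() <= 1e-8

    def test_infinite_regularization_flattens(self):
        rng = np.random.default_rng(2)
        img, mask = _single_voxel(rng.normal(size=60))
        act = icap.deconvolve(img, mask, lam=1e8, max_iter=300)
        assert np.ptp(act.signals[0]) <= 1e-6

    def test_objective_monotone_on_random_voxels(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(20, 1, 1, 80))
        act = icap.deconvolve(make_bold(data, TR), np.ones((20, 1, 1), bool),
                              max_iter=150)
        oh = act.objective_history
        assert np.all(np.diff(oh, axis=1) <= 1e-10 * np.maximum(oh[:, :-1], 1e-12))

    def test_nonpositive_lambda_rejected(self):
        img, mask = _single_voxel(np.arange(10.0))
        with pytest.raises(ContractError):
            icap.deconvolve(img, mask, lam=0.0)


class TestFrameSelection:
    def test_alpha_one_retains_every_frame(self):
        rng = np.random.default_rng(4)
        inn = icap.InnovationFrames(rng.normal(size=(30, 40)),
                                    np.ones((30, 1, 1), bool))
        sel = icap.select_significant_frames(inn, alpha=1.0, seed=0)
        assert len(sel.selected) == 40

    def test_white_noise_rarely_retained(self):
        # null calibration: with min_active_fraction=0.1 the pure-noise
        # retention rate stays at most 5% of frames across seeds
        retained = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            inn = icap.InnovationFrames(rng.normal(size=(200, 60)),
                                        np.ones((200, 1, 1), bool))
            try:
                sel = icap.select_significant_frames(
                    inn, min_active_fraction=0.1, seed=seed)
                retained.append(len(sel.selected) / 60)
            except EmptySelectionError:
                retained.append(0.0)
        assert np.mean(retained) <= 0.05

    def test_planted_events_recovered(self, denoised_phantom):
        config, truth, data = denoised_phantom
        from cordmap.denoise import smooth

        sm = smooth(data["cord"]["unfiltered"], (3, 3, 6))
        act = icap.deconvolve(sm, truth.cord_labels.mask(), max_iter=200)
        sel = icap.select_significant_frames(icap.innovations(act), seed=0)
        chosen = set(int(i) for i in sel.selected)
        hits, total = 0, 0
        for s in range(config.n_segments):
            for t in np.flatnonzero(truth.event_trains[s]):
                total += 1
                # an event at volume t produces an innovation spike at
                # frame t-1 (derivative index); allow +/- 1 volume
                hits += any((t + d) in chosen for d in (-2, -1, 0))
        assert hits / total >= 0.9

    def test_surrogate_count_floor(self):
        inn = icap.InnovationFrames(np.random.default_rng(0).normal(size=(5, 10)),
                                    np.ones((5, 1, 1), bool))
        with pytest.raises(ContractError):
            icap.select_significant_frames(inn, n_surrogates=5)


class TestClusterFrames:
    @staticmethod
    def _planted_frames(K=4, per=30, n_vox=80, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        templates = np.zeros((K, n_vox))
        block = n_vox // K
        for k in range(K):
            templates[k, k * block : (k + 1) * block] = 1.0
        frames, labels = [], []
        for k in range(K):
            for _ in range(per):
                sign = rng.choice([-1.0, 1.0])
                frames.append(sign * templates[k] + noise * rng.normal(size=n_vox))
                labels.append(k)
        return np.array(frames), np.array(labels), templates

    def test_planted_templates_recovered_bijectively(self):
        frames, _, templates = self._planted_frames()
        result = icap.cluster_frames(frames, 4, seed=0)
        corr = np.corrcoef(np.vstack([result.maps.T, templates]))[:4, 4:]
        best = np.abs(corr).argmax(axis=1)
        assert sorted(best) == [0, 1, 2, 3]
        assert (np.abs(corr).max(axis=1) >= 0.99).all()

    def test_k_one_gives_zscored_folded_mean(self):
        frames, _, _ = self._planted_frames(K=2, per=10, seed=1)
        result = icap.cluster_frames(frames, 1, seed=0)
        aligned = frames * result.signs[:, None]
        m = aligned.mean(axis=0)
        z = (m - m.mean()) / m.std(ddof=0)
        if z[np.argmax(np.abs(z))] < 0:
            z = -z
        np.testing.assert_allclose(result.maps[:, 0], z, atol=1e-10)

    def test_duplicating_frames_leaves_maps_unchanged(self):
        frames, _, _ = self._planted_frames(seed=2)
        r1 = icap.cluster_frames(frames, 4, seed=0)
        r2 = icap.cluster_frames(np.vstack([frames, frames]), 4, seed=0)
        # maps may be permuted; match by correlation
        corr = np.corrcoef(np.vstack([r1.maps.T, r2.maps.T]))[:4, 4:]
        assert (np.abs(corr).max(axis=1) >= 0.999).all()

    def test_polarity_invariance(self):
        frames, _, _ = self._planted_frames(seed=3)
        rng = np.random.default_rng(0)
        flips = rng.choice([-1.0, 1.0], size=len(frames))
        r1 = icap.cluster_frames(frames, 4, seed=0)
        r2 = icap.cluster_frames(frames * flips[:, None], 4, seed=0)
        np.testing.assert_allclose(r1.maps, r2.maps, atol=1e-10)
        assert np.array_equal(r1.assignments, r2.assignments)

    def test_too_few_frames(self):
        with pytest.raises(ContractError):
            icap.cluster_frames(np.ones((3, 10)), 5)


class TestConsensus:
    def test_perfectly_separated_clusters_score_one(self):
        frames, _, _ = TestClusterFrames._planted_frames(K=3, per=20, noise=0.001)
        result = icap.consensus_cluster(frames, 3, n_subsamples=20, seed=0)
        np.testing.assert_allclose(result.consensus_scores, 1.0, atol=1e-12)

    def test_single_isotropic_cloud_unstable(self):
        scores = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            frames = rng.normal(size=(60, 30))
            result = icap.consensus_cluster(frames, 2, n_subsamples=20, seed=seed)
            scores.append(result.mean_consensus)
        assert np.mean(scores) < 0.9

    def test_single_subsample_warns(self):
        frames, _, _ = TestClusterFrames._planted_frames(K=2, per=5)
        with pytest.warns(UserWarning, match="uninformative"):
            icap.consensus_cluster(frames, 2, n_subsamples=1, seed=0)


def test_phantom_cord_icap_recovers_segments(denoised_phantom):
    """K=7 clustering of significant innovation frames labels cord voxels
    by segment with good Dice against the planted ground truth."""
    from cordmap import parcellation, seedfc
    from cordmap.denoise import smooth

    config, truth, data = denoised_phantom
    sm = smooth(data["cord"]["unfiltered"], (3, 3, 6))
    gm = truth.cord_labels.mask()
    act = icap.deconvolve(sm, gm, max_iter=200)
    sel = icap.select_significant_frames(icap.innovations(act), seed=0)
    result = icap.cluster_frames(icap.frame_matrix(sel), config.n_segments, seed=0)
    wta = seedfc.winner_take_all(result.maps, gm, truth.cord_labels.affine)
    report = parcellation.match_labels_max_weight(wta.labels, truth.cord_labels)
    assert report.mean_dice >= 0.7
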