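"""MVKD likelihood-ratio scorer: arithmetic, oracles, limits and invariants."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal as mvn
from scipy.stats import norm

from formantlr.mvkd import (
    ComparisonSample,
    MVKDScorer,
    SingularCovarianceError,
    fit_background,
    reference_bandwidth,
)


def _toy_1d_model():
    """3 background speakers with means {0, 1, 2} and pooled W = 1."""
    c = 1 / np.sqrt(2)  # two tokens at mean +- c give pooled variance 2c^2 = 1
    samples = [np.array([[m - c], [m + c]]) for m in (0.0, 1.0, 2.0)]
    return MVKDScorer().fit(samples)


class TestFit:
    def test_pooled_covariance_matches_hand_arithmetic(self):
        samples = {
            "s1": np.array([[1.0], [3.0]]),
            "s2": np.array([[4.0], [8.0]]),
            "s3": np.array([[0.0], [2.0]]),
        }
        model = fit_background(samples, vowel="a", subset=("f1_hz",))
        # per-speaker centered sums of squares: 2, 8, 2 over N - m = 3
        assert model.within_covariance_[0, 0] == pytest.approx((2 + 8 + 2) / 3)
        np.testing.assert_allclose(model.speaker_means_.ravel(), [2.0, 6.0, 1.0])
        assert model.between_covariance_[0, 0] == pytest.approx(np.var([2, 6, 1], ddof=1))
        assert model.vowel == "a" and model.subset == ("f1_hz",)

    def test_normal_reference_bandwidth_closed_form(self):
        assert reference_bandwidth(1, 8) == pytest.approx((4 / 24) ** 0.2)
        assert reference_bandwidth(1, 8) == pytest.approx(0.6988271187715792)
        m = _toy_1d_model()
        assert m.bandwidth_ == pytest.approx((4 / (3 * 3)) ** (1 / 5))

    def test_constant_tokens_raise_singularity_error(self):
        samples = [np.full((3, 1), v) for v in (1.0, 2.0, 3.0)]
        with pytest.raises(SingularCovarianceError):
            MVKDScorer().fit(samples)

    def test_too_few_speakers_rejected(self):
        with pytest.raises(ValueError, match="3 background"):
            MVKDScorer().fit([np.random.default_rng(0).normal(size=(4, 2))] * 2)

    def test_subset_model_equals_fit_on_sliced_data(self, rng):
        samples = [rng.normal(size=(6, 3)) + off for off in (0.0, 1.0, 2.0, 0.5)]
        full = MVKDScorer().fit(samples)
        sub = full.subset_model([0, 2])
        direct = MVKDScorer().fit([s[:, [0, 2]] for s in samples])
        np.testing.assert_allclose(sub.within_covariance_, direct.within_covariance_)
        np.testing.assert_allclose(sub.between_covariance_, direct.between_covariance_)
        np.testing.assert_allclose(sub.speaker_means_, direct.speaker_means_)
        assert sub.bandwidth_ == direct.bandwidth_


class TestScoreOracles:
    def test_1d_toy_matches_numerical_integration(self):
        model = _toy_1d_model()
        W = model.within_covariance_[0, 0]
        C = model.bandwidth_**2 * model.between_covariance_[0, 0]
        mus = model.speaker_means_.ravel()

        def oracle(yq, yr, nq, nr):
            def integrand(theta, j):
                return (
                    norm.pdf(yq, theta, np.sqrt(W / nq))
                    * norm.pdf(yr, theta, np.sqrt(W / nr))
                    * norm.pdf(theta, mus[j], np.sqrt(C))
                )

            num = np.mean(
                [quad(integrand, -50, 50, args=(j,), limit=200)[0] for j in range(3)]
            )
            dq = np.mean([norm.pdf(yq, mu, np.sqrt(C + W / nq)) for mu in mus])
            dr = np.mean([norm.pdf(yr, mu, np.sqrt(C + W / nr)) for mu in mus])
            return np.log10(num / (dq * dr))

        for yq, yr, nq, nr in [(0.9, 1.1, 2, 2), (0.2, 1.9, 3, 2), (-0.5, 0.3, 4, 4)]:
            mine = model.score_means([[yq]], [[yr]], nq, nr)[0]
            expected = oracle(yq, yr, nq, nr)
            assert mine == pytest.approx(expected, rel=1e-6)

    def test_2d_model_matches_grid_integration(self, rng):
        samples = [rng.normal(loc, 1.0, size=(4, 2)) for loc in ([0, 0], [2, 1], [1, 3], [3, 3])]
        model = MVKDScorer().fit(samples)
        W, B, h = model.within_covariance_, model.between_covariance_, model.bandwidth_
        mus, C = model.speaker_means_, h * h * model.between_covariance_
        yq, yr, nq, nr = np.array([1.0, 1.2]), np.array([1.4, 0.9]), 3, 5
        pooled = (nq * yq + nr * yr) / (nq + nr)

        from scipy.integrate import simpson

        g1 = np.linspace(pooled[0] - 2.5, pooled[0] + 2.5, 801)
        g2 = np.linspace(pooled[1] - 2.5, pooled[1] + 2.5, 801)
        T1, T2 = np.meshgrid(g1, g2, indexing="ij")
        theta = np.stack([T1.ravel(), T2.ravel()], axis=1)
        pq = mvn.pdf(theta, yq, W / nq)
        pr = mvn.pdf(theta, yr, W / nr)
        num = np.mean(
            [
                simpson(simpson((pq * pr * mvn.pdf(theta, mu, C)).reshape(T1.shape), x=g2, axis=1), x=g1)
                for mu in mus
            ]
        )
        dq = np.mean([mvn.pdf(yq, mu, C + W / nq) for mu in mus])
        dr = np.mean([mvn.pdf(yr, mu, C + W / nr) for mu in mus])
        expected = np.log10(num / (dq * dr))
        mine = model.score_means(yq[None, :], yr[None, :], nq, nr)[0]
        assert mine == pytest.approx(expected, rel=1e-6)

    def test_single_gaussian_limit_matches_closed_form(self):
        # three identical kernel centres make the between-speaker mixture one
        # Gaussian, reproducing the closed-form normal two-level LR
        mu = np.array([1.0, -0.5])
        Sigma_b = np.array([[2.0, 0.3], [0.3, 1.5]])
        W = np.array([[1.0, 0.2], [0.2, 0.8]])
        model = MVKDScorer()
        model.speaker_means_ = np.vstack([mu, mu, mu])
        model.within_covariance_ = W
        model.n_speakers_ = 3
        model.n_features_in_ = 2
        model.bandwidth_ = reference_bandwidth(2, 3)
        model.between_covariance_ = Sigma_b / model.bandwidth_**2  # C = Sigma_b

        yq, yr, nq, nr = np.array([1.5, 0.0]), np.array([1.2, -0.2]), 4, 6
        w = (nq * yq + nr * yr) / (nq + nr)
        num = mvn.pdf(yq - yr, np.zeros(2), W / nq + W / nr) * mvn.pdf(
            w, mu, Sigma_b + W / (nq + nr)
        )
        den = mvn.pdf(yq, mu, Sigma_b + W / nq) * mvn.pdf(yr, mu, Sigma_b + W / nr)
        expected = np.log10(num / den)
        mine = model.score_means(yq[None, :], yr[None, :], nq, nr)[0]
        assert mine == pytest.approx(expected, abs=1e-3)


class TestScoreBehaviour:
    def test_identical_samples_far_from_background_support_same_origin(self, rng):
        samples = [rng.normal(m, 1.0, size=(5, 1)) for m in (0.0, 1.0, 2.0)]
        model = MVKDScorer().fit(samples)
        tokens = rng.normal(30.0, 1.0, size=(4, 1))  # >= 10 pooled sd away
        assert model.score_pair(tokens, tokens.copy()) > 0

    def test_displaced_typical_samples_support_different_origin(self, rng):
        samples = [rng.normal(m, 1.0, size=(20, 1)) for m in (-5.0, 0.0, 5.0)]
        model = MVKDScorer().fit(samples)
        q = rng.normal(-5.0, 1.0, size=(10, 1))
        r = rng.normal(5.0, 1.0, size=(10, 1))
        assert model.score_pair(q, r) < 0

    def test_monotone_in_mean_separation(self):
        c = 1 / np.sqrt(2)
        samples = [np.array([[m - c], [m + c]]) for m in (-10.0, 0.0, 10.0)]
        model = MVKDScorer().fit(samples)
        deltas = np.linspace(0.0, 4.0, 17)
        scores = [
            model.score_means([[d / 2]], [[-d / 2]], 2, 2)[0] for d in deltas
        ]
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_scores_clamped_to_symmetric_bound(self, rng):
        samples = [rng.normal(m, 1.0, size=(50, 1)) for m in (0.0, 1.0, 2.0)]
        model = MVKDScorer(clamp=10.0).fit(samples)
        llr = model.score_means([[0.0]], [[500.0]], 50, 50)[0]
        assert llr == -10.0

    def test_hs_scores_exceed_hd_scores_on_average(self, rng):
        spk_means = rng.normal(0.0, 3.0, size=10)
        data = {i: rng.normal(m, 1.0, size=(12, 1)) for i, m in enumerate(spk_means)}
        model = MVKDScorer().fit([data[i] for i in range(3, 10)])
        hs = [model.score_pair(data[i][:6], data[i][6:]) for i in range(3)]
        hd = [model.score_pair(data[i][:6], data[j][6:]) for i in range(3) for j in range(3) if i != j]
        assert np.mean(hs) > np.mean(hd)

    def test_dimension_mismatch_rejected(self, rng):
        model = MVKDScorer().fit([rng.normal(size=(4, 2)) + m for m in (0, 1, 2)])
        with pytest.raises(ValueError, match="dimension"):
            model.score_pair(rng.normal(size=(3, 1)), rng.normal(size=(3, 2)))

    def test_comparison_sample_validation(self):
        with pytest.raises(ValueError, match="2 tokens"):
            ComparisonSample("s", "a", np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="finite"):
            ComparisonSample("s", "a", np.array([[1.0], [np.nan]]))
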