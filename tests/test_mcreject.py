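import numpy as np
import pytest

from biosimgen import (Alphabet, FamilySpec, FeatureMatrix, FeatureSpec,
                       RejectionCriteria, filter_candidates,
                       fit_blueprint_model, ks_distance, mahalanobis_d2,
                       make_correlated_features, make_sequence_family,
                       quantile_bounds, simulate_sequences_with_features,
                       MarginalSpec, extract_features)


def _mvn(n, seed, rho=0.3, p=3):
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    return make_correlated_features(
        n, R, [MarginalSpec("normal", (0, 1))] * p, seed=seed)


class TestQuantileBounds:
    def test_q_zero_gives_min_max(self):
        fm = _mvn(100, seed=1)
        b = quantile_bounds(fm, 0.0)
        np.testing.assert_array_equal(b[:, 0], fm.values.min(axis=0))
        np.testing.assert_array_equal(b[:, 1], fm.values.max(axis=0))

    def test_interpolation_oracle(self):
        fm = FeatureMatrix([f"r{i}" for i in range(100)], ["x"],
                           np.arange(1.0, 101.0)[:, None])
        b = quantile_bounds(fm, 0.05)
        # linear-interpolation quantile: index 0.05*99 = 4.95 -> 5.95
        assert b[0, 0] == pytest.approx(5.95)
        assert b[0, 1] == pytest.approx(95.05)

    def test_constant_feature(self):
        fm = FeatureMatrix([f"r{i}" for i in range(10)], ["x"],
                           np.full((10, 1), 3.0))
        b = quantile_bounds(fm, 0.1)
        assert b[0, 0] == b[0, 1] == 3.0

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            quantile_bounds(_mvn(20, seed=2), 0.5)


class TestMahalanobisD2:
    def test_center_is_zero(self):
        assert mahalanobis_d2([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_univariate_reduces_to_z_squared(self):
        assert mahalanobis_d2([5.0], [3.0], [[4.0]]) == pytest.approx(1.0)

    def test_hand_matrix_oracle(self):
        d2 = mahalanobis_d2([1.0, 2.0], [0.0, 0.0], [[1.0, 0.0], [0.0, 4.0]])
        assert d2 == pytest.approx(2.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mahalanobis_d2([1.0], [1.0, 2.0], np.eye(2))


class TestFilterCandidates:
    def test_chi_square_calibration(self):
        original = _mvn(5000, seed=3)
        candidates = _mvn(10_000, seed=4)
        criteria = RejectionCriteria(quantile_q=0.0, mahalanobis_alpha=0.025)
        _, report = filter_candidates(candidates, original, criteria)
        assert report.acceptance_rate == pytest.approx(0.975, abs=0.01)

    def test_quantile_acceptance_independent_features(self):
        """(1-2q)^p acceptance under the matched null with independent features."""
        original = _mvn(20_000, seed=5, rho=0.0)
        candidates = _mvn(10_000, seed=6, rho=0.0)
        criteria = RejectionCriteria(quantile_q=0.05, mahalanobis_alpha=1e-12)
        _, report = filter_candidates(candidates, original, criteria)
        assert report.acceptance_rate == pytest.approx(0.9 ** 3, abs=0.02)

    def test_mean_always_accepted(self):
        original = _mvn(1000, seed=7)
        mean_row = FeatureMatrix(["m"], list(original.feature_names),
                                 original.values.mean(axis=0)[None, :])
        mask, _ = filter_candidates(mean_row, original,
                                    RejectionCriteria(0.05, 0.025))
        assert mask[0]

    def test_gross_outlier_rejected_by_quantile(self):
        original = _mvn(1000, seed=8)
        out = original.values.mean(axis=0).copy()
        out[0] += 10 * original.values[:, 0].std()
        row = FeatureMatrix(["o"], list(original.feature_names), out[None, :])
        mask, report = filter_candidates(row, original,
                                         RejectionCriteria(0.05, 0.5))
        assert not mask[0]
        assert report.n_rejected_quantile == 1

    def test_counts_conserve(self):
        original = _mvn(2000, seed=9)
        candidates = _mvn(5000, seed=10)
        _, r = filter_candidates(candidates, original,
                                 RejectionCriteria(0.05, 0.1))
        assert r.n_generated == r.n_accepted + r.n_rejected_quantile \
            + r.n_rejected_mahalanobis

    def test_monotone_under_tightening(self):
        original = _mvn(2000, seed=11)
        candidates = _mvn(3000, seed=12)
        prev = None
        for q, alpha in [(0.0, 0.01), (0.02, 0.05), (0.1, 0.2)]:
            mask, _ = filter_candidates(candidates, original,
                                        RejectionCriteria(q, alpha))
            if prev is not None:
                assert np.all(mask <= prev)  # tightened set is a subset
            prev = mask

    def test_name_mismatch(self):
        a = _mvn(100, seed=13)
        b = FeatureMatrix(a.row_ids, ["x", "y", "z"], a.values)
        with pytest.raises(ValueError, match="mismatch"):
            filter_candidates(b, a, RejectionCriteria())


class TestSequenceDrivenLoop:
    @pytest.fixture(scope="class")
    def family(self):
        return make_sequence_family(FamilySpec(
            Alphabet.DNA, 60, "lognormal", (5.0, 0.2),
            concentration=(8, 8, 8, 8), seed=21))

    @pytest.fixture(scope="class")
    def spec(self):
        return FeatureSpec.parse(["dinuc:twist,roll,free_energy", "gc"])

    def test_disabled_filters_accept_everything(self, family, spec):
        model = fit_blueprint_model(family)
        criteria = RejectionCriteria(quantile_q=0.0, mahalanobis_alpha=1e-12)
        seqs, feats, report = simulate_sequences_with_features(
            model, spec, family, criteria, 300, np.random.default_rng(22))
        assert len(seqs) == 300
        assert report.iterations == 1
        assert report.n_rejected_quantile == report.n_rejected_mahalanobis == 0

    def test_accepted_set_tracks_original_features(self, family, spec):
        model = fit_blueprint_model(family)
        criteria = RejectionCriteria(quantile_q=0.025, mahalanobis_alpha=0.025)
        seqs, feats, report = simulate_sequences_with_features(
            model, spec, family, criteria, 400, np.random.default_rng(23),
            max_rounds=10)
        original = extract_features(family, spec)
        for j in range(original.p):
            assert ks_distance(original.values[:, j], feats.values[:, j]) < 0.2

    def test_impossible_criteria_shortfall(self, family, spec):
        model = fit_blueprint_model(family)
        criteria = RejectionCriteria(quantile_q=0.49, mahalanobis_alpha=1e-9)
        with pytest.raises(RuntimeError, match="zero acceptance"):
            simulate_sequences_with_features(
                model, spec, family, criteria, 100,
                np.random.default_rng(24), max_rounds=2, batch_size=50)

    def test_report_counts_and_features_align(self, family, spec):
        model = fit_blueprint_model(family)
        criteria = RejectionCriteria(quantile_q=0.05, mahalanobis_alpha=0.05)
        seqs, feats, report = simulate_sequences_with_features(
            model, spec, family, criteria, 150, np.random.default_rng(25),
            max_rounds=5)
        assert len(seqs) == feats.n
        assert report.n_accepted >= len(seqs)
        assert report.n_generated == report.n_accepted \
            + report.n_rejected_quantile + report.n_rejected_mahalanobis
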