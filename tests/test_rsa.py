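import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actionrep.rsa import (DissimilarityMatrix, bootstrap_rsa,
                           dissimilarity_matrix, noise_ceiling, noise_floor,
                           normalize_score, oracle_matrix, rsa_significance,
                           spearman_lower)
from actionrep.synthetic import generate_neural_responses


def brute_force_spearman(a, b):
    """Average-rank Spearman oracle: rank by sorting, then Pearson formula."""

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    ra, rb = ranks(np.asarray(a, float)), ranks(np.asarray(b, float))
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


class TestDissimilarityMatrix:
    def test_duplicated_stimuli_have_zero_dissimilarity(self):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((5, 8))
        F[3] = F[0]
        D = dissimilarity_matrix(F)
        assert D.values[0, 3] == 0.0

    def test_anticorrelated_pair_is_the_off_diagonal_maximum(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(10)
        F = np.vstack([v, -v, rng.standard_normal((3, 10))])
        D = dissimilarity_matrix(F)
        assert D.values[0, 1] == pytest.approx(1.0)
        assert D.norm_record[1] == pytest.approx(2.0)  # pre-normalization 1-(-1)

    def test_matches_hand_computed_pearson_table(self):
        F = np.array([[1.0, 2.0, 4.0],
                      [0.0, 1.0, 1.0],
                      [5.0, 1.0, 0.0],
                      [2.0, 2.0, 3.0]])
        raw = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                a, b = F[i] - F[i].mean(), F[j] - F[j].mean()
                raw[i, j] = 1 - (a @ b) / np.sqrt((a @ a) * (b @ b))
        off = ~np.eye(4, dtype=bool)
        expect = raw.copy()
        expect[off] = (raw[off] - raw[off].min()) / (raw[off].max() - raw[off].min())
        np.fill_diagonal(expect, 0.0)
        D = dissimilarity_matrix(F)
        assert np.abs(D.values - expect).max() < 1e-10

    def test_constant_row_rejected_with_stimulus_id(self):
        F = np.ones((4, 5))
        F[0] = np.arange(5)
        with pytest.raises(ValueError, match="undefined"):
            dissimilarity_matrix(F)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariants_on_random_feature_matrices(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((int(rng.integers(3, 9)), int(rng.integers(2, 7))))
        D = dissimilarity_matrix(F)
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)
        assert D.values.min() >= 0 and D.values.max() <= 1

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 0.2], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(bad)


class TestOracleMatrix:
    def test_five_actions_ten_clips_lower_triangle_zero_count(self):
        labels = np.repeat(np.arange(5), 10)
        D = oracle_matrix(labels)
        lower = D.lower()
        assert len(lower) == 1225  # C(50, 2)
        assert int((lower == 0).sum()) == 225  # 5 * C(10, 2)

    def test_degenerate_label_sets(self):
        assert np.all(oracle_matrix([1, 1, 1]).values == 0)
        allneq = oracle_matrix([0, 1, 2]).values
        assert np.all(allneq[~np.eye(3, dtype=bool)] == 1)


class TestSpearmanLower:
    def test_self_comparison_is_one(self):
        D = dissimilarity_matrix(np.random.default_rng(2).standard_normal((6, 5)))
        assert spearman_lower(D, D) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        D = dissimilarity_matrix(np.random.default_rng(3).standard_normal((6, 5)))
        cubed = DissimilarityMatrix(D.values**3, manifest=D.manifest)
        assert spearman_lower(D, cubed) == pytest.approx(1.0)

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(4)
        for n in (4, 5, 8):
            for _ in range(5):
                A = dissimilarity_matrix(rng.standard_normal((n, 6)))
                B = dissimilarity_matrix(rng.standard_normal((n, 6)))
                assert spearman_lower(A, B) == pytest.approx(
                    brute_force_spearman(A.lower(), B.lower()), abs=1e-10)

    def test_manifest_mismatch_rejected(self):
        A = dissimilarity_matrix(np.random.default_rng(5).standard_normal((4, 5)),
                                 manifest=(0, 1, 2, 3))
        B = dissimilarity_matrix(np.random.default_rng(6).standard_normal((4, 5)),
                                 manifest=(0, 1, 2, 9))
        with pytest.raises(ValueError, match="manifest"):
            spearman_lower(A, B)


class TestBootstrap:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(7)
        A = dissimilarity_matrix(rng.standard_normal((10, 6)))
        B = dissimilarity_matrix(rng.standard_normal((10, 6)))
        return A, B

    def test_full_subset_reproduces_the_full_matrix_score(self, pair):
        A, B = pair
        samples = bootstrap_rsa(A, B, rounds=5, subset=10, seed=0)
        assert np.allclose(samples, spearman_lower(A, B))

    def test_identical_matrices_give_unit_samples(self, pair):
        A, _ = pair
        assert np.allclose(bootstrap_rsa(A, A, rounds=8, subset=6, seed=1), 1.0)

    def test_seed_determinism_and_bad_subsets(self, pair):
        A, B = pair
        assert np.array_equal(bootstrap_rsa(A, B, 10, 6, seed=3),
                              bootstrap_rsa(A, B, 10, 6, seed=3))
        with pytest.raises(ValueError, match="subset"):
            bootstrap_rsa(A, B, 10, 2, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_rsa(A, B, 10, 11, seed=0)


class TestNoiseEstimates:
    def test_identical_subjects_reach_unit_ceiling(self, small_index):
        recset = generate_neural_responses(small_index, n_subjects=2, n_sensors=16,
                                           action_w=1.0, view_w=0.3, actor_w=0.2,
                                           noise_sd=0.0, seed=0)
        n = len(small_index)
        assert noise_ceiling(recset, rounds=1, subset=n, seed=0) == pytest.approx(1.0)
        assert noise_ceiling(recset, rounds=10, seed=0) == pytest.approx(1.0)

    def test_ceiling_decreases_with_subject_noise(self, small_index):
        """Noisier subjects agree less with each other (trend over 3 seeds)."""
        means = {}
        for sd in (0.0, 2.0):
            vals = [noise_ceiling(
                generate_neural_responses(small_index, 4, 32, 1.0, 0.3, 0.2,
                                          noise_sd=sd, seed=s),
                rounds=10, seed=s) for s in range(3)]
            means[sd] = np.mean(vals)
        assert means[0.0] >= means[2.0]

    def test_floor_bounds_and_determinism(self):
        rng = np.random.default_rng(8)
        models = [dissimilarity_matrix(rng.standard_normal((8, 6))) for _ in range(2)]
        D_n = dissimilarity_matrix(rng.standard_normal((8, 6)))
        f1 = noise_floor(models, D_n, rounds=20, seed=5)
        f2 = noise_floor(models, D_n, rounds=20, seed=5)
        assert f1 == f2
        assert f1 >= noise_floor(models[:1], D_n, rounds=1, seed=5)

    def test_scrambled_scores_center_on_zero(self):
        """Per-round scrambled SCCs average to ~0 (null construction)."""
        rng = np.random.default_rng(9)
        D_m = dissimilarity_matrix(rng.standard_normal((12, 8)))
        D_n = dissimilarity_matrix(rng.standard_normal((12, 8)))
        scores = []
        for _ in range(60):
            perm = rng.permutation(12)
            D_s = DissimilarityMatrix(D_n.values[np.ix_(perm, perm)],
                                      manifest=D_n.manifest)
            scores.append(spearman_lower(D_m, D_s))
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores)) < 3 * se + 0.02


class TestNormalization:
    def test_endpoint_and_midpoint_arithmetic(self):
        assert normalize_score(0.9, 0.1, 0.9) == (1.0, False)
        assert normalize_score(0.1, 0.1, 0.9) == (0.0, False)
        score, flag = normalize_score(0.5, 0.1, 0.9)
        assert score == pytest.approx(0.5) and flag is False

    def test_out_of_range_flagged_and_degenerate_rejected(self):
        score, flag = normalize_score(1.2, 0.0, 1.0)
        assert flag is True and score == pytest.approx(1.2)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_score(0.5, 0.8, 0.8)


class TestRSASignificance:
    def test_trivial_paths_and_bonferroni(self):
        base = np.linspace(0.2, 0.4, 10)
        samples = {"m1": base, "m2": base.copy(), "m3": base + 0.3,
                   "m4": base + 0.31}
        rep = rsa_significance(samples, learned_models=("m4",))
        assert rep["bonferroni_factor"] == 6
        assert rep["pairwise"]["m1 vs m2"]["significant"] is False
        assert rep["pairwise"]["m1 vs m3"]["significant"] is True
        assert rep["group_anova"]["significant"] is True

    def test_unpaired_samples_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            rsa_significance({"a": np.zeros(5), "b": np.zeros(6)})
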