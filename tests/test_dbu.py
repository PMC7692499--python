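import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import DBSCAN

from gliotype.dbu import (
    AMBIGUOUS,
    DBUParams,
    IterationLabeling,
    align_iteration_labels,
    canonicalize_labels,
    choose_reference,
    consensus_call,
    filter_iterations,
    run_dbu_iteration,
    select_eps_knee,
    subcluster_group,
)
from gliotype.io_preprocess import ExpressionMatrix

from conftest import two_blob_expr


def make_iteration(labels, iteration_id=0):
    labels = np.asarray(labels, dtype=int)
    return IterationLabeling(
        iteration_id=iteration_id,
        sampled_gene_ids=[],
        labels=labels,
        sample_ids=[f"S{i}" for i in range(len(labels))],
    )


class TestIteration:
    def test_two_blobs_recovered_without_noise(self):
        expr, membership = two_blob_expr()
        params = DBUParams(
            n_iterations=1, genes_per_iteration=60, min_points=20, eps="auto", seed=0
        )
        it = run_dbu_iteration(expr, params, iteration_seed=123)
        assert it.n_clusters == 2
        assert (it.labels == 0).sum() <= 3
        mask = it.labels != 0
        # each blob maps to a single cluster
        table = pd.crosstab(membership[mask], it.labels[mask]).to_numpy()
        assert (table > 0).sum() == 2

    def test_identical_samples_form_at_most_one_cluster(self):
        data = pd.DataFrame(
            np.zeros((30, 120)),
            index=[f"G{i}" for i in range(30)],
            columns=[f"S{j}" for j in range(120)],
        )
        expr = ExpressionMatrix(data, standardized=True)
        params = DBUParams(genes_per_iteration=30, min_points=10, eps="auto")
        it = run_dbu_iteration(expr, params, iteration_seed=5)
        assert it.n_clusters <= 1

    def test_fixed_seed_is_deterministic(self):
        expr, _ = two_blob_expr(n_per_blob=60)
        params = DBUParams(genes_per_iteration=60, min_points=15, eps="auto")
        a = run_dbu_iteration(expr, params, iteration_seed=42)
        b = run_dbu_iteration(expr, params, iteration_seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.sampled_gene_ids == b.sampled_gene_ids

    def test_numeric_eps_bypasses_knee_search(self, monkeypatch):
        expr, _ = two_blob_expr(n_per_blob=60)

        def boom(*a, **k):  # pragma: no cover
            raise AssertionError("knee search should not run for numeric eps")

        monkeypatch.setattr("gliotype.dbu.select_eps_knee", boom)
        params = DBUParams(genes_per_iteration=60, min_points=15, eps=1.55)
        run_dbu_iteration(expr, params, iteration_seed=7)

    def test_requesting_too_many_genes_errors(self):
        expr, _ = two_blob_expr(n_genes=40, n_per_blob=30)
        params = DBUParams(genes_per_iteration=100, min_points=5)
        with pytest.raises(ValueError, match="genes_per_iteration"):
            run_dbu_iteration(expr, params, iteration_seed=1)

    def test_unstandardized_input_rejected(self, random_expr):
        params = DBUParams(genes_per_iteration=10, min_points=3)
        with pytest.raises(ValueError, match="standardized"):
            run_dbu_iteration(random_expr, params, iteration_seed=1)


class TestEpsKnee:
    def test_knee_lands_in_two_cluster_plateau(self):
        rng = np.random.default_rng(0)
        blob_a = rng.normal(0, 0.1, size=(100, 2))
        blob_b = rng.normal(10, 0.1, size=(100, 2))
        emb = np.vstack([blob_a, blob_b])
        eps = select_eps_knee(emb, k=10)
        assert eps < 10  # must not bridge the blobs
        labels = DBSCAN(eps=eps, min_samples=10).fit_predict(emb)
        assert len(set(labels) - {-1}) == 2
        assert (labels == -1).mean() <= 0.1
        # grid scan: the returned eps sits inside the two-cluster plateau
        plateau = [
            e for e in np.geomspace(0.02, 12, 40)
            if len(set(DBSCAN(eps=e, min_samples=10).fit_predict(emb)) - {-1}) == 2
        ]
        assert min(plateau) <= eps <= max(plateau)

    def test_uniform_points_within_curve_range(self):
        rng = np.random.default_rng(1)
        emb = rng.uniform(size=(200, 2))
        from sklearn.neighbors import NearestNeighbors

        dk = np.sort(NearestNeighbors(n_neighbors=11).fit(emb).kneighbors(emb)[0][:, -1])
        eps = select_eps_knee(emb, k=10)
        assert dk[0] <= eps <= dk[-1]

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least"):
            select_eps_knee(np.zeros((5, 2)), k=10)


class TestFilterIterations:
    def test_counts_and_explicit_expectation(self):
        its = [make_iteration([1, 2, 3] if i < 8 else [1, 2, 0]) for i in range(10)]
        retained, expected = filter_iterations(its, 3)
        assert expected == 3
        assert len(retained) == 8

    def test_auto_resolves_to_mode(self):
        its = [make_iteration([1, 2, 3] if i < 8 else [1, 2, 0]) for i in range(10)]
        _, expected = filter_iterations(its, "auto")
        assert expected == 3

    def test_all_removed_errors(self):
        its = [make_iteration([1, 2, 0])]
        with pytest.raises(ValueError, match="all iterations removed"):
            filter_iterations(its, 3)


class TestAlignment:
    def test_permuted_copy_recovers_reference(self):
        rng = np.random.default_rng(2)
        ref = make_iteration(rng.integers(1, 4, size=60))
        perm = {1: 3, 2: 1, 3: 2}
        permuted = make_iteration([perm[v] for v in ref.labels])
        aligned = align_iteration_labels([permuted], ref)
        np.testing.assert_array_equal(aligned[0].labels, ref.labels)

    def test_identity_mapping_for_identical_iteration(self):
        ref = make_iteration([1, 1, 2, 2, 3, 3])
        aligned = align_iteration_labels([make_iteration([1, 1, 2, 2, 3, 3])], ref)
        np.testing.assert_array_equal(aligned[0].labels, ref.labels)

    def test_noise_label_never_remapped(self):
        ref = make_iteration([1, 1, 2, 2, 0, 0])
        it = make_iteration([2, 2, 1, 1, 0, 1])
        aligned = align_iteration_labels([it], ref)
        assert aligned[0].labels[4] == 0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_permutation_search(self, trial):
        rng = np.random.default_rng(trial)
        k = 4
        ref = make_iteration(rng.integers(1, k + 1, size=60))
        it = make_iteration(rng.integers(1, k + 1, size=60))
        aligned = align_iteration_labels([it], ref)[0]
        achieved = int(np.sum(aligned.labels == ref.labels))
        best = max(
            int(np.sum(np.array([perm[v - 1] for v in it.labels]) == ref.labels))
            for perm in itertools.permutations(range(1, k + 1))
        )
        assert achieved == best

    def test_mismatched_cluster_count_excluded(self):
        ref = make_iteration([1, 1, 2, 2, 3, 3])
        two = make_iteration([1, 1, 1, 2, 2, 2])
        aligned = align_iteration_labels([two, make_iteration([1, 1, 2, 2, 3, 3])], ref)
        assert len(aligned) == 1


class TestConsensus:
    def test_exact_threshold_fraction_is_assigned(self):
        # 7 of 10 iterations vote cluster 1: exactly 70% passes
        its = [make_iteration([1]) for _ in range(7)] + [make_iteration([2]) for _ in range(3)]
        calls = consensus_call(its, threshold=0.70)
        assert calls.labels.iloc[0] == "1"
        assert calls.calls["vote_fraction"].iloc[0] == pytest.approx(0.7)

    def test_noise_majority_is_ambiguous(self):
        its = [make_iteration([0]) for _ in range(6)] + [make_iteration([1]) for _ in range(4)]
        calls = consensus_call(its, threshold=0.40)
        assert calls.labels.iloc[0] == AMBIGUOUS

    def test_unanimous_vote(self):
        its = [make_iteration([2, 1]) for _ in range(5)]
        calls = consensus_call(its, threshold=0.70)
        assert calls.labels.tolist() == ["2", "1"]
        assert (calls.calls["vote_fraction"] == 1.0).all()

    def test_vote_rows_plus_noise_sum_to_one(self):
        rng = np.random.default_rng(3)
        its = [make_iteration(rng.integers(0, 4, size=40)) for _ in range(20)]
        calls = consensus_call(its)
        np.testing.assert_allclose(calls.votes.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_iterations_error(self):
        with pytest.raises(ValueError, match="empty"):
            consensus_call([])

    @pytest.mark.parametrize("trial", range(20))
    def test_consensus_invariant_to_label_permutations(self, trial):
        rng = np.random.default_rng(100 + trial)
        base = [make_iteration(rng.integers(0, 4, size=50), i) for i in range(12)]

        def pipeline(iterations):
            retained, _ = filter_iterations(iterations, "auto")
            ref = canonicalize_labels(retained[choose_reference(retained)])
            return consensus_call(align_iteration_labels(retained, ref))

        original = pipeline(base)
        permuted = []
        for it in base:
            perm = rng.permutation([1, 2, 3])
            mapping = {0: 0, 1: int(perm[0]), 2: int(perm[1]), 3: int(perm[2])}
            permuted.append(
                make_iteration([mapping[v] for v in it.labels], it.iteration_id)
            )
        shuffled = pipeline(permuted)
        pd.testing.assert_frame_equal(original.calls, shuffled.calls)
        pd.testing.assert_frame_equal(original.votes, shuffled.votes)


class TestSubcluster:
    def test_homogeneous_group_not_split(self):
        expr, _ = two_blob_expr(n_per_blob=100, n_genes=80, seed=4)
        calls = consensus_call(
            [make_iteration([1] * 100 + [2] * 100) for _ in range(5)]
        )
        # fix sample ids to match the expression matrix
        for frame in (calls.calls, calls.votes):
            frame.index = pd.Index(expr.sample_ids, name="sample_id")
        params = DBUParams(
            n_iterations=10, genes_per_iteration=80, min_points=40, eps="auto", seed=2
        )
        result = subcluster_group(expr, calls, "1", params)
        assert not result.split
        assert set(result.calls.labels) == {"1"}

    def test_too_small_group_errors(self):
        expr, _ = two_blob_expr(n_per_blob=10, n_genes=30)
        calls = consensus_call([make_iteration([1] * 10 + [2] * 10)])
        for frame in (calls.calls, calls.votes):
            frame.index = pd.Index(expr.sample_ids, name="sample_id")
        params = DBUParams(n_iterations=2, genes_per_iteration=30, min_points=100)
        with pytest.raises(ValueError, match="need at least"):
            subcluster_group(expr, calls, "1", params)
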