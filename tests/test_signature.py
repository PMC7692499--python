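import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import gliotype.signature as sig
from gliotype.io_preprocess import ExpressionMatrix
from gliotype.signature import (
    ModelDictionary,
    Signature,
    build_model_dictionary,
    build_signature,
    cv_filter_models,
    one_vs_rest_de,
    partition_gene_groups,
    rfe_select,
)


def labeled_expr(n_per_class=30, n_genes=25, n_classes=3, n_signal=3, seed=0, signal=3.0):
    """Expression with ``n_signal`` genes carrying all the class signal."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    x = rng.normal(size=(n_genes, n))
    y = np.repeat([f"C{k}" for k in range(n_classes)], n_per_class)
    for g in range(n_signal):
        for k in range(n_classes):
            x[g, y == f"C{k}"] += signal * np.cos(2 * np.pi * (g + k) / n_classes)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    em = ExpressionMatrix(
        pd.DataFrame(x, index=[f"G{i}" for i in range(n_genes)],
                     columns=[f"S{j}" for j in range(n)]),
        standardized=True,
    )
    return em, pd.Series(y, index=em.sample_ids)


class TestOneVsRestDE:
    def test_constant_gene_is_null(self):
        em, y = labeled_expr()
        em.data.iloc[-1] = 0.0  # identical values everywhere
        de = one_vs_rest_de(em, y)
        row = de[(de["gene"] == em.gene_ids[-1])]
        assert (row["statistic"] == 0).all()
        assert (row["p"] == 1).all()

    def test_informative_genes_detected(self, small_cohort):
        de = one_vs_rest_de(small_cohort.expression, small_cohort.true_subtype)
        hits = de[(de["gene"].isin(small_cohort.informative_gene_ids)) & (de["adj_p"] < 0.05)]
        frac = hits["gene"].nunique() / len(small_cohort.informative_gene_ids)
        assert frac >= 0.9

    def test_adjusted_p_never_below_raw(self, small_cohort):
        de = one_vs_rest_de(small_cohort.expression, small_cohort.true_subtype)
        assert (de["adj_p"] >= de["p"] - 1e-15).all()
        assert (de["adj_p"] <= 1).all()

    def test_tiny_group_skipped(self):
        em, y = labeled_expr()
        y.iloc[:2] = "rare"
        y = y[lambda s: (s != "C0") | (s.index.isin(s.index[:70]))]
        de = one_vs_rest_de(em, y)
        assert "rare" not in set(de["group"])


class TestPartitionGeneGroups:
    def make_archetypes(self, n_per=10, noise=0.01):
        rng = np.random.default_rng(1)
        subtypes = ["A", "B", "C", "D"]
        n_samples_per = 20
        y = pd.Series(
            np.repeat(subtypes, n_samples_per),
            index=[f"S{j}" for j in range(4 * n_samples_per)],
        )
        archetypes = np.array([
            [3, 0, 0, 0], [0, 3, 0, 0], [0, 0, 3, 0],
            [0, 0, 0, 3], [3, 3, 0, 0], [0, 0, 3, 3],
        ])
        genes, rows = [], []
        for a, proto in enumerate(archetypes):
            for i in range(n_per):
                profile = np.repeat(proto, n_samples_per).astype(float)
                rows.append(profile + rng.normal(0, noise, size=len(profile)))
                genes.append(f"A{a}_{i}")
        em = ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=y.index), standardized=True
        )
        return em, y, [g.split("_")[0] for g in genes]

    def test_archetypes_recovered_exactly(self):
        em, y, truth = self.make_archetypes()
        groups = partition_gene_groups(em, y, em.gene_ids, n_groups=6, seed=0)
        assigned = [groups[g] for g in em.gene_ids]
        assert adjusted_rand_score(truth, assigned) == 1.0

    def test_identical_profiles_share_a_group(self):
        em, y, _ = self.make_archetypes(noise=0.0)
        groups = partition_gene_groups(em, y, ["A0_0", "A0_1"], n_groups=2, seed=0)
        assert groups["A0_0"] == groups["A0_1"]

    def test_level_shift_does_not_change_group(self):
        em, y, _ = self.make_archetypes(noise=0.0)
        shifted = em.data.copy()
        shifted.loc["A2_0"] = shifted.loc["A2_1"] + 7.5  # same pattern, higher level
        em2 = ExpressionMatrix(shifted, standardized=True)
        groups = partition_gene_groups(em2, y, em2.gene_ids, n_groups=6, seed=0)
        assert groups["A2_0"] == groups["A2_1"]

    def test_fewer_genes_than_groups_errors(self):
        em, y, _ = self.make_archetypes()
        with pytest.raises(ValueError, match="cannot form"):
            partition_gene_groups(em, y, em.gene_ids[:3], n_groups=6)


class TestRFE:
    def test_planted_signal_recovered(self):
        em, y = labeled_expr(n_genes=20, n_signal=3, seed=2)
        selected = rfe_select(em, y, em.gene_ids, step=5, seed=0)
        assert {"G0", "G1", "G2"} <= set(selected)

    def test_n_keep_returns_exact_size(self):
        em, y = labeled_expr(n_genes=40, n_signal=3, seed=3)
        selected = rfe_select(em, y, em.gene_ids, step=5, seed=0, n_keep=12)
        assert len(selected) == 12
        assert {"G0", "G1", "G2"} <= set(selected)

    def test_empty_candidates_error(self):
        em, y = labeled_expr()
        with pytest.raises(ValueError, match="empty"):
            rfe_select(em, y, [])


class TestDictionary:
    def test_half_sampling_pool_size(self, monkeypatch):
        # six groups of 28 genes -> each model's pre-RFE pool has 84 genes
        genes = [f"G{i}" for i in range(168)]
        signature = Signature(
            gene_ids=genes,
            curated_gene_ids=[],
            selected_gene_ids=genes,
            group_assignment={g: (i % 6) + 1 for i, g in enumerate(genes)},
        )
        pools = []
        monkeypatch.setattr(
            sig, "rfe_select", lambda expr, labels, pool, **kw: pools.append(list(pool)) or list(pool)
        )
        build_model_dictionary(None, pd.Series(dtype=object), signature, n_models=5, seed=0)
        assert [len(p) for p in pools] == [84] * 5
        assert all(len(set(p)) == 84 for p in pools)

    def test_reproducible_from_seed(self):
        em, y = labeled_expr(n_genes=30, n_signal=4, seed=4)
        signature = Signature(
            gene_ids=em.gene_ids,
            curated_gene_ids=[],
            selected_gene_ids=em.gene_ids,
            group_assignment=partition_gene_groups(em, y, em.gene_ids, n_groups=3, seed=0),
        )
        d1 = build_model_dictionary(em, y, signature, n_models=6, seed=9)
        d2 = build_model_dictionary(em, y, signature, n_models=6, seed=9)
        assert d1.entries == d2.entries

    def test_entries_subset_of_signature(self, small_cohort):
        signature = build_signature(
            small_cohort.expression, small_cohort.true_subtype,
            n_select=24, n_groups=6, seed=0,
        )
        d = build_model_dictionary(
            small_cohort.expression, small_cohort.true_subtype, signature,
            n_models=10, seed=1,
        )
        for entry in d.entries:
            assert set(entry) <= set(signature.gene_ids)
        assert len(set(d.entry_sizes)) >= 1
        assert all(size >= 5 for size in d.entry_sizes)


@pytest.fixture(scope="module")
def cohort_dictionary(small_cohort):
    """A small signature + dictionary built from the cohort's true labels."""
    em, y = small_cohort.expression, small_cohort.true_subtype
    signature = build_signature(em, y, n_select=40, n_groups=6, seed=3)
    dictionary = build_model_dictionary(em, y, signature, n_models=8, seed=4)
    return signature, dictionary


class TestCVFilter:
    def test_good_labels_retain_entries(self, small_cohort, cohort_dictionary):
        em, y = small_cohort.expression, small_cohort.true_subtype
        _, dictionary = cohort_dictionary
        filtered = cv_filter_models(dictionary, em, y, floor=0.95, seed=0)
        assert len(filtered) >= 0.75 * len(dictionary)
        assert all(a >= 0.95 for a in filtered.cv_accuracy)

    def test_permuted_labels_drop_everything(self, small_cohort):
        em = small_cohort.expression
        rng = np.random.default_rng(5)
        y = pd.Series(
            rng.permutation(small_cohort.true_subtype.to_numpy()),
            index=small_cohort.true_subtype.index,
        )
        d = ModelDictionary(entries=[small_cohort.informative_gene_ids[:30]] * 3)
        with pytest.raises(ValueError, match="floor"):
            cv_filter_models(d, em, y, floor=0.95, seed=0)

    def test_floor_monotone(self, small_cohort):
        em, y = small_cohort.expression, small_cohort.true_subtype
        entries = [small_cohort.informative_gene_ids[k: k + 12] for k in range(0, 60, 12)]
        low = cv_filter_models(ModelDictionary(entries=entries), em, y, floor=0.5, seed=0)
        high_entries = []
        try:
            high = cv_filter_models(ModelDictionary(entries=entries), em, y, floor=0.97, seed=0)
            high_entries = high.entries
        except ValueError:
            pass
        assert all(e in low.entries for e in high_entries)


class TestSignatureConstruction:
    def test_signature_invariants_and_curated_exemption(self, small_cohort):
        curated = [g for g in small_cohort.expression.gene_ids[:5]
                   if g not in small_cohort.informative_gene_ids][:3]
        signature = build_signature(
            small_cohort.expression, small_cohort.true_subtype,
            n_select=20, curated_genes=curated, n_groups=4, seed=0,
        )
        assert set(signature.curated_gene_ids) == set(curated)
        assert len(signature.selected_gene_ids) == 20
        assert set(signature.gene_ids) == set(curated) | set(signature.selected_gene_ids)
        assert signature.n_groups <= 4

    def test_json_roundtrip(self, small_cohort, tmp_path):
        signature = build_signature(
            small_cohort.expression, small_cohort.true_subtype, n_select=12, n_groups=3, seed=0
        )
        signature.to_json(tmp_path / "sig.json")
        back = Signature.from_json(tmp_path / "sig.json")
        assert back == signature
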