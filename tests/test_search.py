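"""Evolutionary structure search: sampling, moves, oracle equivalence."""

import itertools
import logging

import numpy as np
import pytest

import sigtransfer as st
from sigtransfer.formula import Leaf, Node, fit_parameters
from sigtransfer.search import SearchError, _left_deep, default_gene_pool


def small_config(**kw):
    defaults = dict(population_size=12, generations=3, n_restarts_fit=2, seed=0)
    defaults.update(kw)
    return st.SearchConfig(**defaults)


class TestSampleStructure:
    def test_single_gene_pool_forces_single_leaf(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = st.sample_structure(["g1"], small_config(), rng)
            assert m.features == ["g1"] and m.tree.gene == "g1"

    def test_all_gene_sets_reachable(self):
        """Coupon check: 10,000 draws from 5 genes at <=2 features hit all
        5 singles and all 10 unordered pairs."""
        rng = np.random.default_rng(1)
        pool = [f"g{i}" for i in range(5)]
        cfg = small_config(max_features=2)
        seen = {frozenset(st.sample_structure(pool, cfg, rng).features)
                for _ in range(10_000)}
        singles = {frozenset([g]) for g in pool}
        pairs = {frozenset(p) for p in itertools.combinations(pool, 2)}
        assert singles <= seen and pairs <= seen

    def test_seeded_determinism(self):
        pool = [f"g{i}" for i in range(8)]
        cfg = small_config()
        rng = np.random.default_rng(42)
        seq1 = [st.sample_structure(pool, cfg, rng).structure_key() for _ in range(10)]
        rng = np.random.default_rng(42)
        seq2 = [st.sample_structure(pool, cfg, rng).structure_key() for _ in range(10)]
        assert seq1 == seq2


class TestMutate:
    rates = {"swap_gene": 0.25, "swap_operator": 0.25, "grow": 0.25, "shrink": 0.25}

    def test_shrink_on_single_feature_redraws(self):
        rng = np.random.default_rng(0)
        m = st.FormulaModel(tree=Leaf("g1"))
        for _ in range(30):
            out = st.mutate(m, ["g1", "g2", "g3"], {"shrink": 0.99, "swap_gene": 0.01}, rng)
            # shrink is illegal; the only legal resolution is a gene swap
            assert out.features != ["g1"] or len(out.features) > 1

    def test_swap_operator_on_leaf_redraws(self):
        rng = np.random.default_rng(1)
        m = st.FormulaModel(tree=Leaf("g1"))
        out = st.mutate(m, ["g1", "g2"], {"swap_operator": 0.9, "grow": 0.1}, rng)
        assert len(out.features) == 2  # resolved via grow

    def test_grow_respects_max_features(self):
        rng = np.random.default_rng(2)
        m = _left_deep(["g1", "g2", "g3"], ["add", "add"])
        for _ in range(30):
            out = st.mutate(m, [f"g{i}" for i in range(1, 7)],
                            {"grow": 0.9, "swap_gene": 0.1}, rng, max_features=3)
            assert len(out.features) <= 3

    def test_moves_preserve_invariants(self):
        rng = np.random.default_rng(3)
        pool = [f"g{i}" for i in range(10)]
        m = _left_deep(["g1", "g2"], ["multiply"])
        for _ in range(200):
            m = st.mutate(m, pool, self.rates, rng)
            assert 1 <= len(m.features) <= 3
            assert len(set(m.features)) == len(m.features)


class TestSearch:
    def test_single_feature_search_matches_exhaustive_enumeration(self, mini_slice):
        """At max_features=1 over a 6-gene pool, the search's best model must
        equal the best of fitting every single-gene structure."""
        pool = [f"G{i:04d}" for i in range(1, 7)]
        cfg = st.SearchConfig(population_size=12, generations=3, max_features=1,
                              n_models=6, candidate_gene_pool=pool,
                              n_restarts_fit=3, seed=0)
        result = st.search(mini_slice, cfg)
        best_by_enum, best_loss = None, np.inf
        for g in pool:
            m = st.FormulaModel(tree=Leaf(g))
            fr = fit_parameters(m, mini_slice, n_restarts=6, seed=0, maxiter=300)
            if fr.loss < best_loss:
                best_by_enum, best_loss = g, fr.loss
        assert result[0].model.features == [best_by_enum]
        assert result[0].fit.loss == pytest.approx(best_loss, abs=1e-3)

    def test_two_feature_search_matches_exhaustive_within_tolerance(self, mini_slice):
        """Generous budget, 8-gene pool, <=2 features: top-1 loss within 1e-3
        of brute-force enumeration over all 64 structures."""
        pool = [f"G{i:04d}" for i in range(1, 9)]
        cfg = st.SearchConfig(population_size=100, generations=20, max_features=2,
                              candidate_gene_pool=pool, n_restarts_fit=3, seed=3)
        result = st.search(mini_slice, cfg)
        losses = []
        for g in pool:
            fr = fit_parameters(st.FormulaModel(tree=Leaf(g)), mini_slice,
                                n_restarts=6, seed=0, maxiter=300)
            losses.append(fr.loss)
        for a, b in itertools.combinations(pool, 2):
            for op in ("add", "multiply"):
                m = st.FormulaModel(tree=Node(op, Leaf(a), Leaf(b)))
                fr = fit_parameters(m, mini_slice, n_restarts=6, seed=0, maxiter=300)
                losses.append(fr.loss)
        assert result[0].fit.loss <= min(losses) + 1e-3

    def test_returned_candidates_are_distinct_structures(self, mini_slice):
        result = st.search(mini_slice, small_config(population_size=20, generations=4))
        keys = [c.model.structure_key() for c in result]
        assert len(set(keys)) == len(keys)

    def test_best_loss_non_increasing_across_generations(self, mini_slice, caplog):
        with caplog.at_level(logging.INFO, logger="sigtransfer.search"):
            st.search(mini_slice, small_config(population_size=16, generations=6))
        best = [float(rec.message.split("best loss ")[1].split(" ")[0])
                for rec in caplog.records if "best loss" in rec.message]
        assert len(best) == 6
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_search_is_reproducible_under_seed(self, mini_slice):
        cfg = small_config(population_size=16, generations=3, seed=9)
        a = st.search(mini_slice, cfg)
        b = st.search(mini_slice, cfg)
        assert [c.model.structure_key() for c in a] == [c.model.structure_key() for c in b]
        assert [c.fit.loss for c in a] == [c.fit.loss for c in b]

    def test_single_class_slice_rejected(self, mini_slice):
        import pandas as pd

        sl = st.CellTypeSlice(
            dataset_id="X", cell_type="A", X=np.ones((4, 2)),
            labels=np.zeros(4, dtype=int), gene_ids=pd.Index(["a", "b"]),
        )
        with pytest.raises(SearchError, match="single class"):
            st.search(sl, small_config())

    def test_default_pool_is_top_variance_genes(self, mini_slice):
        pool = default_gene_pool(mini_slice, cap=5)
        assert len(pool) == 5
        X = np.asarray(mini_slice.X.todense())
        variances = dict(zip(map(str, mini_slice.gene_ids), X.var(axis=0)))
        cutoff = sorted(variances.values(), reverse=True)[4]
        assert all(variances[g] >= cutoff for g in pool)

    def test_shuffled_labels_cap_training_pr_auc(self, mini_cohort):
        """Permutation null: with labels detached from expression, even the
        best structure found cannot rank training cells well."""
        from sigtransfer.pipeline import permute_labels

        cohort, _ = mini_cohort
        shuffled = st.normalize_log1p(permute_labels(cohort.datasets[0], seed=0))
        sl = st.slice_cell_type(shuffled, "Goblet Cell")
        result = st.search(sl, small_config(population_size=16, generations=4))
        assert result[0].train_metrics.pr_auc < 0.65
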