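"""Metrics: AUC oracles, the transfer score identity, response surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import sigtransfer as st
from sigtransfer.formula import Leaf, Node
from sigtransfer.metrics import MetricError, pr_curve_points, threshold_metrics


# -- independent brute-force oracles (threshold enumeration / pair counting) --


def brute_force_average_precision(labels, scores):
    """AP = sum over distinct descending thresholds of dRecall * precision."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = np.sum(labels[pred] == 1)
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_force_roc_auc(labels, scores):
    """Concordant-pair fraction with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instances(n_instances=200, max_len=12, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_instances:
        n = int(rng.integers(2, max_len + 1))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        # half the instances use tie-prone discrete scores
        if rng.random() < 0.5:
            s = rng.integers(0, 4, size=n).astype(float) / 3.0
        else:
            s = rng.random(n)
        out.append((y, s))
    return out


class TestRankingMetrics:
    def test_perfect_ranking_gives_one(self):
        assert st.pr_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)

    def test_pr_auc_hand_example(self):
        assert st.pr_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(5 / 6)

    def test_roc_auc_hand_examples(self):
        assert st.roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(3 / 4)
        assert st.roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == 0.0  # anti-ranked
        assert st.roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5  # all tied

    def test_aucs_match_brute_force_oracles(self):
        for y, s in random_instances():
            assert st.pr_auc(y, s) == pytest.approx(
                brute_force_average_precision(y, s), abs=1e-12
            )
            assert st.roc_auc(y, s) == pytest.approx(
                brute_force_roc_auc(y, s), abs=1e-12
            )

    def test_single_class_raises_metric_error(self):
        with pytest.raises(MetricError):
            st.pr_auc([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(MetricError):
            st.roc_auc([0, 0], [0.1, 0.2])

    def test_invariant_under_monotone_transform(self):
        for y, s in random_instances(20, seed=3):
            for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
                assert st.pr_auc(y, f(s)) == pytest.approx(st.pr_auc(y, s), abs=1e-12)
                assert st.roc_auc(y, f(s)) == pytest.approx(st.roc_auc(y, s), abs=1e-12)

    def test_threshold_metrics_handles_empty_predictions(self):
        acc, prec, rec = threshold_metrics([1, 0, 1], [0.1, 0.2, 0.3], threshold=0.5)
        assert acc == pytest.approx(1 / 3)
        assert np.isnan(prec)  # nothing predicted positive
        assert rec == 0.0

    def test_compute_metrics_fields(self):
        rep = st.compute_metrics([1, 0, 1, 0], [0.9, 0.2, 0.8, 0.4])
        assert rep.n_cells == 4 and rep.positive_fraction == 0.5
        assert rep.accuracy == 1.0 and rep.precision == 1.0 and rep.recall == 1.0
        assert rep.pr_auc == pytest.approx(1.0) and rep.roc_auc == pytest.approx(1.0)

    def test_pr_curve_points_exportable(self):
        pts = pr_curve_points([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert pts.shape[1] == 3


class TestTransferScore:
    def test_worked_examples(self):
        assert st.transfer_score(0.7, 0.9) == pytest.approx(0.6)
        assert st.transfer_score(0.8, 0.8) == pytest.approx(0.8)

    @given(a=hst.floats(0, 1), b=hst.floats(0, 1))
    def test_symmetric_and_bounded_by_min(self, a, b):
        s = st.transfer_score(a, b)
        assert s == st.transfer_score(b, a)
        assert s <= min(a, b) + 1e-12
        # algebraic identity: s = min - |delta|/2
        assert s == pytest.approx(min(a, b) - abs(a - b) / 2, abs=1e-12)

    @given(a=hst.floats(0, 1))
    def test_equal_aucs_incur_no_penalty(self, a):
        assert st.transfer_score(a, a) == pytest.approx(a)

    def test_rounding_half_up_to_two_decimals(self):
        assert st.round_half_up(st.transfer_score(0.95, 0.94)) == 0.94
        assert st.round_half_up(0.935) == 0.94
        assert st.round_half_up(0.934999) == 0.93


class TestResponseSurface:
    def test_additive_positive_weight_is_increasing(self, mini_slice):
        m = st.FormulaModel(tree=Node("add", Leaf("G0003", 1.0), Leaf("G0011", 0.5)))
        surf = st.response_surface(m, mini_slice, ["G0003"])
        assert np.all(np.diff(surf.probabilities) > 0)
        assert "G0011" in surf.fixed_values

    def test_multiply_annihilates_on_zero_median_factor(self):
        # fixed feature's median is 0 -> product term vanishes along the grid
        X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 1.0]])
        sl = st.CellTypeSlice(
            dataset_id="T", cell_type="A", X=X,
            labels=np.array([0, 0, 1, 1]), gene_ids=pd.Index(["u", "v"]),
        )
        m = st.FormulaModel(tree=Node("multiply", Leaf("u", 1.0, 0.0), Leaf("v", 1.0, 0.0)))
        surf = st.response_surface(m, sl, ["u"])
        assert np.allclose(surf.probabilities, 0.5)

    def test_bias_only_model_gives_flat_surface(self, mini_slice):
        m = st.FormulaModel(tree=None, output_bias=1.0)
        surf = st.response_surface(m, mini_slice, ["G0001"])
        assert np.allclose(surf.probabilities, 1 / (1 + np.exp(-1.0)))

    def test_two_feature_grid_shape(self, mini_slice):
        m = st.FormulaModel(
            tree=Node("add", Node("add", Leaf("G0003"), Leaf("G0011")), Leaf("G0001"))
        )
        surf = st.response_surface(m, mini_slice, ["G0003", "G0011"], n_points=10)
        assert surf.probabilities.shape == (10, 10)
        assert list(surf.fixed_values) == ["G0001"]

    def test_varied_feature_not_in_model_rejected(self, mini_slice):
        m = st.FormulaModel(tree=Leaf("G0003"))
        with pytest.raises(ValueError, match="G0002"):
            st.response_surface(m, mini_slice, ["G0002"])
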