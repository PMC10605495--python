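"""Cross-dataset transfer of per-cell-type signatures and table-style reporting.

For every cell type shared by at least two datasets, the pipeline searches
for candidate signatures on each dataset that contains the type, evaluates
all candidates on each other dataset sharing it, applies the selection
strategy (overfitting gap filter, then simplicity preferences), and emits one
:class:`TransferRecord` per (train, test, cell type) — the row structure of a
transfer-study summary table: train/test PR AUC, the transferability-corrected
score, cell counts, per-dataset disease fractions of the type, and the two
genes that dominate the candidate shortlist.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, CellTypeSlice, slice_cell_type
from .formula import FormulaModel, evaluate
from .metrics import pr_auc, round_half_up, transfer_score
from .search import ModelCandidate, SearchConfig, search

__all__ = [
    "SelectionCriteria",
    "TransferRecord",
    "shared_cell_types",
    "uc_fraction",
    "select_model",
    "dominant_features",
    "run_transfer",
    "summarize",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "Training ID",
    "Test ID",
    "Cell Type",
    "Dominant Features",
    "PR AUC",
    "Score",
    "Count",
    "UC Fraction",
]


@dataclass
class SelectionCriteria:
    """How the final model is chosen among the shortlist.

    Candidates whose train/test PR AUC gap reaches ``max_auc_gap`` are treated
    as overfitting and dropped; survivors are ranked by simplicity (fewer
    features, additive before multiplicative) and then by transfer score. If
    nothing survives the gap filter, the highest-scoring candidate is kept
    with a fallback flag. ``rank_score_first`` flips the ordering to score
    before simplicity. ``holdout_fraction`` computes the gap on a
    training-internal split instead of the test set (avoids selecting on test
    information; not the historical convention, hence off by default).
    """

    max_auc_gap: float = 0.10
    prefer_fewer_features: bool = True
    prefer_additive: bool = True
    relative_gap: bool = False
    rank_score_first: bool = False
    holdout_fraction: "float | None" = None

    def __post_init__(self) -> None:
        if not 0 < self.max_auc_gap <= 1:
            raise ValueError("max_auc_gap must lie in (0, 1]")
        if self.holdout_fraction is not None and not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")


@dataclass
class EvaluatedCandidate:
    """A shortlist candidate with its test-slice performance attached."""

    candidate: ModelCandidate
    pr_auc_train: float
    pr_auc_test: float
    gap: float  # the quantity the overfitting filter applies to

    @property
    def score(self) -> float:
        return transfer_score(self.pr_auc_train, self.pr_auc_test)


@dataclass
class TransferRecord:
    train_id: str
    test_id: str
    cell_type: str
    pr_auc_train: float
    pr_auc_test: float
    score: float
    n_train_cells: int
    n_test_cells: int
    uc_fraction_train: float
    uc_fraction_test: float
    dominant_features: tuple[str, str]
    selected_model: FormulaModel
    fallback_selection: bool = False

    def __post_init__(self) -> None:
        expected = transfer_score(self.pr_auc_train, self.pr_auc_test)
        if abs(self.score - expected) > 1e-12:
            raise ValueError("score must equal transfer_score(pr_auc_train, pr_auc_test)")


def permute_labels(ds: ExpressionDataset, seed: int = 0) -> ExpressionDataset:
    """Copy of the dataset with the cell→sample assignment permuted.

    Breaks any real association between expression and disease state while
    preserving both marginals — the permutation null for transfer scores."""
    rng = np.random.default_rng(seed)
    adata = ds.adata.copy()
    perm = rng.permutation(adata.n_obs)
    adata.obs["sample_id"] = adata.obs["sample_id"].to_numpy()[perm]
    return replace(ds, adata=adata)


def shared_cell_types(datasets: list[ExpressionDataset]) -> dict[str, set[str]]:
    """Map each observed cell type to the set of dataset ids containing it."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    out: dict[str, set[str]] = {}
    for ds in datasets:
        for ct in ds.cell_type.unique():
            out.setdefault(str(ct), set()).add(ds.dataset_id)
    return out


def uc_fraction(ds: ExpressionDataset, cell_type: str) -> float:
    """Fraction of the type's cells that come from disease-labeled samples."""
    mask = (ds.cell_type == cell_type).to_numpy()
    if not mask.any():
        raise LookupError(f"cell type {cell_type!r} not in dataset {ds.dataset_id!r}")
    return float(ds.cell_labels("disease")[mask].mean())


def select_model(
    evaluated: list[EvaluatedCandidate], criteria: SelectionCriteria
) -> tuple[EvaluatedCandidate, bool]:
    """Apply the gap filter, then the simplicity/score ranking.

    Returns (chosen, fallback_used)."""
    if not evaluated:
        raise ValueError("no evaluated candidates to select from")
    survivors = [e for e in evaluated if e.gap < criteria.max_auc_gap]
    fallback = not survivors
    if fallback:
        logger.warning("no candidate under the %.0f%% AUC-gap filter; "
                       "falling back to highest score", 100 * criteria.max_auc_gap)
        chosen = max(evaluated, key=lambda e: (e.score, _rank_key(e, criteria)))
        return chosen, True

    def key(e: EvaluatedCandidate):
        simplicity = _rank_key(e, criteria)
        return (e.score, simplicity) if criteria.rank_score_first else (simplicity, e.score)

    # maximize: rank keys are built so bigger is better
    return max(survivors, key=key), False


def _rank_key(e: EvaluatedCandidate, criteria: SelectionCriteria):
    m = e.candidate.model
    n_feat = -len(m.features) if criteria.prefer_fewer_features else 0
    additive = 1 if (criteria.prefer_additive and m.is_additive()) else 0
    # final tie-break: lexicographically smallest expression key wins
    return (n_feat, additive, e.score, _NegStr(m.structure_key()))


class _NegStr(str):
    """String whose ordering is reversed, for lexicographic tie-breaks under max()."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def dominant_features(candidates: list[ModelCandidate]) -> tuple[str, str]:
    """The two genes present in the most shortlist models (presence per model,
    not leaf multiplicity); ties break lexicographically; second slot empty
    when only one gene is ever used."""
    if not candidates:
        raise ValueError("no candidates")
    counts: dict[str, int] = {}
    for c in candidates:
        for g in set(c.model.features):
            counts[g] = counts.get(g, 0) + 1
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    top = (ranked + ["", ""])[:2]
    return top[0], top[1]


# ---------------------------------------------------------------------------
# the full run


def _derived_seed(base: int, *parts: str) -> int:
    digest = hashlib.sha256(":".join([str(base), *parts]).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _holdout_split(slice_: CellTypeSlice, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    n = slice_.n_cells
    idx = rng.permutation(n)
    n_hold = max(1, int(round(fraction * n)))
    hold, train = idx[:n_hold], idx[n_hold:]
    mk = lambda rows: CellTypeSlice(
        dataset_id=slice_.dataset_id, cell_type=slice_.cell_type,
        X=slice_.X[rows], labels=slice_.labels[rows], gene_ids=slice_.gene_ids,
    )
    return mk(train), mk(hold)


def run_transfer(
    datasets: list[ExpressionDataset],
    search_config: SearchConfig | None = None,
    criteria: SelectionCriteria | None = None,
    positive_class: str = "disease",
    pairs: "list[tuple[str, str]] | None" = None,
) -> list[TransferRecord]:
    """Train on every (dataset, shared cell type), transfer to every other
    dataset with that type, and emit one record per direction.

    All datasets must be normalized. Fully deterministic for a fixed
    ``search_config.seed``: per-(dataset, cell type) search seeds are derived
    by hashing, independent of iteration order. ``pairs`` optionally restricts
    the run to specific (train_id, test_id) directions.
    """
    search_config = search_config or SearchConfig()
    criteria = criteria or SelectionCriteria()
    if len(datasets) < 2:
        raise ValueError("transfer needs at least 2 datasets")
    for ds in datasets:
        if not ds.normalized:
            raise ValueError(f"dataset {ds.dataset_id!r} must be normalized first")
    by_id = {ds.dataset_id: ds for ds in datasets}
    shared = {ct: ids for ct, ids in shared_cell_types(datasets).items() if len(ids) >= 2}
    if not shared:
        logger.warning("no cell type is shared between datasets; nothing to transfer")
        return []

    records: list[TransferRecord] = []
    for ct in sorted(shared):
        for train_id in sorted(shared[ct]):
            if pairs is not None and not any(t == train_id for t, _ in pairs):
                continue
            train_ds = by_id[train_id]
            train_slice = slice_cell_type(train_ds, ct, positive_class)
            if not train_slice.has_both_classes():
                logger.warning("skip %s/%s as training: single-class slice", train_id, ct)
                continue
            cfg = replace(search_config, seed=_derived_seed(search_config.seed, train_id, ct))
            candidates = search(train_slice, cfg)
            dom = dominant_features(candidates)
            for test_id in sorted(shared[ct] - {train_id}):
                if pairs is not None and (train_id, test_id) not in pairs:
                    continue
                test_ds = by_id[test_id]
                test_slice = slice_cell_type(test_ds, ct, positive_class)
                if not test_slice.has_both_classes():
                    logger.warning("skip %s->%s/%s: single-class test slice",
                                   train_id, test_id, ct)
                    continue
                evaluated = _evaluate_candidates(
                    candidates, train_slice, test_slice, criteria,
                    seed=_derived_seed(search_config.seed, train_id, test_id, ct),
                )
                if not evaluated:
                    logger.warning("skip %s->%s/%s: no candidate transferable",
                                   train_id, test_id, ct)
                    continue
                chosen, fallback = select_model(evaluated, criteria)
                records.append(
                    TransferRecord(
                        train_id=train_id,
                        test_id=test_id,
                        cell_type=ct,
                        pr_auc_train=chosen.pr_auc_train,
                        pr_auc_test=chosen.pr_auc_test,
                        score=chosen.score,
                        n_train_cells=train_slice.n_cells,
                        n_test_cells=test_slice.n_cells,
                        uc_fraction_train=uc_fraction(train_ds, ct),
                        uc_fraction_test=uc_fraction(test_ds, ct),
                        dominant_features=dom,
                        selected_model=chosen.candidate.model,
                        fallback_selection=fallback,
                    )
                )
    return records


def _evaluate_candidates(
    candidates: list[ModelCandidate],
    train_slice: CellTypeSlice,
    test_slice: CellTypeSlice,
    criteria: SelectionCriteria,
    seed: int,
) -> list[EvaluatedCandidate]:
    test_genes = set(map(str, test_slice.gene_ids))
    if criteria.holdout_fraction is not None:
        sub_train, holdout = _holdout_split(train_slice, criteria.holdout_fraction, seed)
    out: list[EvaluatedCandidate] = []
    for cand in candidates:
        feats = cand.model.features
        unmatched = [g for g in feats if g not in test_genes]
        if unmatched:
            logger.info("candidate %s skipped: gene(s) %s absent from test panel",
                        cand.model.structure_key(), unmatched)
            continue
        auc_train = cand.train_metrics.pr_auc
        auc_test = pr_auc(test_slice.labels, _scores(cand.model, test_slice))
        if criteria.holdout_fraction is not None and holdout.has_both_classes() \
                and sub_train.has_both_classes():
            a = pr_auc(sub_train.labels, _scores(cand.model, sub_train))
            b = pr_auc(holdout.labels, _scores(cand.model, holdout))
            gap = abs(a - b)
            ref = max(a, b)
        else:
            gap = abs(auc_train - auc_test)
            ref = max(auc_train, auc_test)
        if criteria.relative_gap and ref > 0:
            gap = gap / ref
        out.append(EvaluatedCandidate(cand, auc_train, auc_test, gap))
    return out


def _scores(model: FormulaModel, slice_: CellTypeSlice) -> np.ndarray:
    X = slice_.feature_matrix(model.features) if model.features else np.zeros((slice_.n_cells, 0))
    return evaluate(model, X)


# ---------------------------------------------------------------------------
# reporting


def summarize(records: list[TransferRecord]) -> pd.DataFrame:
    """Summary-table rows: 2-decimal AUC/score display (half-up), integer
    percent disease fractions, sorted by Training ID then Score descending."""
    rows = []
    for r in sorted(records, key=lambda r: (r.train_id, -r.score, r.test_id, r.cell_type)):
        dom = ", ".join(g for g in r.dominant_features if g)
        rows.append(
            {
                "Training ID": r.train_id,
                "Test ID": r.test_id,
                "Cell Type": r.cell_type,
                "Dominant Features": dom,
                "PR AUC": f"{round_half_up(r.pr_auc_train):.2f}/{round_half_up(r.pr_auc_test):.2f}",
                "Score": f"{round_half_up(r.score):.2f}",
                "Count": f"{r.n_train_cells}/{r.n_test_cells}",
                "UC Fraction": (
                    f"{round_half_up(100 * r.uc_fraction_train, 0):.0f}%/"
                    f"{round_half_up(100 * r.uc_fraction_test, 0):.0f}%"
                ),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(records: list[TransferRecord], path) -> None:
    summarize(records).to_csv(path, sep="\t", index=False)


def records_frame(records: list[TransferRecord]) -> pd.DataFrame:
    """Raw (unrounded) record fields plus the selected model's expression."""
    return pd.DataFrame(
        [
            {
                "train_id": r.train_id,
                "test_id": r.test_id,
                "cell_type": r.cell_type,
                "pr_auc_train": r.pr_auc_train,
                "pr_auc_test": r.pr_auc_test,
                "score": r.score,
                "n_train_cells": r.n_train_cells,
                "n_test_cells": r.n_test_cells,
                "uc_fraction_train": r.uc_fraction_train,
                "uc_fraction_test": r.uc_fraction_test,
                "dominant_features": ", ".join(g for g in r.dominant_features if g),
                "selected_model": r.selected_model.expression(),
                "fallback_selection": r.fallback_selection,
            }
            for r in records
        ]
    )
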