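"""Expression datasets: disk round trip, labeling, normalization, slicing.

An :class:`ExpressionDataset` is a cells × genes count (or normalized) matrix
backed by :class:`anndata.AnnData`, with per-cell metadata (cell type, sample)
and a per-sample binary disease state. On disk a dataset is one directory:

    matrix.mtx   Matrix Market coordinate counts (cells × genes, 1-based)
    genes.tsv    gene_id
    cells.tsv    cell_id  cell_type  sample_id
    samples.tsv  sample_id  disease_state

Disease labels live on samples (patients) and are inherited by cells; the
positive class is disease = 1 by default, switchable to healthy via
``positive_class``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "ValidationError",
    "ExpressionDataset",
    "CellTypeSlice",
    "read_dataset",
    "write_dataset",
    "normalize_log1p",
    "slice_cell_type",
]


class ValidationError(ValueError):
    """Inconsistent dataset contents; the message names the offending record."""


@dataclass
class ExpressionDataset:
    """Cells × genes expression with sample-level disease labels."""

    dataset_id: str
    adata: AnnData  # X: counts or normalized; obs: cell_type, sample_id; var index: gene ids
    samples: pd.DataFrame  # index: sample_id; column: disease_state (0/1)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- views ------------------------------------------------------------

    @property
    def matrix(self):
        return self.adata.X

    @property
    def gene_ids(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def cell_type(self) -> pd.Series:
        return self.adata.obs["cell_type"]

    @property
    def sample_id(self) -> pd.Series:
        return self.adata.obs["sample_id"]

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    def cell_labels(self, positive_class: str = "disease") -> np.ndarray:
        """Per-cell binary label inherited from the cell's sample."""
        states = self.samples["disease_state"].reindex(self.sample_id.to_numpy())
        y = states.to_numpy(dtype=np.int64)
        if positive_class == "healthy":
            y = 1 - y
        elif positive_class != "disease":
            raise ValueError("positive_class must be 'disease' or 'healthy'")
        return y

    def cell_types(self) -> list[str]:
        return sorted(self.cell_type.unique())

    def validate(self) -> None:
        a = self.adata
        if a.n_obs < 1:
            raise ValidationError(f"dataset {self.dataset_id!r} has no cells")
        for col in ("cell_type", "sample_id"):
            if col not in a.obs.columns:
                raise ValidationError(f"cells table missing column {col!r}")
        if a.obs_names.duplicated().any():
            dup = a.obs_names[a.obs_names.duplicated()][0]
            raise ValidationError(f"duplicate cell_id {dup!r}")
        if a.var_names.duplicated().any():
            dup = a.var_names[a.var_names.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        if "disease_state" not in self.samples.columns:
            raise ValidationError("samples table missing column 'disease_state'")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad_states = set(self.samples["disease_state"]) - {0, 1}
        if bad_states:
            raise ValidationError(f"disease_state must be 0/1, found {sorted(bad_states)}")
        unknown = set(a.obs["sample_id"]) - set(self.samples.index)
        if unknown:
            raise ValidationError(
                f"cell references unknown sample_id {sorted(unknown)[0]!r}"
            )
        X = a.X
        minval = X.data.min() if sp.issparse(X) and X.nnz else (0 if sp.issparse(X) else np.min(X))
        if minval < 0:
            raise ValidationError("expression entries must be non-negative")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        dataset_id: str,
        X,
        gene_ids,
        cell_ids,
        cell_type,
        sample_id,
        samples: pd.DataFrame,
        normalized: bool = False,
    ) -> "ExpressionDataset":
        obs = pd.DataFrame(
            {
                "cell_type": [str(x) for x in cell_type],
                "sample_id": [str(x) for x in sample_id],
            },
            index=pd.Index([str(c) for c in cell_ids], name="cell_id"),
        )
        var = pd.DataFrame(index=pd.Index([str(g) for g in gene_ids], name="gene_id"))
        if not sp.issparse(X):
            X = np.asarray(X)
        adata = AnnData(X=X, obs=obs, var=var)
        samples = samples.copy()
        if samples.index.name != "sample_id" and "sample_id" in samples.columns:
            samples = samples.set_index("sample_id")
        return cls(dataset_id=dataset_id, adata=adata, samples=samples, normalized=normalized)


def read_dataset(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a dataset directory (matrix.mtx + genes/cells/samples TSVs).

    Matrix Market's 1-based coordinates become 0-based internal positions via
    the standard reader; TSVs tolerate CRLF line endings and '%' comment lines.
    """
    path = Path(path)
    for fname in ("matrix.mtx", "genes.tsv", "cells.tsv", "samples.tsv"):
        if not (path / fname).exists():
            raise ValidationError(f"missing {fname} in {path}")
    X = scipy.io.mmread(path / "matrix.mtx").tocsr()
    genes = _read_tsv(path / "genes.tsv")
    cells = _read_tsv(path / "cells.tsv")
    samples = _read_tsv(path / "samples.tsv")
    if X.shape[0] != len(cells):
        raise ValidationError(
            f"matrix has {X.shape[0]} rows but cells.tsv lists {len(cells)} cells"
        )
    if X.shape[1] != len(genes):
        raise ValidationError(
            f"matrix has {X.shape[1]} columns but genes.tsv lists {len(genes)} genes"
        )
    meta = _read_meta(path)
    return ExpressionDataset.from_arrays(
        dataset_id=dataset_id or meta.get("dataset_id", path.name),
        X=X,
        gene_ids=genes["gene_id"],
        cell_ids=cells["cell_id"],
        cell_type=cells["cell_type"],
        sample_id=cells["sample_id"],
        samples=samples.astype({"disease_state": int}),
        normalized=bool(meta.get("normalized", False)),
    )


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="%", dtype=str)


def _read_meta(path: Path) -> dict:
    meta_path = path / "dataset.tsv"
    if not meta_path.exists():
        return {}
    df = _read_tsv(meta_path)
    rec = df.iloc[0].to_dict()
    rec["normalized"] = rec.get("normalized", "False") == "True"
    return rec


def write_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the directory layout read by :func:`read_dataset`.

    Integer count matrices round-trip losslessly (MTX integer field)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = ds.matrix
    Xs = sp.coo_matrix(X) if not sp.issparse(X) else X.tocoo()
    is_int = np.issubdtype(Xs.dtype, np.integer) or (
        Xs.nnz > 0 and np.allclose(Xs.data, np.round(Xs.data)) and not ds.normalized
    )
    if is_int:
        Xs = Xs.astype(np.int64)
    scipy.io.mmwrite(path / "matrix.mtx", Xs, field="integer" if is_int else "real")
    pd.DataFrame({"gene_id": ds.gene_ids}).to_csv(path / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "cell_type": ds.cell_type.to_numpy(),
            "sample_id": ds.sample_id.to_numpy(),
        }
    ).to_csv(path / "cells.tsv", sep="\t", index=False)
    ds.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path / "samples.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"dataset_id": ds.dataset_id, "normalized": ds.normalized}]
    ).to_csv(path / "dataset.tsv", sep="\t", index=False)


def normalize_log1p(ds: ExpressionDataset, target_sum: float = 1e4) -> ExpressionDataset:
    """Total-count scale each cell to ``target_sum``, then log(1 + x).

    The standard scRNA-seq preprocessing: it removes per-cell depth differences
    so that expression values are comparable across cells and datasets (a
    prerequisite for transferring a signature). Cells with zero total counts
    stay all-zero. Raises on already-normalized input.
    """
    if ds.normalized:
        raise ValueError(f"dataset {ds.dataset_id!r} is already normalized")
    import scanpy as sc

    adata = ds.adata.copy()
    adata.X = adata.X.astype(np.float64)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*zero counts.*")
        sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    adata.uns.pop("log1p", None)
    return replace(ds, adata=adata, normalized=True)


@dataclass
class CellTypeSlice:
    """All cells of one type in one dataset, with per-cell disease labels."""

    dataset_id: str
    cell_type: str
    X: "sp.spmatrix | np.ndarray"  # cells × genes, normalized
    labels: np.ndarray  # 0/1 per cell
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.labels.size:
            raise ValidationError("labels length must match the cell count")
        if self.X.shape[0] < 1:
            raise ValidationError("a cell-type slice needs at least one cell")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary")
        if sp.issparse(self.X):
            self.X = self.X.tocsc()

    @property
    def n_cells(self) -> int:
        return int(self.X.shape[0])

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.labels))

    def has_both_classes(self) -> bool:
        return np.unique(self.labels).size == 2

    def feature_matrix(self, genes) -> np.ndarray:
        """Dense (cells × len(genes)) block with columns aligned to ``genes``."""
        indexer = self.gene_ids.get_indexer([str(g) for g in genes])
        missing = [g for g, j in zip(genes, indexer) if j < 0]
        if missing:
            raise KeyError(f"gene(s) not in slice panel: {missing}")
        block = self.X[:, indexer]
        return np.asarray(block.todense()) if sp.issparse(block) else np.asarray(block)


def slice_cell_type(
    ds: ExpressionDataset, cell_type: str, positive_class: str = "disease"
) -> CellTypeSlice:
    """Extract the cells of one type with labels inherited from their samples."""
    if not ds.normalized:
        raise ValueError("normalize the dataset before slicing (normalize_log1p)")
    mask = (ds.cell_type == cell_type).to_numpy()
    if not mask.any():
        raise LookupError(
            f"cell type {cell_type!r} not in dataset {ds.dataset_id!r}; "
            f"available: {ds.cell_types()}"
        )
    return CellTypeSlice(
        dataset_id=ds.dataset_id,
        cell_type=cell_type,
        X=ds.matrix[mask],
        labels=ds.cell_labels(positive_class)[mask],
        gene_ids=ds.gene_ids,
    )
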