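"""Drug featurization: dimensionality reduction and pair aggregation.

Each drug is described by two sparse binary vectors — its mono side effects
and its protein interaction partners.  Both blocks are reduced independently
(PCA keeping the minimum number of components whose cumulative explained
variance reaches a threshold, 0.95 by default, or alternatively a
low-variance column filter) and concatenated into the drug feature matrix
``[F1 | F2]``.  A drug pair (d_i, d_j) is featurized by summing (default) or
concatenating rows i and j of that matrix; summation makes the pair
representation order-invariant by construction.

PCA here is deterministic: a full eigendecomposition of the centred
covariance (no randomized solver), with each component's sign fixed so that
its largest-magnitude loading is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_ingest import BinaryMatrix, EntityVocabulary


@dataclass
class ReducedBlock:
    """One reduced feature block (scores matrix plus reduction metadata).

    ``explained_variance`` holds per-component fractions of the total input
    variance (PCA only); ``column_means`` the centring offsets needed to
    project new drugs (PCA only).
    """

    values: np.ndarray  # drugs x k
    block_label: str  # "F1" | "F2"
    reducer: str  # "pca" | "low_variance"
    drug_vocab: EntityVocabulary
    explained_variance: np.ndarray | None = None
    column_means: np.ndarray | None = None
    components: np.ndarray | None = None  # k x input-columns loadings (pca)
    kept_columns: np.ndarray | None = None  # input column indices (low_variance)

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def save(self, path_prefix: str | Path) -> None:
        """Write scores as TSV with header plus a JSON metadata sidecar."""
        prefix = Path(path_prefix)
        with open(prefix.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
            fh.write("drug_id\t" + "\t".join(f"f{i:03d}" for i in range(self.k)) + "\n")
            for drug, row in zip(self.drug_vocab.index_to_id, self.values):
                fh.write(drug + "\t" + "\t".join(f"{v:.17e}" for v in row) + "\n")
        meta = {
            "block_label": self.block_label,
            "reducer": self.reducer,
            "k": int(self.k),
            "explained_variance": None
            if self.explained_variance is None
            else [float(v) for v in self.explained_variance],
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


@dataclass
class DrugFeatureMatrix:
    """Dense drugs x (k1 + k2) matrix, F1 columns before F2 columns."""

    values: np.ndarray
    block_boundary: int  # column index where F1 ends and F2 begins
    drug_vocab: EntityVocabulary

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def blocks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.values[:, : self.block_boundary], self.values[:, self.block_boundary :]


def pca_reduce(
    m: BinaryMatrix, variance_threshold: float = 0.95, block_label: str = "F1"
) -> ReducedBlock:
    """Centred PCA keeping the fewest components reaching ``variance_threshold``.

    Columns are mean-centred but not scaled to unit variance.  k is minimal:
    the cumulative explained-variance fraction first reaches the threshold at
    k components.  Raises on an all-constant matrix (no variance to retain).
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    dense = m.dense()
    if dense.shape[0] < 2:
        raise ValueError("PCA needs at least 2 drugs")
    means = dense.mean(axis=0)
    centred = dense - means
    # SVD of the centred matrix == eigendecomposition of the covariance,
    # but better conditioned; deterministic full decomposition.
    u, svals, vt = np.linalg.svd(centred, full_matrices=False)
    n = dense.shape[0]
    variances = svals**2 / (n - 1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("matrix is constant: no variance to retain")
    fractions = variances / total
    cumulative = np.cumsum(fractions)
    k = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    k = min(k, len(svals))

    components = vt[:k]  # k x p loadings
    # Sign convention: largest-|loading| entry of each component is positive.
    flip = np.sign(components[np.arange(k), np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    scores = centred @ components.T
    return ReducedBlock(
        values=scores,
        block_label=block_label,
        reducer="pca",
        drug_vocab=m.row_vocab,
        explained_variance=fractions[:k],
        column_means=means,
        components=components,
    )


def low_variance_reduce(m: BinaryMatrix, k: int, block_label: str = "F1") -> ReducedBlock:
    """Keep the k highest-sample-variance columns, uncentred, in input order.

    Ties in variance are broken toward the lower column index.
    """
    dense = m.dense()
    p = dense.shape[1]
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    variances = dense.var(axis=0, ddof=1) if dense.shape[0] > 1 else dense.var(axis=0)
    # stable sort on descending variance keeps lower indices first among ties
    order = np.argsort(-variances, kind="stable")[:k]
    kept = np.sort(order)
    return ReducedBlock(
        values=dense[:, kept],
        block_label=block_label,
        reducer="low_variance",
        drug_vocab=m.row_vocab,
        kept_columns=kept,
    )


def concat_blocks(f1: ReducedBlock, f2: ReducedBlock) -> DrugFeatureMatrix:
    """Concatenate F1 and F2 scores into the drug feature matrix."""
    if f1.drug_vocab.index_to_id != f2.drug_vocab.index_to_id:
        raise ValueError("blocks were built over different drug vocabularies")
    return DrugFeatureMatrix(
        values=np.hstack([f1.values, f2.values]),
        block_boundary=f1.k,
        drug_vocab=f1.drug_vocab,
    )


def pair_features(
    fm: DrugFeatureMatrix,
    pairs: np.ndarray | list[tuple[int, int]],
    mode: str = "sum",
) -> np.ndarray:
    """Aggregate two drug rows into one pair feature vector.

    ``sum`` adds rows i and j (symmetric in the pair, the default the method
    uses); ``concat`` stacks them ordered by ascending drug index so that the
    output is still independent of the order the pair was written in.
    """
    idx = np.asarray(pairs, dtype=int)
    if idx.ndim != 2 or idx.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) index array")
    if np.any(idx[:, 0] == idx[:, 1]):
        raise ValueError("self-pairs cannot be featurized")
    if idx.min(initial=0) < 0 or idx.max(initial=0) >= fm.values.shape[0]:
        raise IndexError("pair indices outside the drug feature matrix")
    if mode == "sum":
        return fm.values[idx[:, 0]] + fm.values[idx[:, 1]]
    if mode == "concat":
        lo = np.minimum(idx[:, 0], idx[:, 1])
        hi = np.maximum(idx[:, 0], idx[:, 1])
        return np.hstack([fm.values[lo], fm.values[hi]])
    raise ValueError(f"mode must be 'sum' or 'concat', got {mode!r}")
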