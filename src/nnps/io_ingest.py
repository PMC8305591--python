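"""Ingestion of drug-pair, mono-side-effect and drug-protein interaction tables.

Three tab-separated table families are consumed:

* a drug-pair / polypharmacy-side-effect table (TWOSIDES-style):
  one row per (drug, drug, side effect) association;
* two-column drug-feature tables (SIDER/OFFSIDES-style mono side effects,
  STITCH-style drug-protein interactions);
* the synthetic fixtures written by :mod:`nnps.synthetic_data`, which use
  the same dialects.

All identifiers are opaque strings.  Drug pairs are unordered: ``(a, b)`` and
``(b, a)`` denote the same pair and are stored once in canonical order
(lexicographically smaller identifier first).  Feature values are strictly
binary presence/absence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("nnps")

#: Default column names for each table family; override via the ``dialect``
#: argument (or the ``columns`` block of a run config).
DEFAULT_DIALECTS = {
    "pairs": {"drug_a": "drug1", "drug_b": "drug2", "side_effect": "side_effect_id"},
    "mono_side_effect": {"drug": "drug_id", "feature": "effect_id"},
    "protein": {"drug": "chemical", "feature": "protein"},
}

VOCAB_KINDS = ("drug", "protein", "mono_side_effect", "poly_side_effect")


class ConfigurationError(ValueError):
    """A table or config does not match its declared dialect."""


# ---------------------------------------------------------------------------
# Vocabularies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityVocabulary:
    """Bijective map between external string identifiers and dense indices.

    Indices are contiguous from 0 and assigned in sorted identifier order, so
    a vocabulary built from the same identifier set is always identical.
    """

    kind: str
    index_to_id: tuple[str, ...]
    id_to_index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_ids(cls, kind: str, ids: Iterable[str]) -> "EntityVocabulary":
        if kind not in VOCAB_KINDS:
            raise ValueError(f"unknown vocabulary kind {kind!r}")
        ordered = tuple(sorted(set(ids)))
        return cls(kind, ordered, {s: i for i, s in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.index_to_id)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.id_to_index

    def index(self, identifier: str) -> int:
        return self.id_to_index[identifier]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\n" for s in self.index_to_id), encoding="utf-8"
        )

    @classmethod
    def load(cls, kind: str, path: str | Path) -> "EntityVocabulary":
        ids = [line.rstrip("\n") for line in Path(path).read_text(encoding="utf-8").splitlines()]
        vocab = cls.from_ids(kind, ids)
        if list(vocab.index_to_id) != ids:
            raise ConfigurationError(f"vocabulary file {path} is not sorted/unique")
        return vocab


# ---------------------------------------------------------------------------
# Binary drug-feature matrices
# ---------------------------------------------------------------------------


@dataclass
class BinaryMatrix:
    """Sparse 0/1 drug-by-feature matrix with its two vocabularies.

    Rows are drugs, columns are mono side effects or proteins.  Repeated
    assertions of the same (drug, feature) fact are idempotent.
    """

    values: sp.csr_matrix
    row_vocab: EntityVocabulary
    col_vocab: EntityVocabulary

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.int8)
        self.values.data[:] = 1  # presence only
        self.values.eliminate_zeros()
        if self.values.shape != (len(self.row_vocab), len(self.col_vocab)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match vocabularies "
                f"({len(self.row_vocab)} x {len(self.col_vocab)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=float)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        row_vocab: EntityVocabulary,
        col_vocab: EntityVocabulary,
    ) -> "BinaryMatrix":
        rows, cols = [], []
        for drug, feat in pairs:
            rows.append(row_vocab.index(drug))
            cols.append(col_vocab.index(feat))
        values = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(row_vocab), len(col_vocab)),
        )
        return cls(values, row_vocab, col_vocab)

    def triplets(self) -> list[tuple[str, str]]:
        """Nonzero entries as sorted (drug_id, feature_id) pairs."""
        coo = self.values.tocoo()
        out = [
            (self.row_vocab.index_to_id[r], self.col_vocab.index_to_id[c])
            for r, c in zip(coo.row, coo.col)
        ]
        return sorted(out)

    def save(self, path: str | Path) -> None:
        """Persist as a diffable TSV triplet table (row_id, col_id, 1)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("row_id\tcol_id\tvalue\n")
            for drug, feat in self.triplets():
                fh.write(f"{drug}\t{feat}\t1\n")


# ---------------------------------------------------------------------------
# Drug-drug interaction table
# ---------------------------------------------------------------------------


@dataclass
class DDITable:
    """Canonicalized, deduplicated (drug, drug, side effect) records.

    Each record is an unordered drug pair labelled with one polypharmacy side
    effect; it is stored once with the lexicographically smaller drug first.
    """

    records: list[tuple[str, str, str]]
    drug_vocab: EntityVocabulary
    side_effect_vocab: EntityVocabulary

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "DDITable":
        canon = set()
        for a, b, s in records:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) is not a drug-drug interaction")
            canon.add((min(a, b), max(a, b), s))
        recs = sorted(canon)
        drugs = {a for a, _, _ in recs} | {b for _, b, _ in recs}
        effects = {s for _, _, s in recs}
        return cls(
            recs,
            EntityVocabulary.from_ids("drug", drugs),
            EntityVocabulary.from_ids("poly_side_effect", effects),
        )

    def __len__(self) -> int:
        return len(self.records)

    def pairs_for(self, side_effect: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, s in self.records if s == side_effect]

    def pair_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, s in self.records:
            counts[s] = counts.get(s, 0) + 1
        return counts

    def save(self, path: str | Path, dialect: Mapping[str, str] | None = None) -> None:
        d = dict(DEFAULT_DIALECTS["pairs"], **(dialect or {}))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{d['drug_a']}\t{d['drug_b']}\t{d['side_effect']}\n")
            for a, b, s in self.records:
                fh.write(f"{a}\t{b}\t{s}\n")


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    return frame


def load_pair_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> DDITable:
    """Load a drug-pair/side-effect TSV into a canonical :class:`DDITable`.

    Symmetric duplicates collapse; self-pair rows are rejected with a logged
    warning count rather than an error.
    """
    d = dict(DEFAULT_DIALECTS["pairs"], **(dialect or {}))
    frame = _read_tsv(path, [d["drug_a"], d["drug_b"], d["side_effect"]])
    records, self_pairs = [], 0
    for a, b, s in frame[[d["drug_a"], d["drug_b"], d["side_effect"]]].itertuples(index=False):
        if a == b:
            self_pairs += 1
            continue
        records.append((a, b, s))
    if self_pairs:
        logger.warning("%s: rejected %d self-pair row(s)", path, self_pairs)
    table = DDITable.from_records(records)
    logger.info(
        "%s: %d records, %d drugs, %d side effects",
        path, len(table), len(table.drug_vocab), len(table.side_effect_vocab),
    )
    return table


def load_drug_feature_table(
    path: str | Path,
    kind: str,
    drug_vocab: EntityVocabulary | None = None,
    col_vocab: EntityVocabulary | None = None,
    dialect: Mapping[str, str] | None = None,
    min_score: float | None = None,
    score_column: str = "score",
) -> BinaryMatrix:
    """Load a two-column (drug, feature) TSV into a :class:`BinaryMatrix`.

    Parameters
    ----------
    kind
        ``"mono_side_effect"`` or ``"protein"``; selects the default dialect
        and the column-vocabulary kind.
    drug_vocab
        Optional drug vocabulary restricting rows.  Drugs present in the
        vocabulary but absent from the file get all-zero rows; file rows for
        unlisted drugs are skipped.
    min_score
        Optional confidence cutoff applied to ``score_column`` if present
        (interaction scores are otherwise ignored: any listed row counts).
    """
    if kind not in ("mono_side_effect", "protein"):
        raise ValueError(f"kind must be mono_side_effect or protein, got {kind!r}")
    d = dict(DEFAULT_DIALECTS[kind], **(dialect or {}))
    frame = _read_tsv(path, [d["drug"], d["feature"]])
    n_rows = len(frame)
    if min_score is not None:
        if score_column not in frame.columns:
            raise ConfigurationError(
                f"{path}: min_score given but no {score_column!r} column"
            )
        frame = frame[pd.to_numeric(frame[score_column]) >= min_score]

    kept: list[tuple[str, str]] = []
    skipped = 0
    for i, (drug, feat) in enumerate(frame[[d["drug"], d["feature"]]].itertuples(index=False)):
        if not drug or not feat:
            skipped += 1
            logger.warning("%s: skipping unreadable row %d", path, i + 2)
            continue
        if drug_vocab is not None and drug not in drug_vocab:
            skipped += 1
            continue
        kept.append((drug, feat))
    if n_rows > 0 and not kept:
        raise ValueError(f"{path}: every row was skipped; nothing to load")

    if drug_vocab is None:
        drug_vocab = EntityVocabulary.from_ids("drug", (d_ for d_, _ in kept))
    if col_vocab is None:
        col_vocab = EntityVocabulary.from_ids(kind, (f for _, f in kept))
    return BinaryMatrix.from_pairs(kept, drug_vocab, col_vocab)


def merge_mono_side_effect_sources(
    a: BinaryMatrix,
    b: BinaryMatrix,
    synonym_map: Mapping[str, str] | None = None,
) -> BinaryMatrix:
    """Union two mono-side-effect matrices over a shared drug vocabulary.

    Feature identifiers are first canonicalized through ``synonym_map``
    (feature id -> canonical id); column vocabularies are then unioned and an
    entry is 1 if it is 1 in either source.  Mirrors the union-with-synonym-
    elimination construction of a single mono-side-effect matrix from two
    overlapping catalogues.
    """
    if a.row_vocab.index_to_id != b.row_vocab.index_to_id:
        raise ValueError("mono side-effect sources must share the drug vocabulary")
    syn = dict(synonym_map or {})
    for key, value in syn.items():
        if value in syn and syn[value] != value:
            raise ValueError(f"conflicting synonym mapping through {key!r} -> {value!r}")

    def canon(feature: str) -> str:
        return syn.get(feature, feature)

    pairs = {(drug, canon(f)) for drug, f in a.triplets()} | {
        (drug, canon(f)) for drug, f in b.triplets()
    }
    col_vocab = EntityVocabulary.from_ids(
        "mono_side_effect",
        {canon(f) for f in a.col_vocab.index_to_id}
        | {canon(f) for f in b.col_vocab.index_to_id},
    )
    return BinaryMatrix.from_pairs(sorted(pairs), a.row_vocab, col_vocab)


def filter_side_effects(ddi: DDITable, min_pairs: int) -> DDITable:
    """Keep only side effects occurring in at least ``min_pairs`` distinct pairs.

    The inclusive >= cutoff with ``min_pairs=500`` is the filter that reduces
    the full TWOSIDES catalogue to the 964 frequently observed polypharmacy
    side effects.  Vocabularies are rebuilt from the surviving records.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    counts = ddi.pair_counts()
    keep = {s for s, n in counts.items() if n >= min_pairs}
    if not keep:
        logger.warning("filter_side_effects: no side effect has >= %d pairs", min_pairs)
    records = [r for r in ddi.records if r[2] in keep]
    return DDITable.from_records(records)


# ---------------------------------------------------------------------------
# Persistence helpers (matrix round-trip through triplet TSV)
# ---------------------------------------------------------------------------


def load_binary_matrix(
    path: str | Path,
    kind: str,
    row_vocab: EntityVocabulary,
    col_vocab: EntityVocabulary | None = None,
) -> BinaryMatrix:
    """Re-read a triplet TSV written by :meth:`BinaryMatrix.save`."""
    frame = _read_tsv(path, ["row_id", "col_id"])
    pairs = [(r, c) for r, c in frame[["row_id", "col_id"]].itertuples(index=False)]
    if col_vocab is None:
        col_vocab = EntityVocabulary.from_ids(kind, (c for _, c in pairs))
    return BinaryMatrix.from_pairs(pairs, row_vocab, col_vocab)


def save_manifest(path: str | Path, payload: Mapping) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
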