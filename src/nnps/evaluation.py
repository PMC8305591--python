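"""Example construction, splits, metrics and aggregation.

For every polypharmacy side effect the known interacting drug pairs are the
positive examples; negatives are sampled uniformly from the canonical
non-self drug pairs that are *not* associated with that side effect (1:1 by
default).  Examples are split 80/10/10 into train/validation/test under
5-fold cross-validation: each fold's held-out fifth is halved into the
validation and test parts, so both printed split statements hold at once.

The per-side-effect decision threshold θ_i is the candidate (0 or any
observed score) maximizing the F-score on the validation split; a pair is
called positive iff its predicted probability strictly exceeds θ_i.  The
metric suite (AUROC, AUPRC, precision, recall, F-score, ACC, MCC) defines
every 0/0 ratio as 0.  AUROC/AUPRC ride on scikit-learn's implementations;
AUPRC is step-wise average precision, not trapezoidal interpolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import sklearn.metrics as _skm

from .io_ingest import EntityVocabulary
from .neural_model import TrainTrace


# ---------------------------------------------------------------------------
# Example sets and negative sampling
# ---------------------------------------------------------------------------


@dataclass
class PairExampleSet:
    """Labelled unordered drug pairs for one side effect.

    ``pairs`` holds canonical (i, j) index pairs with i < j; positives and
    sampled negatives are disjoint and duplicate-free.
    """

    side_effect: str
    pairs: np.ndarray  # (n, 2) int, i < j
    labels: np.ndarray  # (n,) in {0, 1}
    provenance: list[str]  # "positive_source" | "sampled_negative"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must be canonical: i < j")
        keys = {tuple(p) for p in self.pairs}
        if len(keys) != len(self.pairs):
            raise ValueError("duplicate pairs in example set")

    def __len__(self) -> int:
        return len(self.labels)


def _pair_to_linear(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    # canonical pairs (i<j) enumerated by i, then j
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def _linear_to_pair(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.arange(n) * (2 * n - np.arange(n) - 1) // 2
    i = np.searchsorted(offsets, idx, side="right") - 1
    j = idx - offsets[i] + i + 1
    return i, j


def sample_negatives(
    positives: Sequence[tuple[int, int]],
    drug_vocab: EntityVocabulary | int,
    ratio: float = 1.0,
    seed: int = 0,
    side_effect: str = "",
) -> PairExampleSet:
    """Build an example set: known positives plus uniform negative pairs.

    Negatives are drawn uniformly without replacement from the canonical
    non-self pairs not in the positive set of this side effect; the count is
    ``round(ratio * len(positives))``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n = drug_vocab if isinstance(drug_vocab, int) else len(drug_vocab)
    pos = np.asarray(
        [(min(i, j), max(i, j)) for i, j in positives], dtype=int
    ).reshape(-1, 2)
    if len(pos) and (pos[:, 0] == pos[:, 1]).any():
        raise ValueError("positive list contains a self-pair")
    pos_lin = np.unique(_pair_to_linear(pos[:, 0], pos[:, 1], n)) if len(pos) else np.empty(0, int)
    if len(pos_lin) != len(pos):
        raise ValueError("duplicate positive pairs")
    total = n * (n - 1) // 2
    n_neg = int(round(ratio * len(pos)))
    candidates = np.setdiff1d(np.arange(total), pos_lin, assume_unique=True)
    if len(candidates) < n_neg:
        raise ValueError(
            f"cannot sample {n_neg} negatives: only {len(candidates)} candidate "
            f"pairs exist (short by {n_neg - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(candidates, size=n_neg, replace=False))
    ni, nj = _linear_to_pair(chosen, n)
    pairs = np.vstack([pos, np.column_stack([ni, nj])]) if len(pos) else np.column_stack([ni, nj])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(n_neg, int)])
    provenance = ["positive_source"] * len(pos) + ["sampled_negative"] * n_neg
    return PairExampleSet(side_effect, pairs, labels, provenance)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Per-fold train/validation/test index arrays over one example set.

    For fold f the held-out fifth (at 5 folds) is split in half into
    validation and test, giving the 80/10/10 proportions; across folds every
    example is held out exactly once.
    """

    folds: list[dict[str, np.ndarray]]
    seed: int

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(n_examples: int, folds: int = 5, seed: int = 0) -> FoldAssignment:
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n_examples < 2 * folds:
        raise ValueError(f"need at least {2 * folds} examples for {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_examples)
    parts = np.array_split(order, folds)
    assignments = []
    for f in range(folds):
        held = parts[f]
        half = len(held) // 2
        train = np.concatenate([parts[g] for g in range(folds) if g != f])
        assignments.append(
            {"train": np.sort(train), "val": np.sort(held[:half]), "test": np.sort(held[half:])}
        )
    return FoldAssignment(assignments, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _check_scores(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).ravel().astype(int)
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and scores differ in length")
    return y, p


def roc_curve(y: np.ndarray, p: np.ndarray):
    """(fpr, tpr, thresholds) of the ROC curve; both classes required."""
    y, p = _check_scores(y, p)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC curve is undefined for single-class labels")
    fpr, tpr, thr = _skm.roc_curve(y, p)
    return fpr, tpr, thr


def auroc(y: np.ndarray, p: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic, ties counted half)."""
    y, p = _check_scores(y, p)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC is undefined for single-class labels")
    return float(_skm.roc_auc_score(y, p))


def auprc(y: np.ndarray, p: np.ndarray) -> float:
    """Average precision: the step-wise area under the precision-recall curve."""
    y, p = _check_scores(y, p)
    if y.sum() == 0:
        raise ValueError("AUPRC is undefined without positive examples")
    return float(_skm.average_precision_score(y, p))


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Precision/recall/F/ACC/MCC from a confusion matrix; 0/0 defined as 0."""

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f_score = _ratio(2 * precision * recall, precision + recall)
    acc = _ratio(tp + tn, tp + fp + tn + fn)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "acc": acc,
        "mcc": mcc,
    }


def confusion_and_metrics(y: np.ndarray, p: np.ndarray, theta: float) -> dict[str, float]:
    """Confusion counts and threshold metrics at cutoff θ (positive iff p > θ)."""
    y, p = _check_scores(y, p)
    pred = p > theta
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    out = {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "theta": float(theta)}
    out.update(metrics_from_counts(tp, fp, tn, fn))
    return out


def select_threshold(y: np.ndarray, p: np.ndarray) -> float:
    """θ_i maximizing validation F-score over {0} ∪ {observed scores}.

    Ties are broken toward the larger threshold.  With an all-positive
    validation set θ=0 (call everything positive, F=1) is returned; with no
    positives the F-score is 0 at every threshold, so the selection is
    meaningless and falls back to 0.5 with a warning.
    """
    import warnings

    y, p = _check_scores(y, p)
    if y.sum() == 0:
        warnings.warn("no positives in validation set: falling back to theta=0.5")
        return 0.5
    candidates = np.concatenate([[0.0], np.unique(p)])
    best_theta, best_f = 0.0, -1.0
    for theta in candidates:  # ascending: later >= ties keep the larger theta
        f = confusion_and_metrics(y, p, theta)["f_score"]
        if f >= best_f:
            best_theta, best_f = float(theta), f
    return best_theta


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "side_effect", "theta", "tp", "fp", "tn", "fn",
    "precision", "recall", "f_score", "acc", "mcc", "auroc", "auprc",
)

METRIC_NAMES = ("precision", "recall", "f_score", "acc", "mcc", "auroc", "auprc")


@dataclass
class SideEffectReport:
    """Test-set results of one side effect under one fold-run."""

    side_effect: str
    theta: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_score: float
    acc: float
    mcc: float
    auroc: float
    auprc: float

    @classmethod
    def from_scores(
        cls, side_effect: str, y: np.ndarray, p: np.ndarray, theta: float
    ) -> "SideEffectReport":
        cm = confusion_and_metrics(y, p, theta)
        return cls(
            side_effect=side_effect,
            theta=float(theta),
            tp=cm["tp"], fp=cm["fp"], tn=cm["tn"], fn=cm["fn"],
            precision=cm["precision"], recall=cm["recall"], f_score=cm["f_score"],
            acc=cm["acc"], mcc=cm["mcc"],
            auroc=auroc(y, p), auprc=auprc(y, p),
        )

    def row(self) -> str:
        vals = [getattr(self, c) for c in REPORT_COLUMNS]
        return "\t".join(
            v if isinstance(v, str) else (str(v) if isinstance(v, int) else f"{v:.10g}")
            for v in vals
        )


@dataclass
class AggregateReport:
    """Unweighted aggregates over per-side-effect reports and traces.

    ``mloss[e]`` is the mean training loss and ``mauroc[e]`` the mean
    validation AUROC across side effects at epoch e; θ statistics and metric
    means are unweighted over reports.  Confusion counts are additionally
    pooled (summed) — pooled counts and averaged metrics answer different
    questions and are labelled separately.
    """

    n_reports: int
    mloss: list[float]
    mauroc: list[float]
    theta_mean: float
    theta_sd: float
    metric_means: dict[str, float]
    pooled_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "mloss": self.mloss,
            "mauroc": self.mauroc,
            "theta_mean": self.theta_mean,
            "theta_sd": self.theta_sd,
            "metric_means": self.metric_means,
            "pooled_counts": self.pooled_counts,
        }


def aggregate(
    reports: Sequence[SideEffectReport], traces: Sequence[TrainTrace] = ()
) -> AggregateReport:
    """Average reports (and epoch traces) without weighting by example count."""
    if not reports:
        raise ValueError("nothing to aggregate")
    if traces:
        epochs = {len(t.train_loss) for t in traces}
        if len(epochs) != 1:
            raise ValueError(f"mismatched epoch counts across traces: {sorted(epochs)}")
        mloss = [float(np.mean([t.train_loss[e] for t in traces])) for e in range(epochs.pop())]
        mauroc = [
            float(np.mean([t.val_auroc[e] for t in traces])) if all(t.val_auroc for t in traces) else float("nan")
            for e in range(len(mloss))
        ]
    else:
        mloss, mauroc = [], []
    thetas = np.array([r.theta for r in reports])
    return AggregateReport(
        n_reports=len(reports),
        mloss=mloss,
        mauroc=mauroc,
        theta_mean=float(thetas.mean()),
        theta_sd=float(thetas.std(ddof=1)) if len(thetas) > 1 else 0.0,
        metric_means={
            m: float(np.mean([getattr(r, m) for r in reports])) for m in METRIC_NAMES
        },
        pooled_counts={
            c: int(sum(getattr(r, c) for r in reports)) for c in ("tp", "fp", "tn", "fn")
        },
    )


# ---------------------------------------------------------------------------
# TSV / JSON writers
# ---------------------------------------------------------------------------


def write_reports(reports: Sequence[SideEffectReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in reports:
            fh.write(r.row() + "\n")


def write_aggregate(report: AggregateReport, path_prefix: str | Path) -> None:
    prefix = Path(path_prefix)
    prefix.with_suffix(".json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    with open(prefix.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"n_reports\t{report.n_reports}\n")
        fh.write(f"theta_mean\t{report.theta_mean:.10g}\n")
        fh.write(f"theta_sd\t{report.theta_sd:.10g}\n")
        for m, v in report.metric_means.items():
            fh.write(f"mean_{m}\t{v:.10g}\n")
        for c, v in report.pooled_counts.items():
            fh.write(f"pooled_{c}\t{v}\n")


def write_traces(traces: Sequence[TrainTrace], names: Sequence[str], path: str | Path) -> None:
    """One TSV row per (side effect run, epoch) for external plotting."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("run\tepoch\ttrain_loss\tval_loss\tval_auroc\n")
        for name, t in zip(names, traces):
            for e, loss in enumerate(t.train_loss):
                vl = f"{t.val_loss[e]:.10g}" if t.val_loss else ""
                va = f"{t.val_auroc[e]:.10g}" if t.val_auroc else ""
                fh.write(f"{name}\t{e}\t{loss:.10g}\t{vl}\t{va}\n")
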