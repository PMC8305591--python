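"""End-to-end orchestration: ingest -> features -> per-side-effect models.

A run is described by one :class:`RunConfig`, fully serialized into the
output directory for provenance.  For every retained side effect and every
(repetition, fold) pair the run samples negatives, trains one network,
selects θ_i on the validation split, evaluates on the test split, and writes
per-side-effect report rows, epoch traces, and the aggregate report.

All randomness derives from the single run seed through
``numpy.random.SeedSequence`` keyed on (side-effect index, repetition), so
per-side-effect results do not depend on execution order or parallelism
degree.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import evaluation, features, io_ingest, neural_model, synthetic_data

logger = logging.getLogger("nnps")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Console (and optional file) logging for pipeline runs."""
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    console = logging.StreamHandler(sys.stderr)
    console.setFormatter(fmt)
    logger.addHandler(console)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults are the selected operating
    point (min_pairs 500, 95% PCA variance, sum aggregation, 300/200/100
    hidden units, dropout 0.1, lr 0.01, momentum 0.9, batch 1024, 50 epochs,
    5 folds x 10 repetitions)."""

    # inputs: either explicit table paths ...
    pairs_path: str | None = None
    mono_path: str | None = None
    dpi_path: str | None = None
    drugs_path: str | None = None  # optional explicit drug vocabulary
    # ... or a fixture directory written by synthetic_data.write_fixture
    fixture_dir: str | None = None

    columns: dict = field(default_factory=dict)  # per-family dialect overrides
    min_pairs: int = 500
    variance_threshold: float = 0.95
    reducer: str = "pca"  # pca | low_variance
    low_variance_k: int = 50  # per block, capped at the block's column count
    aggregation: str = "sum"  # sum | concat
    negative_ratio: float = 1.0

    hidden_sizes: tuple[int, ...] = (300, 200, 100)
    dropout_rate: float = 0.1
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 1024
    epochs: int = 50

    folds: int = 5
    repetitions: int = 10
    side_effects: tuple[str, ...] | None = None  # subset selector; None = all
    save_models: bool = False
    n_jobs: int = 1
    output_dir: str = "nnps_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reducer not in ("pca", "low_variance"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.aggregation not in ("sum", "concat"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.fixture_dir is None and not (
            self.pairs_path and self.mono_path and self.dpi_path
        ):
            raise ValueError("either fixture_dir or all three table paths are required")
        if self.folds < 2 or self.repetitions < 1:
            raise ValueError("folds >= 2 and repetitions >= 1 required")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.side_effects is not None:
            self.side_effects = tuple(self.side_effects)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML/JSON config file; keyword overrides win."""
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


# ---------------------------------------------------------------------------
# Stage 1: ingestion
# ---------------------------------------------------------------------------


def ingest(config: RunConfig):
    """Load and filter the three tables over one shared drug vocabulary."""
    if config.fixture_dir is not None:
        ds = synthetic_data.load_fixture(config.fixture_dir)
        ddi, mono, dpi = ds.ddi, ds.mono, ds.dpi
    else:
        ddi = io_ingest.load_pair_table(config.pairs_path, config.columns.get("pairs"))
        if config.drugs_path:
            drug_vocab = io_ingest.EntityVocabulary.load("drug", config.drugs_path)
        else:
            mono0 = io_ingest.load_drug_feature_table(
                config.mono_path, "mono_side_effect", dialect=config.columns.get("mono_side_effect")
            )
            dpi0 = io_ingest.load_drug_feature_table(
                config.dpi_path, "protein", dialect=config.columns.get("protein")
            )
            drug_vocab = io_ingest.EntityVocabulary.from_ids(
                "drug",
                set(ddi.drug_vocab.index_to_id)
                | set(mono0.row_vocab.index_to_id)
                | set(dpi0.row_vocab.index_to_id),
            )
        mono = io_ingest.load_drug_feature_table(
            config.mono_path, "mono_side_effect",
            drug_vocab=drug_vocab, dialect=config.columns.get("mono_side_effect"),
        )
        dpi = io_ingest.load_drug_feature_table(
            config.dpi_path, "protein",
            drug_vocab=drug_vocab, dialect=config.columns.get("protein"),
        )
    ddi = io_ingest.filter_side_effects(ddi, config.min_pairs)
    logger.info(
        "ingest: %d drugs, mono %s, dpi %s, %d pair records, %d side effects pass min_pairs=%d",
        len(mono.row_vocab), mono.shape, dpi.shape, len(ddi),
        len(ddi.side_effect_vocab), config.min_pairs,
    )
    return ddi, mono, dpi


# ---------------------------------------------------------------------------
# Stage 2: drug feature matrix
# ---------------------------------------------------------------------------


def build_drug_features(config: RunConfig, mono, dpi) -> features.DrugFeatureMatrix:
    if config.reducer == "pca":
        f1 = features.pca_reduce(mono, config.variance_threshold, "F1")
        f2 = features.pca_reduce(dpi, config.variance_threshold, "F2")
    else:
        f1 = features.low_variance_reduce(
            mono, min(config.low_variance_k, mono.shape[1]), "F1"
        )
        f2 = features.low_variance_reduce(
            dpi, min(config.low_variance_k, dpi.shape[1]), "F2"
        )
    fm = features.concat_blocks(f1, f2)
    logger.info(
        "features: reducer=%s k1=%d k2=%d width=%d", config.reducer, f1.k, f2.k, fm.width
    )
    return fm


# ---------------------------------------------------------------------------
# Stage 3: one side effect, one repetition
# ---------------------------------------------------------------------------


def _run_one(
    config: RunConfig,
    fm: features.DrugFeatureMatrix,
    drug_vocab: io_ingest.EntityVocabulary,
    side_effect: str,
    se_index: int,
    positives: list[tuple[int, int]],
    repetition: int,
):
    """All folds of one (side effect, repetition); independently seeded."""
    ss = np.random.SeedSequence([config.seed, se_index, repetition])
    sub_seeds = [int(s) for s in ss.generate_state(3, dtype=np.uint32)]
    examples = evaluation.sample_negatives(
        positives, drug_vocab, config.negative_ratio, seed=sub_seeds[0],
        side_effect=side_effect,
    )
    fold_assignment = evaluation.make_folds(len(examples), config.folds, seed=sub_seeds[1])
    x_all = features.pair_features(fm, examples.pairs, config.aggregation)
    y_all = examples.labels

    reports, traces, models = [], [], []
    for f, split in enumerate(fold_assignment.folds):
        cfg = neural_model.ModelConfig(
            input_width=x_all.shape[1],
            hidden_sizes=config.hidden_sizes,
            dropout_rate=config.dropout_rate,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            batch_size=config.batch_size,
            epochs=config.epochs,
            seed=sub_seeds[2] + f,
        )
        model = neural_model.init_model(cfg)
        model, trace = neural_model.train(
            model,
            x_all[split["train"]], y_all[split["train"]],
            x_all[split["val"]], y_all[split["val"]],
            cfg,
        )
        p_val = neural_model.forward(model, x_all[split["val"]])
        theta = evaluation.select_threshold(y_all[split["val"]], p_val)
        p_test = neural_model.forward(model, x_all[split["test"]])
        reports.append(
            evaluation.SideEffectReport.from_scores(
                f"{side_effect}|rep{repetition}|fold{f}",
                y_all[split["test"]], p_test, theta,
            )
        )
        traces.append(trace)
        models.append(model)
    return reports, traces, models, examples, fold_assignment


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True) + "\n"
    )
    try:
        ddi, mono, dpi = ingest(config)
    except Exception as exc:
        raise RuntimeError(f"stage ingest failed: {exc}") from exc
    try:
        fm = build_drug_features(config, mono, dpi)
    except Exception as exc:
        raise RuntimeError(f"stage features failed: {exc}") from exc

    drug_vocab = mono.row_vocab
    selected = (
        list(ddi.side_effect_vocab.index_to_id)
        if config.side_effects is None
        else [s for s in ddi.side_effect_vocab.index_to_id if s in set(config.side_effects)]
    )
    tasks = []
    for side_effect in selected:
        se_index = ddi.side_effect_vocab.index(side_effect)
        positives = [
            (drug_vocab.index(a), drug_vocab.index(b))
            for a, b in ddi.pairs_for(side_effect)
        ]
        for rep in range(config.repetitions):
            tasks.append((side_effect, se_index, positives, rep))

    def _task(side_effect, se_index, positives, rep):
        return _run_one(config, fm, drug_vocab, side_effect, se_index, positives, rep)

    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=config.n_jobs)(delayed(_task)(*t) for t in tasks)
    else:
        results = [_task(*t) for t in tasks]

    all_reports, all_traces = [], []
    for (side_effect, se_index, _, rep), (reports, traces, models, _, _) in zip(tasks, results):
        all_reports.extend(reports)
        all_traces.extend(traces)
        if config.save_models:
            for f, model in enumerate(models):
                neural_model.save_model(
                    model, out / "models" / f"{side_effect}_rep{rep}_fold{f}"
                )
        logger.info(
            "side effect %s rep %d: mean test AUROC %.3f",
            side_effect, rep, float(np.mean([r.auroc for r in reports])),
        )

    try:
        agg = evaluation.aggregate(all_reports, all_traces)
    except ValueError as exc:
        raise RuntimeError(f"stage aggregate failed: {exc}") from exc
    evaluation.write_reports(all_reports, out / "reports.tsv")
    evaluation.write_aggregate(agg, out / "aggregate")
    evaluation.write_traces(all_traces, [r.side_effect for r in all_reports], out / "traces.tsv")
    io_ingest.save_manifest(
        out / "run_manifest.json",
        {
            "n_drugs": len(drug_vocab),
            "mono_shape": list(mono.shape),
            "dpi_shape": list(dpi.shape),
            "k1": int(fm.block_boundary),
            "k2": int(fm.width - fm.block_boundary),
            "feature_width": int(fm.width),
            "pair_input_width": int(fm.width if config.aggregation == "sum" else 2 * fm.width),
            "side_effects": selected,
            "n_reports": len(all_reports),
            "seed": config.seed,
        },
    )
    logger.info(
        "run complete: %d reports, mean AUROC %.3f, mean theta %.3f",
        agg.n_reports, agg.metric_means["auroc"], agg.theta_mean,
    )
    return out


def recompute_aggregate(reports_tsv: str | Path) -> evaluation.AggregateReport:
    """Rebuild the aggregate from a per-side-effect report TSV.

    Used by the ``report`` subcommand and the self-consistency check: every
    number in the stored aggregate must be recoverable from the row file.
    """
    import pandas as pd

    frame = pd.read_csv(reports_tsv, sep="\t")
    reports = [
        evaluation.SideEffectReport(
            side_effect=str(r.side_effect), theta=float(r.theta),
            tp=int(r.tp), fp=int(r.fp), tn=int(r.tn), fn=int(r.fn),
            precision=float(r.precision), recall=float(r.recall),
            f_score=float(r.f_score), acc=float(r.acc), mcc=float(r.mcc),
            auroc=float(r.auroc), auprc=float(r.auprc),
        )
        for r in frame.itertuples(index=False)
    ]
    return evaluation.aggregate(reports)
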