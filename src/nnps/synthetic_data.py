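"""Seeded synthetic datasets with planted latent structure.

The generator emulates the *shape* of the real inputs — a sparse binary
drug x mono-side-effect matrix, a sparse binary drug x protein matrix, and
per-side-effect positive drug-pair lists — while planting a known latent
signal so the full pipeline's detection power is predictable:

* every drug gets a latent vector ``z_i ~ N(0, I)`` of dimension
  ``latent_dim``;
* every mono-side-effect and protein column gets a latent loading, and a
  binary entry is Bernoulli of a logistic in (loading . z_i), with the
  intercept solved numerically so the realized density matches
  ``feature_density``;
* every side effect gets a random direction ``w``, and pair (i, j) is
  positive with probability logistic(signal_strength x standardized
  w.(z_i + z_j) + intercept) — the *sum* z_i + z_j enters the label law, so
  the pipeline's summation aggregation is well-specified for this data.
  The intercept targets slightly more expected positives than requested and
  the draw is then thinned uniformly to exactly
  ``positive_pairs_per_effect`` pairs.

With ``signal_strength = 0`` labels are independent of all features (the
null case); raising it makes the planted signal, and hence the attainable
AUROC, stronger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io_ingest import (
    DEFAULT_DIALECTS,
    BinaryMatrix,
    DDITable,
    EntityVocabulary,
    load_drug_feature_table,
    load_pair_table,
    save_manifest,
)

#: Standard deviation of the per-column feature logits before the intercept;
#: 2.0 makes individual binary columns clearly (but noisily) informative
#: about the latent vector, mimicking sparse side-effect/target profiles.
FEATURE_LOGIT_SCALE = 2.0

#: The label-law intercept targets this multiple of the requested positive
#: count before thinning, so the realized count hits the cap essentially
#: always while each pair's inclusion stays logistic in the planted score.
POSITIVE_OVERSHOOT = 1.1


@dataclass
class SyntheticSpec:
    """Dimensions and strengths of one synthetic dataset."""

    n_drugs: int = 200
    n_proteins: int = 60
    n_mono_effects: int = 120
    n_side_effects: int = 5
    latent_dim: int = 8
    signal_strength: float = 3.0
    positive_pairs_per_effect: int = 1000
    feature_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_drugs, self.n_proteins, self.n_mono_effects,
            self.n_side_effects, self.latent_dim, self.positive_pairs_per_effect,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not 0 < self.feature_density < 1:
            raise ValueError("feature_density must be in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")


@dataclass
class SyntheticDataset:
    """In-memory synthetic inputs plus the latent truth that generated them."""

    spec: SyntheticSpec
    mono: BinaryMatrix
    dpi: BinaryMatrix
    ddi: DDITable
    latent: np.ndarray  # n_drugs x latent_dim


def _solve_intercept(logits: np.ndarray, target_mean: float) -> float:
    """Intercept b with mean(expit(logits + b)) == target_mean."""
    return float(brentq(lambda b: expit(logits + b).mean() - target_mean, -60.0, 60.0))


def _binary_from_latent(
    latent: np.ndarray, n_cols: int, density: float, rng: np.random.Generator
) -> np.ndarray:
    d = latent.shape[1]
    loadings = rng.normal(0.0, FEATURE_LOGIT_SCALE / np.sqrt(d), size=(d, n_cols))
    logits = latent @ loadings
    b = _solve_intercept(logits, density)
    return (rng.random(logits.shape) < expit(logits + b)).astype(np.int8)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_drugs
    total_pairs = n * (n - 1) // 2
    if spec.positive_pairs_per_effect > total_pairs:
        raise ValueError(
            f"{spec.positive_pairs_per_effect} positives requested but only "
            f"{total_pairs} drug pairs exist"
        )

    width = len(str(n - 1))
    drug_ids = tuple(f"D{i:0{width}d}" for i in range(n))
    drug_vocab = EntityVocabulary.from_ids("drug", drug_ids)
    latent = rng.normal(size=(n, spec.latent_dim))

    mono_dense = _binary_from_latent(latent, spec.n_mono_effects, spec.feature_density, rng)
    dpi_dense = _binary_from_latent(latent, spec.n_proteins, spec.feature_density, rng)
    mono = BinaryMatrix(
        mono_dense,
        drug_vocab,
        EntityVocabulary.from_ids(
            "mono_side_effect",
            (f"E{c:0{len(str(spec.n_mono_effects - 1))}d}" for c in range(spec.n_mono_effects)),
        ),
    )
    dpi = BinaryMatrix(
        dpi_dense,
        drug_vocab,
        EntityVocabulary.from_ids(
            "protein",
            (f"P{c:0{len(str(spec.n_proteins - 1))}d}" for c in range(spec.n_proteins)),
        ),
    )

    # canonical pair index arrays (i < j)
    iu, ju = np.triu_indices(n, k=1)
    pair_sums = latent[iu] + latent[ju]  # total_pairs x latent_dim

    target_expected = min(POSITIVE_OVERSHOOT * spec.positive_pairs_per_effect, 0.99 * total_pairs)
    records: list[tuple[str, str, str]] = []
    for s in range(spec.n_side_effects):
        w = rng.normal(size=spec.latent_dim)
        score = pair_sums @ w
        b = _solve_intercept(spec.signal_strength * score, target_expected / total_pairs)
        prob = expit(spec.signal_strength * score + b)
        drawn = np.flatnonzero(rng.random(total_pairs) < prob)
        if len(drawn) > spec.positive_pairs_per_effect:
            drawn = rng.choice(drawn, size=spec.positive_pairs_per_effect, replace=False)
        sid = f"S{s:0{len(str(spec.n_side_effects - 1))}d}"
        for k in drawn:
            records.append((drug_ids[iu[k]], drug_ids[ju[k]], sid))

    return SyntheticDataset(spec, mono, dpi, DDITable.from_records(records), latent)


# ---------------------------------------------------------------------------
# Fixture files (the same TSV dialects the ingestion module consumes)
# ---------------------------------------------------------------------------


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write pairs/mono/DPI TSVs, the drug vocabulary and a spec manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs": directory / "pairs.tsv",
        "mono": directory / "mono_side_effects.tsv",
        "dpi": directory / "drug_protein.tsv",
        "drugs": directory / "drugs.tsv",
        "effects": directory / "mono_effect_vocab.tsv",
        "proteins": directory / "protein_vocab.tsv",
        "manifest": directory / "manifest.json",
    }
    dataset.ddi.save(paths["pairs"])
    d_mono = DEFAULT_DIALECTS["mono_side_effect"]
    with open(paths["mono"], "w", encoding="utf-8") as fh:
        fh.write(f"{d_mono['drug']}\t{d_mono['feature']}\n")
        for drug, feat in dataset.mono.triplets():
            fh.write(f"{drug}\t{feat}\n")
    d_dpi = DEFAULT_DIALECTS["protein"]
    with open(paths["dpi"], "w", encoding="utf-8") as fh:
        fh.write(f"{d_dpi['drug']}\t{d_dpi['feature']}\n")
        for drug, feat in dataset.dpi.triplets():
            fh.write(f"{drug}\t{feat}\n")
    dataset.mono.row_vocab.save(paths["drugs"])
    # column vocabularies too, so all-zero feature columns survive a reload
    dataset.mono.col_vocab.save(paths["effects"])
    dataset.dpi.col_vocab.save(paths["proteins"])
    save_manifest(paths["manifest"], {"spec": asdict(dataset.spec)})
    return paths


def load_fixture(directory: str | Path) -> SyntheticDataset:
    """Re-read a fixture directory; inverse of :func:`write_fixture`.

    The returned dataset carries no latent matrix (shape (0, 0)): the files
    are exactly what a real-data run would see.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = SyntheticSpec(**manifest["spec"])
    drug_vocab = EntityVocabulary.load("drug", directory / "drugs.tsv")
    mono = load_drug_feature_table(
        directory / "mono_side_effects.tsv", "mono_side_effect",
        drug_vocab=drug_vocab,
        col_vocab=EntityVocabulary.load("mono_side_effect", directory / "mono_effect_vocab.tsv"),
    )
    dpi = load_drug_feature_table(
        directory / "drug_protein.tsv", "protein",
        drug_vocab=drug_vocab,
        col_vocab=EntityVocabulary.load("protein", directory / "protein_vocab.tsv"),
    )
    ddi = load_pair_table(directory / "pairs.tsv")
    return SyntheticDataset(spec, mono, dpi, ddi, np.empty((0, 0)))
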