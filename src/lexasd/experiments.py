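"""Standard study configurations and benchmark runners.

The synthetic benchmarks exercised here define the package's operating
conditions: a strong-effect parameter-recovery benchmark, a null-calibration
benchmark, and a rule-deterministic annotator-recovery benchmark.  The DNN
widths and epoch counts used by the benchmarks are scaled to small synthetic
corpora (the reference hyperparameters — width 300, 50 epochs — remain the
config defaults for full-size runs).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import synth
from .annotator import (
    AnnotatorConfig, annotate, dataset_annotation_metrics, train_annotator,
)
from .classify import ClassifierConfig, train_classifier
from .corpus import Dataset
from .evalstats import auc_score, confusion_metrics, loocv_run
from .schema import TagSchema, default_schema


def small_classifier_config(variant: str, seed: int = 0, **overrides) -> ClassifierConfig:
    """DNN classifier sized for small synthetic corpora."""
    defaults = dict(
        variant=variant, embedding_dim=32, hidden_dim=32, epochs=30,
        batch_size=16, seed=seed,
    )
    defaults.update(overrides)
    return ClassifierConfig(**defaults)


def small_annotator_config(seed: int = 0, **overrides) -> AnnotatorConfig:
    defaults = dict(
        embedding_dim=24, hidden_dim=24, epochs=20, batch_size=8, seed=seed,
    )
    defaults.update(overrides)
    return AnnotatorConfig(**defaults)


def binomial_null_band(n: int, level: float = 0.99) -> tuple[float, float]:
    """Central ``level`` band of accuracy under Binomial(n, 1/2) guessing."""
    alpha = (1.0 - level) / 2
    lo = stats.binom.ppf(alpha, n, 0.5) / n
    hi = stats.binom.isf(alpha, n, 0.5) / n
    return float(lo), float(hi)


def train_test_split_stratified(
    dataset: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in ("AS", "nonAS"):
        idx = [i for i, d in enumerate(dataset) if d.label == label]
        idx = list(rng.permutation(idx))
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx += idx[:n_test]
        train_idx += idx[n_test:]
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# Strong-effect parameter recovery
# ---------------------------------------------------------------------------

def run_strong_tag_linear(seed: int = 0, schema: TagSchema | None = None) -> dict:
    """Strong-effect benchmark for the interpretable tag-frequency model.

    Returns LOOCV accuracy (manual-annotation path) and the fraction of
    implicated tags whose full-data coefficient sign matches the injected
    (reduced-in-AS, hence negative) direction.
    """
    schema = schema or default_schema()
    cfg = synth.benchmark_strong_config(schema, seed=seed)
    data = synth.generate_corpus(cfg, schema)
    records = loocv_run(
        data, ClassifierConfig(variant="tag_linear", seed=seed),
        annotator_config="oracle", base_seed=seed, schema=schema,
    )
    metrics = confusion_metrics(records)
    clf = train_classifier(data, ClassifierConfig(variant="tag_linear", seed=seed), schema)
    implicated = synth.benchmark_implicated_tags(schema)
    signs = clf.coefficients[implicated]
    return {
        "accuracy": metrics.accuracy,
        "auc": metrics.auc,
        "n": metrics.n,
        "sign_recovery": float(np.mean(signs < 0)),
        "n_implicated": len(implicated),
    }


def run_strong_text_tag_dnn(
    seed: int = 0, schema: TagSchema | None = None, epochs: int = 30
) -> dict:
    """Held-out AUC of the tag+text Bi-LSTM on an 80/20 split of the
    strong-effect benchmark corpus."""
    schema = schema or default_schema()
    cfg = synth.benchmark_strong_config(schema, seed=seed)
    data = synth.generate_corpus(cfg, schema)
    train, test = train_test_split_stratified(data, 0.2, seed)
    clf_cfg = small_classifier_config("text_tag_dnn", seed=seed, epochs=epochs)
    clf = train_classifier(train, clf_cfg, schema)
    from .classify import predict_proba

    y = np.array([d.label == "AS" for d in test])
    p = np.array([predict_proba(clf, d, schema) for d in test])
    acc = float(np.mean((p >= 0.5) == y))
    return {"auc": auc_score(y, p), "accuracy": acc, "n_test": len(test)}


def run_strong_dnn_loocv(
    seed: int = 0,
    schema: TagSchema | None = None,
    n_per_group: int = 15,
    variant: str = "text_tag_dnn",
    epochs: int = 15,
    learning_rate: float = 0.01,
) -> dict:
    """Reduced-size LOOCV of a DNN variant on strong-effect data."""
    schema = schema or default_schema()
    cfg = synth.benchmark_strong_config(
        schema, n_as=n_per_group, n_non_as=n_per_group, seed=seed
    )
    data = synth.generate_corpus(cfg, schema)
    clf_cfg = small_classifier_config(
        variant, seed=seed, epochs=epochs, embedding_dim=16, hidden_dim=16,
        learning_rate=learning_rate,
    )
    records = loocv_run(
        data, clf_cfg, annotator_config="oracle", base_seed=seed, schema=schema
    )
    m = confusion_metrics(records)
    return {"accuracy": m.accuracy, "auc": m.auc, "n": m.n}


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def run_null_calibration(
    seed: int = 0,
    schema: TagSchema | None = None,
    n_per_group: int = 12,
    variants: tuple[str, ...] = ("tag_linear", "tag_dnn", "text_dnn", "text_tag_dnn"),
    epochs: int = 20,
    learning_rate: float = 0.02,
) -> dict:
    """LOOCV accuracy of every variant on a no-signal corpus.

    With all effect multipliers at 1 and zero word-tag coupling, each
    variant's accuracy should fall inside the central 99% binomial band
    around 0.5 (returned alongside the accuracies).
    """
    schema = schema or default_schema()
    cfg = synth.null_config(
        schema, n_as=n_per_group, n_non_as=n_per_group, length_mean=60.0, seed=seed
    )
    data = synth.generate_corpus(cfg, schema)
    accuracies: dict[str, float] = {}
    for variant in variants:
        if variant == "tag_linear":
            clf_cfg = ClassifierConfig(variant=variant, seed=seed)
        else:
            clf_cfg = small_classifier_config(
                variant, seed=seed, epochs=epochs, embedding_dim=16, hidden_dim=16,
                learning_rate=learning_rate,
            )
        records = loocv_run(
            data, clf_cfg, annotator_config="oracle", base_seed=seed, schema=schema
        )
        accuracies[variant] = confusion_metrics(records).accuracy
    lo, hi = binomial_null_band(len(data))
    return {"accuracies": accuracies, "band": (lo, hi), "n": len(data)}


# ---------------------------------------------------------------------------
# Annotator recovery
# ---------------------------------------------------------------------------

def annotator_recovery_config(schema: TagSchema, seed: int = 0) -> synth.GeneratorConfig:
    """Rule-deterministic corpus: at most one tag per word, coupling 1, so a
    word's surface identifies its tag exactly."""
    base = np.zeros(schema.tag_count)
    base[synth.benchmark_implicated_tags(schema, 10)] = 0.04
    return synth.GeneratorConfig(
        n_as=16, n_non_as=16, length_mean=60.0, base_rates=base,
        coupling=1.0, exclusive_tags=True, seed=seed,
    )


def run_annotator_recovery(seed: int = 0, schema: TagSchema | None = None) -> dict:
    """Train the tagger on a rule-deterministic corpus and score micro-F1 on
    freshly generated held-out documents."""
    schema = schema or default_schema()
    cfg = annotator_recovery_config(schema, seed=seed)
    train = synth.generate_corpus(cfg, schema)
    heldout_cfg = annotator_recovery_config(schema, seed=seed + 10_000)
    heldout_cfg.n_as = heldout_cfg.n_non_as = 4
    heldout = synth.generate_corpus(heldout_cfg, schema)
    # rare positive cells (~0.3% of word-tag pairs) need many small-batch
    # Adam steps and a raised learning rate to clear the 0.5 threshold
    ann_cfg = small_annotator_config(
        seed=seed, epochs=120, batch_size=4, learning_rate=0.02
    )
    model = train_annotator(train, ann_cfg, schema)
    return dataset_annotation_metrics(model, heldout)
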