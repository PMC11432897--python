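"""Nested leave-one-out evaluation protocol and statistics.

For each document n of an N-document dataset the protocol holds n out, trains
the automatic tagger on the remaining N-1 manually tagged documents, tags the
held-out tokens with it, trains the classifier on the same N-1 documents
(always on manual tags), and scores the held-out document twice: under its
manual tags and under the automatic tags.  Pooling the N held-out predictions
yields accuracy, precision, sensitivity, specificity (AS positive, threshold
0.5) with Wald 95% confidence intervals, and a threshold-free AUC
(Wilcoxon-Mann-Whitney with midrank ties).  Paired classifiers are compared
with the McNemar test on discordant counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import annotator as annot_mod
from . import classify as classify_mod
from .classify import ClassifierConfig, TAG_VARIANTS
from .annotator import AnnotatorConfig
from .corpus import Dataset
from .schema import TagSchema, default_schema

Z_95 = 1.96


@dataclass
class FoldRecord:
    doc_id: str
    y_true: str                  # "AS" | "nonAS"
    p_manual: float
    p_auto: float
    fold_seed: int


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    auc: float | None
    n: int = field(init=False)
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        self.n = self.tp + self.fp + self.fn + self.tn
        self.accuracy = (self.tp + self.tn) / self.n if self.n else 0.0
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.sensitivity = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        self.specificity = self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0


@dataclass
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return round(self.lower, ndigits), round(self.upper, ndigits)


@dataclass
class McNemarResult:
    b: int          # correct only by model 1
    c: int          # correct only by model 2
    statistic: float
    p_value: float
    method: str


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def loocv_run(
    dataset: Dataset,
    classifier_config: ClassifierConfig,
    annotator_config: AnnotatorConfig | str = "oracle",
    base_seed: int = 0,
    schema: TagSchema | None = None,
    fold_callback=None,
) -> list[FoldRecord]:
    """Run the nested leave-one-out protocol; returns one record per document.

    ``annotator_config`` may be an :class:`AnnotatorConfig` (train the tagger
    on each fold's training set and tag the held-out tokens with it) or the
    string ``"oracle"`` (reuse the manual tags as the automatic ones, i.e.
    p_auto == p_manual; used when only the manual-annotation path is under
    study).  Fold n uses seed ``base_seed + n`` for both models.
    ``fold_callback(n, train_ids, test_id)`` is invoked per fold (audit hook).
    """
    schema = schema or default_schema()
    N = len(dataset)
    if N < 3:
        raise ValueError(f"LOOCV needs at least 3 documents, got {N}")
    for doc in dataset:
        if doc.label not in ("AS", "nonAS"):
            raise ValueError(f"document {doc.id!r} is unlabeled")
        if doc.tags is None:
            raise ValueError(f"document {doc.id!r} has no manual tags")

    variant = classifier_config.variant
    records: list[FoldRecord] = []
    for n in range(N):
        fold_seed = base_seed + n
        train_idx = [i for i in range(N) if i != n]
        train = dataset.subset(train_idx)
        test_doc = dataset[n]
        if fold_callback is not None:
            fold_callback(n, [d.id for d in train], test_doc.id)

        clf_cfg = _reseed(classifier_config, fold_seed)
        clf = classify_mod.train_classifier(train, clf_cfg, schema)
        p_manual = classify_mod.predict_proba(clf, test_doc, schema)

        if variant in TAG_VARIANTS:
            if annotator_config == "oracle":
                # oracle tagger: the manual tags re-enter through the
                # automatic-annotation path, so p_auto must equal p_manual
                auto_doc = test_doc.with_tags(test_doc.tags, "auto")
                p_auto = classify_mod.predict_proba(clf, auto_doc, schema)
            else:
                ann_cfg = _reseed(annotator_config, fold_seed)
                tagger = annot_mod.train_annotator(train, ann_cfg, schema)
                auto_doc = annot_mod.annotate_document(tagger, test_doc)
                p_auto = classify_mod.predict_proba(clf, auto_doc, schema)
        else:
            p_auto = p_manual  # text-only model carries one probability
        records.append(
            FoldRecord(
                doc_id=test_doc.id, y_true=test_doc.label,
                p_manual=p_manual, p_auto=p_auto, fold_seed=fold_seed,
            )
        )
    return records


def _reseed(config, seed: int):
    from dataclasses import replace

    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """Wilcoxon-Mann-Whitney AUC with midrank ties; None if one class only."""
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(scores)  # midranks
    rank_sum = ranks[y_true].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(
    records: list[FoldRecord], use_auto: bool = False, threshold: float = 0.5
) -> ConfusionMetrics:
    if not records:
        raise ValueError("no fold records")
    y = np.array([r.y_true == "AS" for r in records])
    p = np.array([r.p_auto if use_auto else r.p_manual for r in records])
    pred = p >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, auc=auc_score(y, p))


def correct_vector(
    records: list[FoldRecord], use_auto: bool = False, threshold: float = 0.5
) -> np.ndarray:
    y = np.array([r.y_true == "AS" for r in records])
    p = np.array([r.p_auto if use_auto else r.p_manual for r in records])
    return (p >= threshold) == y


def wald_ci(point: float, n: int, level: float = 0.95) -> IntervalEstimate:
    """Wald interval point +/- z * sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= point <= 1.0:
        raise ValueError("point must lie in [0, 1]")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(point * (1.0 - point) / n)
    return IntervalEstimate(
        point=point,
        lower=max(0.0, point - half),
        upper=min(1.0, point + half),
        level=level,
    )


# ---------------------------------------------------------------------------
# Paired and contingency tests
# ---------------------------------------------------------------------------

def chi2_pvalue_from_statistic(statistic: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value for a printed test statistic."""
    return float(stats.chi2.sf(statistic, df))


def mcnemar_test(
    correct1,
    correct2,
    method: str = "auto",
    exact_threshold: int = 25,
) -> McNemarResult:
    """McNemar test on two paired correctness vectors.

    b counts samples only model 1 got right, c those only model 2 got right.
    Methods: ``chi2`` ((b-c)^2/(b+c)), ``chi2_corrected`` (continuity
    corrected), ``exact`` (two-sided binomial), or ``auto``
    (continuity-corrected chi-square, falling back to exact when
    b + c < ``exact_threshold``).  With no discordant pairs the statistic is
    0 and p is 1.
    """
    correct1 = np.asarray(correct1, dtype=bool)
    correct2 = np.asarray(correct2, dtype=bool)
    if correct1.shape != correct2.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(correct1 & ~correct2))
    c = int(np.sum(~correct1 & correct2))
    if method == "auto":
        method = "exact" if b + c < exact_threshold else "chi2_corrected"
    if method not in ("chi2", "chi2_corrected", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if b + c == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0, method=method)
    if method == "exact":
        k = min(b, c)
        p = float(stats.binomtest(k, b + c, 0.5, alternative="two-sided").pvalue)
        return McNemarResult(b=b, c=c, statistic=float(k), p_value=min(p, 1.0),
                             method=method)
    if method == "chi2":
        statistic = (b - c) ** 2 / (b + c)
    else:
        statistic = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    return McNemarResult(
        b=b, c=c, statistic=float(statistic),
        p_value=chi2_pvalue_from_statistic(statistic), method=method,
    )


def mcnemar_from_records(
    records1: list[FoldRecord],
    records2: list[FoldRecord],
    use_auto: bool = False,
    method: str = "auto",
) -> McNemarResult:
    ids1 = [r.doc_id for r in records1]
    ids2 = [r.doc_id for r in records2]
    if ids1 != ids2:
        raise ValueError("fold records do not cover the same documents in order")
    return mcnemar_test(
        correct_vector(records1, use_auto), correct_vector(records2, use_auto),
        method=method,
    )


def chi2_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    statistic, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(statistic), float(p)


# ---------------------------------------------------------------------------
# Report building
# ---------------------------------------------------------------------------

#: The paired comparisons reported for the protocol, in order.
MCNEMAR_PAIRS = (
    ("tag_linear", "tag_dnn"),
    ("tag_dnn", "text_tag_dnn"),
    ("text_dnn", "text_tag_dnn"),
)


def metrics_row(records: list[FoldRecord], use_auto: bool) -> dict:
    m = confusion_metrics(records, use_auto=use_auto)
    ci = wald_ci(m.accuracy, m.n)
    lo, hi = ci.rounded(2)
    return {
        "n": m.n,
        "accuracy": round(m.accuracy, 2),
        "ci_lower": lo,
        "ci_upper": hi,
        "precision": round(m.precision, 2),
        "sensitivity": round(m.sensitivity, 2),
        "specificity": round(m.specificity, 2),
        "auc": round(m.auc, 2) if m.auc is not None else None,
    }


def build_report(
    fold_records: dict[tuple[str, str], list[FoldRecord]],
    mcnemar_method: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the metric table and the pairwise McNemar table.

    ``fold_records`` maps (task, variant) to that run's fold records.  The
    metric table has one row per (task, variant, annotation source); the
    McNemar table compares the standard variant pairs available per task and
    annotation source.  All proportions are rounded to 2 decimals.
    """
    if not fold_records:
        raise ValueError("no fold records supplied")
    metric_rows = []
    for (task, variant), records in fold_records.items():
        sources = ("manual",) if variant == "text_dnn" else ("manual", "auto")
        for source in sources:
            row = {"task": task, "variant": variant, "annotation": source}
            row |= metrics_row(records, use_auto=source == "auto")
            metric_rows.append(row)
    metrics = pd.DataFrame(metric_rows)

    test_rows = []
    tasks = {task for task, _ in fold_records}
    for task in sorted(tasks):
        for v1, v2 in MCNEMAR_PAIRS:
            r1 = fold_records.get((task, v1))
            r2 = fold_records.get((task, v2))
            if r1 is None or r2 is None:
                continue
            for source in ("manual", "auto"):
                res = mcnemar_from_records(
                    r1, r2, use_auto=source == "auto", method=mcnemar_method
                )
                test_rows.append(
                    {
                        "task": task, "model_1": v1, "model_2": v2,
                        "annotation": source, "b": res.b, "c": res.c,
                        "statistic": round(res.statistic, 2),
                        "p_value": round(res.p_value, 2),
                        "method": res.method,
                    }
                )
    tests = pd.DataFrame(test_rows)
    return metrics, tests


def records_to_frame(records: list[FoldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "doc_id": [r.doc_id for r in records],
            "y_true": [r.y_true for r in records],
            "p_manual": [r.p_manual for r in records],
            "p_auto": [r.p_auto for r in records],
            "fold_seed": [r.fold_seed for r in records],
        }
    )
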