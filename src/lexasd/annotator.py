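"""Automatic lexicogrammatical tagging as multi-label sequence labelling.

A single-layer Bi-LSTM over learned word embeddings emits, for every token,
147 independent sigmoid scores — one per tag type.  A tag is predicted active
when its score strictly exceeds the decision threshold.  Training minimises
per-token, per-tag binary cross-entropy; padded positions never enter the
loss.  The reference hyperparameters (embedding and hidden width 300, 50
epochs, batch 32, Adam at lr 0.001, threshold 0.5) are the defaults; smaller
widths train in seconds on synthetic corpora and are used throughout the test
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .corpus import Dataset, Document
from .schema import TagSchema, default_schema

PAD, UNK = 0, 1


@dataclass
class AnnotatorConfig:
    embedding_dim: int = 300
    hidden_dim: int = 300
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    threshold: float = 0.5
    min_token_freq: int = 1  # tokens rarer than this map to UNK at train time
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.hidden_dim, self.epochs, self.batch_size) <= 0:
            raise ValueError("dims, epochs and batch size must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class AnnotatorModel:
    config: AnnotatorConfig
    vocab: dict[str, int]  # word -> embedding row; PAD=0, UNK=1
    params: dict[str, np.ndarray]
    n_tags: int

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.vocab.get(w, UNK) for w in tokens], dtype=np.int64)


def build_vocab(dataset: Dataset, min_freq: int = 1) -> dict[str, int]:
    freq: dict[str, int] = {}
    for doc in dataset:
        for w in doc.tokens:
            freq[w] = freq.get(w, 0) + 1
    vocab = {"<pad>": PAD, "<unk>": UNK}
    for w in sorted(freq, key=lambda w: (-freq[w], w)):
        if freq[w] >= min_freq:
            vocab[w] = len(vocab)
    return vocab


def _pad_batch(
    seqs: list[np.ndarray], tag_mats: list[np.ndarray] | None, n_tags: int
):
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    L = int(lengths.max())
    B = len(seqs)
    ids = np.zeros((B, L), dtype=np.int64)
    mask = np.zeros((B, L, 1))
    targets = np.zeros((B, L, n_tags)) if tag_mats is not None else None
    for b, seq in enumerate(seqs):
        ids[b, : len(seq)] = seq
        mask[b, : len(seq)] = 1.0
        if tag_mats is not None:
            targets[b, : len(seq)] = tag_mats[b]
    return ids, lengths, mask, targets


def train_annotator(
    train: Dataset,
    config: AnnotatorConfig | None = None,
    schema: TagSchema | None = None,
) -> AnnotatorModel:
    """Train the tagger on manually annotated documents.

    Runs exactly ``config.epochs`` epochs; epoch shuffling and parameter
    initialisation derive from ``config.seed``, so training is bitwise
    reproducible on one device.
    """
    config = config or AnnotatorConfig()
    schema = schema or default_schema()
    if len(train) == 0:
        raise ValueError("training set is empty")
    for doc in train:
        if doc.tags is None:
            raise ValueError(f"document {doc.id!r} lacks a tag matrix")
    n_tags = schema.tag_count

    rng = np.random.default_rng(config.seed)
    vocab = build_vocab(train, config.min_token_freq)
    d, h = config.embedding_dim, config.hidden_dim
    params: dict[str, np.ndarray] = {
        "emb": rng.normal(0.0, 0.1, size=(len(vocab), d)),
    }
    params |= nn.bilstm_init(rng, d, h)
    out = nn.linear_init(rng, 2 * h, n_tags)
    params["out_W"], params["out_b"] = out["W"], out["b"]

    seqs = [
        np.array([vocab.get(w, UNK) for w in doc.tokens], dtype=np.int64)
        for doc in train
    ]
    tag_mats = [doc.tags.astype(np.float64) for doc in train]

    opt = nn.Adam(params, lr=config.learning_rate)
    for _ in range(config.epochs):
        for batch in nn.minibatch_indices(len(seqs), config.batch_size, rng):
            ids, lengths, mask, targets = _pad_batch(
                [seqs[i] for i in batch], [tag_mats[i] for i in batch], n_tags
            )
            x = params["emb"][ids]
            h_tok, _, cache = nn.bilstm_forward(x, lengths, params)
            logits = h_tok @ params["out_W"] + params["out_b"]
            _, g = nn.bce_with_logits(logits, targets)
            g = g * mask / (mask.sum() * n_tags)  # mean over real cells
            grads = {
                "out_W": np.einsum("blh,blc->hc", h_tok, g),
                "out_b": g.sum((0, 1)),
            }
            d_tok = g @ params["out_W"].T
            bi_grads, dx = nn.bilstm_backward(d_tok, None, cache, params)
            grads |= bi_grads
            d_emb = np.zeros_like(params["emb"])
            np.add.at(d_emb, ids.ravel(), dx.reshape(-1, d))
            grads["emb"] = d_emb
            opt.step(grads)

    return AnnotatorModel(config=config, vocab=vocab, params=params, n_tags=n_tags)


def tag_scores(model: AnnotatorModel, tokens: list[str]) -> np.ndarray:
    """Per-token sigmoid scores, shape (L, n_tags)."""
    if len(tokens) < 1:
        raise ValueError("token list must be non-empty")
    ids = model.encode(tokens)[None, :]
    lengths = np.array([len(tokens)])
    x = model.params["emb"][ids]
    h_tok, _, _ = nn.bilstm_forward(x, lengths, model.params)
    logits = h_tok[0] @ model.params["out_W"] + model.params["out_b"]
    return nn.sigmoid(logits)


def annotate(model: AnnotatorModel, tokens: list[str]) -> np.ndarray:
    """Binary (L, n_tags) matrix; a cell is 1 iff its score strictly exceeds
    the decision threshold.  Unknown words map to the UNK embedding."""
    return (tag_scores(model, tokens) > model.config.threshold).astype(np.uint8)


def annotate_document(model: AnnotatorModel, doc: Document) -> Document:
    return doc.with_tags(annotate(model, doc.tokens), "auto")


def annotation_metrics(pred: np.ndarray, gold: np.ndarray) -> dict[str, float]:
    """Micro-averaged precision, recall and F1 over all (word, tag) cells.

    Conventions: any metric with a zero denominator is 0.
    """
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gold.shape}")
    tp = int(np.sum((pred == 1) & (gold == 1)))
    fp = int(np.sum((pred == 1) & (gold == 0)))
    fn = int(np.sum((pred == 0) & (gold == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def dataset_annotation_metrics(
    model: AnnotatorModel, docs: Dataset
) -> dict[str, float]:
    """Micro metrics pooled over all documents (equals pooled-count metrics)."""
    tp = fp = fn = 0
    for doc in docs:
        m = annotation_metrics(annotate(model, doc.tokens), doc.tags)
        tp += m["tp"]; fp += m["fp"]; fn += m["fn"]
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}
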