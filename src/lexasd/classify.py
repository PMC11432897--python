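"""AS vs non-AS differentiation models.

Four variants, all producing P(AS) for a document:

``tag_linear``
    L2-regularised logistic regression on the tag-frequency vector
    (per-tag active-word count / total words).  Order-free and fully
    interpretable: the fitted coefficients are exposed.
``tag_dnn``
    Per word, the embeddings of its active tags are summed (an empty tag set
    gives a zero row); the resulting L x d sequence feeds a Bi-LSTM whose
    last state (forward state at the final token || backward state at the
    first token) goes through a fully connected layer to a single sigmoid.
``text_dnn``
    Identical architecture with learned word embeddings as input.
``text_tag_dnn``
    Per-timestep concatenation of tag and word embeddings (width 2d).

All DNN variants train for exactly ``epochs`` epochs with Adam; no early
stopping, no validation split, no pretrained embeddings.  AS is the positive
class throughout and the decision threshold is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .annotator import PAD, UNK, build_vocab
from .corpus import Dataset, Document, frequency_matrix
from .schema import TagSchema, default_schema

VARIANTS = ("tag_linear", "tag_dnn", "text_dnn", "text_tag_dnn")
TAG_VARIANTS = ("tag_linear", "tag_dnn", "text_tag_dnn")
TEXT_VARIANTS = ("text_dnn", "text_tag_dnn")


@dataclass
class ClassifierConfig:
    variant: str = "tag_linear"
    embedding_dim: int = 300
    hidden_dim: int = 300
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    threshold: float = 0.5
    l2_penalty: float = 0.01  # tag_linear only; weak by default
    min_token_freq: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if min(self.embedding_dim, self.hidden_dim, self.epochs, self.batch_size) <= 0:
            raise ValueError("dims, epochs and batch size must be positive")
        if self.l2_penalty <= 0:
            raise ValueError("l2_penalty must be positive")


@dataclass
class TrainedClassifier:
    variant: str
    config: ClassifierConfig
    n_tags: int
    # tag_linear
    coef: np.ndarray | None = None       # (C,) log-odds per unit tag frequency
    intercept: float | None = None
    # DNN variants
    params: dict[str, np.ndarray] | None = None
    vocab: dict[str, int] | None = None  # text variants only

    @property
    def coefficients(self) -> np.ndarray:
        if self.coef is None:
            raise AttributeError(f"{self.variant} has no linear coefficients")
        return self.coef


def embed_tags(tag_matrix: np.ndarray, tag_table: np.ndarray) -> np.ndarray:
    """Sum of the active tags' embedding rows for each word: (L, d).

    A word with no active tags gets the zero vector (empty sum).
    """
    tag_matrix = np.asarray(tag_matrix)
    if tag_matrix.ndim != 2 or tag_matrix.shape[1] != tag_table.shape[0]:
        raise ValueError(
            f"tag matrix shape {tag_matrix.shape} incompatible with table "
            f"{tag_table.shape}"
        )
    return tag_matrix.astype(np.float64) @ tag_table


def _labels_to_y(docs: Dataset) -> np.ndarray:
    y = np.array([1.0 if d.label == "AS" else 0.0 for d in docs])
    for d in docs:
        if d.label == "unknown":
            raise ValueError(f"document {d.id!r} is unlabeled")
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    return y


def _check_requirements(docs, variant: str) -> None:
    if variant in TAG_VARIANTS:
        for d in docs:
            if d.tags is None:
                raise ValueError(
                    f"variant {variant} requires tag matrices; document "
                    f"{d.id!r} has none"
                )


def train_classifier(
    train: Dataset,
    config: ClassifierConfig | None = None,
    schema: TagSchema | None = None,
) -> TrainedClassifier:
    config = config or ClassifierConfig()
    schema = schema or default_schema()
    _check_requirements(train, config.variant)
    y = _labels_to_y(train)

    if config.variant == "tag_linear":
        X = frequency_matrix(train, schema)
        lr = LogisticRegression(
            C=1.0 / config.l2_penalty, solver="lbfgs", max_iter=5000
        )
        lr.fit(X, y)
        return TrainedClassifier(
            variant="tag_linear", config=config, n_tags=schema.tag_count,
            coef=lr.coef_[0].copy(), intercept=float(lr.intercept_[0]),
        )
    return _train_dnn(train, y, config, schema)


def _input_width(variant: str, d: int) -> int:
    return 2 * d if variant == "text_tag_dnn" else d


def _batch_inputs(
    docs: list[Document],
    variant: str,
    params: dict[str, np.ndarray],
    vocab: dict[str, int] | None,
):
    """Build padded (B, L, din) inputs plus the pieces backprop needs."""
    lengths = np.array([d.n_tokens for d in docs], dtype=np.int64)
    B, L = len(docs), int(lengths.max())
    tag_mats = None
    ids = None
    if variant in ("tag_dnn", "text_tag_dnn"):
        C = params["tag_table"].shape[0]
        tag_mats = np.zeros((B, L, C))
        for b, doc in enumerate(docs):
            tag_mats[b, : doc.n_tokens] = doc.tags
        x_tag = tag_mats @ params["tag_table"]
    if variant in ("text_dnn", "text_tag_dnn"):
        ids = np.zeros((B, L), dtype=np.int64)
        for b, doc in enumerate(docs):
            ids[b, : doc.n_tokens] = [vocab.get(w, UNK) for w in doc.tokens]
        x_word = params["emb"][ids]
    if variant == "tag_dnn":
        x = x_tag
    elif variant == "text_dnn":
        x = x_word
    else:
        x = np.concatenate([x_tag, x_word], axis=2)
    return x, lengths, tag_mats, ids


def _train_dnn(
    train: Dataset, y: np.ndarray, config: ClassifierConfig, schema: TagSchema
) -> TrainedClassifier:
    rng = np.random.default_rng(config.seed)
    d, h = config.embedding_dim, config.hidden_dim
    variant = config.variant
    params: dict[str, np.ndarray] = {}
    vocab = None
    if variant in ("tag_dnn", "text_tag_dnn"):
        params["tag_table"] = rng.normal(0.0, 0.1, size=(schema.tag_count, d))
    if variant in TEXT_VARIANTS:
        vocab = build_vocab(train, config.min_token_freq)
        params["emb"] = rng.normal(0.0, 0.1, size=(len(vocab), d))
    params |= nn.bilstm_init(rng, _input_width(variant, d), h)
    out = nn.linear_init(rng, 2 * h, 1)
    params["out_W"], params["out_b"] = out["W"], out["b"]

    docs = list(train)
    opt = nn.Adam(params, lr=config.learning_rate)
    for _ in range(config.epochs):
        for batch in nn.minibatch_indices(len(docs), config.batch_size, rng):
            sub = [docs[i] for i in batch]
            yb = y[batch][:, None]
            x, lengths, tag_mats, ids = _batch_inputs(sub, variant, params, vocab)
            _, h_last, cache = nn.bilstm_forward(x, lengths, params)
            logits = h_last @ params["out_W"] + params["out_b"]
            _, g = nn.bce_with_logits(logits, yb)
            g = g / len(sub)
            grads = {"out_W": h_last.T @ g, "out_b": g.sum(0)}
            d_last = g @ params["out_W"].T
            bi_grads, dx = nn.bilstm_backward(None, d_last, cache, params)
            grads |= bi_grads
            if variant == "tag_dnn":
                grads["tag_table"] = np.einsum("blc,bld->cd", tag_mats, dx)
            elif variant == "text_dnn":
                d_emb = np.zeros_like(params["emb"])
                np.add.at(d_emb, ids.ravel(), dx.reshape(-1, d))
                grads["emb"] = d_emb
            else:
                grads["tag_table"] = np.einsum("blc,bld->cd", tag_mats, dx[:, :, :d])
                d_emb = np.zeros_like(params["emb"])
                np.add.at(d_emb, ids.ravel(), dx[:, :, d:].reshape(-1, d))
                grads["emb"] = d_emb
            opt.step(grads)

    return TrainedClassifier(
        variant=variant, config=config, n_tags=schema.tag_count,
        params=params, vocab=vocab,
    )


def predict_proba(
    model: TrainedClassifier, doc: Document, schema: TagSchema | None = None
) -> float:
    """P(AS) for one document; the label is AS iff this is >= the threshold."""
    schema = schema or default_schema()
    if model.variant in TAG_VARIANTS and doc.tags is None:
        raise ValueError(
            f"variant {model.variant} requires a tag matrix; document "
            f"{doc.id!r} has none"
        )
    if model.variant == "tag_linear":
        from .corpus import tag_frequency_vector

        x = tag_frequency_vector(doc, schema).values
        z = float(x @ model.coef + model.intercept)
        return float(nn.sigmoid(np.array([z]))[0])
    x, lengths, _, _ = _batch_inputs([doc], model.variant, model.params, model.vocab)
    _, h_last, _ = nn.bilstm_forward(x, lengths, model.params)
    logit = h_last @ model.params["out_W"] + model.params["out_b"]
    return float(nn.sigmoid(logit)[0, 0])


def predict_label(
    model: TrainedClassifier, doc: Document, schema: TagSchema | None = None
) -> str:
    return "AS" if predict_proba(model, doc, schema) >= model.config.threshold else "nonAS"
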