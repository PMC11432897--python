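"""Documents, datasets, and IO.

A :class:`Document` is one participant's tokenized spoken output for one
elicitation task (interview or picture-book recounting), optionally carrying a
binary L x C tag matrix over the 147-tag schema.  Datasets are stored as
JSON-lines (one document per line, tags as per-token lists of active column
indices); single documents interchange as CoNLL-style TSV with columns
``token_index``, ``token``, ``tags`` (pipe-joined tag names, ``_`` if none).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .schema import SCHEMA_VERSION, TagSchema

LABELS = ("AS", "nonAS", "unknown")
TASKS = ("interview", "recounting")
ANNOTATION_SOURCES = ("manual", "auto", "none")


class CorpusError(ValueError):
    """Malformed corpus content (parse or validation failure)."""


@dataclass
class Document:
    id: str
    label: str
    task: str
    tokens: list[str]
    tags: np.ndarray | None = None  # (L, C) uint8, or None
    annotation_source: str = "none"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise CorpusError(f"document {self.id!r}: bad label {self.label!r}")
        if self.task not in TASKS:
            raise CorpusError(f"document {self.id!r}: bad task {self.task!r}")
        if self.annotation_source not in ANNOTATION_SOURCES:
            raise CorpusError(
                f"document {self.id!r}: bad annotation_source "
                f"{self.annotation_source!r}"
            )
        if len(self.tokens) < 1:
            raise CorpusError(f"document {self.id!r}: needs at least one token")
        if self.tags is not None:
            tags = np.asarray(self.tags)
            if tags.ndim != 2 or tags.shape[0] != len(self.tokens):
                raise CorpusError(
                    f"document {self.id!r}: tag matrix shape {tags.shape} does "
                    f"not match {len(self.tokens)} tokens"
                )
            if not np.isin(tags, (0, 1)).all():
                raise CorpusError(f"document {self.id!r}: tag entries must be 0/1")
            self.tags = tags.astype(np.uint8)
        if self.tags is None and self.annotation_source != "none":
            raise CorpusError(
                f"document {self.id!r}: annotation_source without a tag matrix"
            )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def with_tags(self, tags: np.ndarray, source: str) -> "Document":
        return replace(self, tags=tags, annotation_source=source)


@dataclass
class Dataset:
    documents: list[Document] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusError(f"duplicate document ids: {dupes}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def filter_task(self, task: str) -> "Dataset":
        return Dataset(
            [d for d in self.documents if d.task == task], self.schema_version
        )

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.documents[i] for i in indices], self.schema_version)

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.documents]


@dataclass(frozen=True)
class TagFrequencyVector:
    """Per-tag active-word counts divided by the total word count."""

    values: np.ndarray  # (C,)
    n_tokens: int


def tag_frequency_vector(doc: Document, schema: TagSchema) -> TagFrequencyVector:
    """Frequency of each tag in ``doc``: active-word count / total words.

    Discards token order entirely; each value lies in [0, 1] because a tag is
    active at most once per word.
    """
    if doc.tags is None:
        raise CorpusError(f"document {doc.id!r} has no tag matrix")
    if doc.tags.shape[1] != schema.tag_count:
        raise CorpusError(
            f"document {doc.id!r}: {doc.tags.shape[1]} tag columns, schema "
            f"has {schema.tag_count}"
        )
    counts = doc.tags.sum(axis=0, dtype=np.float64)
    return TagFrequencyVector(values=counts / doc.n_tokens, n_tokens=doc.n_tokens)


def frequency_matrix(dataset: Dataset, schema: TagSchema) -> np.ndarray:
    """(N, C) matrix stacking each document's tag-frequency vector."""
    return np.stack(
        [tag_frequency_vector(d, schema).values for d in dataset.documents]
    )


# ---------------------------------------------------------------------------
# JSON-lines container
# ---------------------------------------------------------------------------

def _doc_to_record(doc: Document) -> dict:
    record: dict = {
        "id": doc.id,
        "label": doc.label,
        "task": doc.task,
        "tokens": list(doc.tokens),
        "annotation_source": doc.annotation_source,
    }
    if doc.tags is None:
        record["tags"] = None
    else:
        record["tags"] = [np.flatnonzero(row).tolist() for row in doc.tags]
    return record


def _record_to_doc(record: dict, n_columns: int) -> Document:
    tags = None
    raw = record.get("tags")
    if raw is not None:
        tokens = record["tokens"]
        if len(raw) != len(tokens):
            raise CorpusError(
                f"document {record.get('id')!r}: {len(raw)} tag rows for "
                f"{len(tokens)} tokens"
            )
        tags = np.zeros((len(tokens), n_columns), dtype=np.uint8)
        for row, active in enumerate(raw):
            for col in active:
                if not 0 <= col < n_columns:
                    raise CorpusError(
                        f"document {record.get('id')!r}: tag index {col} out "
                        f"of range 0..{n_columns - 1}"
                    )
                tags[row, col] = 1
    return Document(
        id=record["id"],
        label=record["label"],
        task=record["task"],
        tokens=list(record["tokens"]),
        tags=tags,
        annotation_source=record.get(
            "annotation_source", "none" if tags is None else "manual"
        ),
    )


def write_corpus(dataset: Dataset, path) -> None:
    with open(path, "w") as fh:
        header = {"schema_version": dataset.schema_version}
        fh.write(json.dumps({"_header": header}) + "\n")
        for doc in dataset.documents:
            fh.write(json.dumps(_doc_to_record(doc)) + "\n")


def read_corpus(path, n_columns: int = 147) -> Dataset:
    documents: list[Document] = []
    schema_version = SCHEMA_VERSION
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: malformed JSON on line {lineno}: {exc}")
            if "_header" in record:
                schema_version = record["_header"].get(
                    "schema_version", schema_version
                )
                continue
            try:
                documents.append(_record_to_doc(record, n_columns))
            except KeyError as exc:
                raise CorpusError(
                    f"{path}: line {lineno}: missing field {exc}"
                ) from None
    return Dataset(documents, schema_version)


# ---------------------------------------------------------------------------
# CoNLL-style token table
# ---------------------------------------------------------------------------

def to_token_table(doc: Document, schema: TagSchema) -> list[tuple[str, str, str]]:
    """One (token_index, token, tags) row per token; tags pipe-joined, '_' if none."""
    rows = []
    for i, token in enumerate(doc.tokens):
        if doc.tags is None:
            cell = "_"
        else:
            active = [schema.tag_name(c) for c in np.flatnonzero(doc.tags[i])]
            cell = "|".join(active) if active else "_"
        rows.append((str(i), token, cell))
    return rows


def from_token_table(
    rows: Iterable[Sequence[str]],
    schema: TagSchema,
    doc_id: str = "doc",
    label: str = "unknown",
    task: str = "interview",
    annotation_source: str = "manual",
) -> Document:
    tokens: list[str] = []
    tag_rows: list[list[int]] = []
    any_tags = False
    for row in rows:
        if len(row) != 3:
            raise CorpusError(f"token table row {row!r}: expected 3 columns")
        _, token, cell = row
        tokens.append(token)
        if cell == "_":
            tag_rows.append([])
        else:
            any_tags = True
            tag_rows.append([schema.tag_index(name) for name in cell.split("|")])
    tags = None
    source = "none"
    if any_tags:
        tags = np.zeros((len(tokens), schema.tag_count), dtype=np.uint8)
        for i, cols in enumerate(tag_rows):
            tags[i, cols] = 1
        source = annotation_source
    return Document(
        id=doc_id, label=label, task=task, tokens=tokens, tags=tags,
        annotation_source=source,
    )


def write_token_table(doc: Document, schema: TagSchema, path) -> None:
    with open(path, "w") as fh:
        for row in to_token_table(doc, schema):
            fh.write("\t".join(row) + "\n")


def read_token_table(path, schema: TagSchema, **kwargs) -> Document:
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return from_token_table(rows, schema, **kwargs)
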