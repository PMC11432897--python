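"""Lexicogrammatical tag schema.

The annotation scheme groups 147 tag types under 16 lexicogrammar headings
(process type, ergativity, transitivity, clause complexes, logico-semantic
relation, auxiliary verbs, modality, appraisal-attitude, appraisal-graduation,
negotiating particle, explanative mood, evidentiality, optative mood,
benefactive auxiliaries, onomatopoeia, filler).  The first six headings realise
the ideational metafunction, the remaining ten the interpersonal metafunction.
Every tag matrix, frequency vector and embedding table in the package is
indexed by the fixed 0..146 column order defined here, so the schema ships as
a versioned data file rather than being rebuilt at run time.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

SCHEMA_VERSION = "1.0"

#: Tag-type counts per heading, in heading order.  They sum to 147.
HEADING_COUNTS = (10, 2, 2, 22, 13, 20, 8, 18, 4, 12, 12, 3, 1, 10, 2, 8)


class UnknownTagError(KeyError):
    """Raised when a tag name is not part of the schema."""


@dataclass(frozen=True)
class TagType:
    """A single tag type: a column of the L x C annotation matrix."""

    name: str
    heading: str
    metafunction: str  # "ideational" or "interpersonal"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("tag name must be non-empty")
        if not self.heading:
            raise ValueError(f"tag {self.name!r}: heading must be non-empty")
        if self.metafunction not in ("ideational", "interpersonal"):
            raise ValueError(
                f"tag {self.name!r}: metafunction must be ideational or "
                f"interpersonal, got {self.metafunction!r}"
            )


@dataclass(frozen=True)
class TagSchema:
    """Ordered collection of :class:`TagType` with a stable name->index map."""

    tags: tuple[TagType, ...]
    version: str = SCHEMA_VERSION
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {tag.name: i for i, tag in enumerate(self.tags)}
        if len(index) != len(self.tags):
            raise ValueError("tag names must be unique within the schema")
        object.__setattr__(self, "_index", index)

    @property
    def tag_count(self) -> int:
        return len(self.tags)

    @property
    def headings(self) -> tuple[str, ...]:
        """Heading labels in first-appearance order."""
        seen: dict[str, None] = {}
        for tag in self.tags:
            seen.setdefault(tag.heading, None)
        return tuple(seen)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(tag.name for tag in self.tags)

    def tag_index(self, name: str) -> int:
        """Column index of tag ``name`` (0-based)."""
        try:
            return self._index[name]
        except KeyError:
            raise UnknownTagError(
                f"unknown tag name {name!r} (schema version {self.version})"
            ) from None

    def tag_name(self, index: int) -> str:
        return self.tags[index].name

    def heading_tags(self, heading: str) -> tuple[TagType, ...]:
        return tuple(tag for tag in self.tags if tag.heading == heading)

    def indices(self, names: Iterable[str]) -> list[int]:
        return [self.tag_index(n) for n in names]

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self.tags)

    def to_records(self) -> list[dict[str, str]]:
        return [
            {
                "index": str(i),
                "name": t.name,
                "heading": t.heading,
                "metafunction": t.metafunction,
                "description": t.description,
            }
            for i, t in enumerate(self.tags)
        ]

    def save_tsv(self, path) -> None:
        records = self.to_records()
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(records[0]), delimiter="\t")
            writer.writeheader()
            writer.writerows(records)


def _schema_from_rows(rows: list[dict[str, str]], version: str) -> TagSchema:
    ordered = sorted(rows, key=lambda r: int(r["index"]))
    for expected, row in enumerate(ordered):
        if int(row["index"]) != expected:
            raise ValueError(f"schema file indices are not contiguous at {expected}")
    tags = tuple(
        TagType(
            name=row["name"],
            heading=row["heading"],
            metafunction=row["metafunction"],
            description=row.get("description", ""),
        )
        for row in ordered
    )
    return TagSchema(tags=tags, version=version)


def load_schema_tsv(path, version: str = SCHEMA_VERSION) -> TagSchema:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return _schema_from_rows(rows, version)


def default_schema() -> TagSchema:
    """The built-in 147-tag schema, loaded from the packaged data file."""
    resource = importlib.resources.files("lexasd.data").joinpath("tag_schema.tsv")
    with importlib.resources.as_file(resource) as path:
        schema = load_schema_tsv(path)
    counts = tuple(len(schema.heading_tags(h)) for h in schema.headings)
    if counts != HEADING_COUNTS or schema.tag_count != 147:
        raise RuntimeError("packaged schema data file is corrupt")
    return schema
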