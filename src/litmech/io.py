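"""Readers and writers for the four input formats and result tables.

All tabular files are tab-separated UTF-8 with a mandatory header row.
Columns bind by NAME, not position, so exports with permuted columns parse
identically. The unit of evidence everywhere is the (article, record) pair;
sentence-level detail present in real predication dumps is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError

PREDICATION_COLUMNS = [
    "article_id",
    "subject_id",
    "subject_name",
    "subject_semtype",
    "predicate",
    "object_id",
    "object_name",
    "object_semtype",
]

MESH_COLUMNS = ["article_id", "descriptor_id", "descriptor_name", "is_major"]

TREE_COLUMNS = ["descriptor_id", "tree_number"]

_MAJOR_TOKENS = {"Y": True, "1": True, "N": False, "0": False}


@dataclass(frozen=True, slots=True)
class Predication:
    """One extracted subject-PREDICATE-object triple attributed to one article."""

    article_id: int
    subject_id: str
    subject_name: str
    subject_semtype: str
    predicate: str
    object_id: str
    object_name: str
    object_semtype: str

    def key(self) -> tuple[str, str, str]:
        """Directed triple key (subject, PREDICATE, object)."""
        return (self.subject_id, self.predicate, self.object_id)


@dataclass(frozen=True, slots=True)
class MeshAnnotation:
    """One descriptor assigned to one article, with the major-topic flag."""

    article_id: int
    descriptor_id: str
    descriptor_name: str
    is_major: bool


class RecordList(list):
    """A list of parsed records carrying reader bookkeeping.

    ``n_dropped`` counts data rows discarded because the article identifier
    was not a positive integer.
    """

    n_dropped: int = 0


class MeshTree:
    """Descriptor -> tree-number mapping with hierarchy depth lookups.

    Depth of a descriptor is the minimum, over its tree numbers, of
    ``1 + number of dots`` — i.e. its shallowest position in the hierarchy.
    Unknown descriptors have depth ``None``.
    """

    def __init__(self, tree_numbers: dict[str, list[str]] | None = None):
        self.tree_numbers: dict[str, list[str]] = dict(tree_numbers or {})

    def add(self, descriptor_id: str, tree_number: str) -> None:
        numbers = self.tree_numbers.setdefault(descriptor_id, [])
        if tree_number not in numbers:
            numbers.append(tree_number)

    def depth(self, descriptor_id: str) -> int | None:
        numbers = self.tree_numbers.get(descriptor_id)
        if not numbers:
            return None
        return min(1 + n.count(".") for n in numbers)

    def __len__(self) -> int:
        return len(self.tree_numbers)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.tree_numbers

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeshTree):
            return NotImplemented
        return {k: sorted(v) for k, v in self.tree_numbers.items()} == {
            k: sorted(v) for k, v in other.tree_numbers.items()
        }


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return frame


def _parse_article_id(token: str) -> int | None:
    token = token.strip()
    if not token.isdigit():
        return None
    value = int(token)
    return value if value > 0 else None


def read_predications(path: str | Path) -> RecordList:
    """Read a predication table into :class:`Predication` records.

    Rows whose ``article_id`` is not a positive integer are dropped and
    counted on the returned list's ``n_dropped`` attribute. File order is
    preserved.
    """
    frame = _read_table(path, PREDICATION_COLUMNS)
    records = RecordList()
    dropped = 0
    for row in frame.itertuples(index=False):
        article_id = _parse_article_id(getattr(row, "article_id"))
        if article_id is None:
            dropped += 1
            continue
        records.append(
            Predication(
                article_id=article_id,
                subject_id=getattr(row, "subject_id"),
                subject_name=getattr(row, "subject_name"),
                subject_semtype=getattr(row, "subject_semtype"),
                predicate=getattr(row, "predicate"),
                object_id=getattr(row, "object_id"),
                object_name=getattr(row, "object_name"),
                object_semtype=getattr(row, "object_semtype"),
            )
        )
    records.n_dropped = dropped
    return records


def read_mesh_annotations(path: str | Path) -> RecordList:
    """Read a MeSH annotation table; ``is_major`` accepts Y/N or 1/0."""
    frame = _read_table(path, MESH_COLUMNS)
    records = RecordList()
    dropped = 0
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        token = getattr(row, "is_major").strip()
        if token not in _MAJOR_TOKENS:
            raise FormatError(f"{path}: row {i}: unknown is_major token {token!r}")
        article_id = _parse_article_id(getattr(row, "article_id"))
        if article_id is None:
            dropped += 1
            continue
        records.append(
            MeshAnnotation(
                article_id=article_id,
                descriptor_id=getattr(row, "descriptor_id"),
                descriptor_name=getattr(row, "descriptor_name"),
                is_major=_MAJOR_TOKENS[token],
            )
        )
    records.n_dropped = dropped
    return records


def read_mesh_tree(path: str | Path) -> MeshTree:
    """Read a two-column descriptor/tree-number file into a :class:`MeshTree`.

    Duplicate (descriptor, tree number) pairs deduplicate silently.
    """
    frame = _read_table(path, TREE_COLUMNS)
    tree = MeshTree()
    for row in frame.itertuples(index=False):
        number = getattr(row, "tree_number").strip()
        if not number:
            raise FormatError(f"{path}: empty tree number for {getattr(row, 'descriptor_id')}")
        tree.add(getattr(row, "descriptor_id"), number)
    return tree


def read_pmid_list(path: str | Path) -> list[int]:
    """Read a plain-text PubMed-ID list: one integer per line.

    Blank lines and lines starting with ``#`` are ignored; duplicates are
    removed preserving first occurrence.
    """
    path = Path(path)
    seen: set[int] = set()
    ids: list[int] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            value = _parse_article_id(line)
            if value is None:
                raise FormatError(f"{path}: line {lineno}: not a PubMed ID: {line!r}")
            if value not in seen:
                seen.add(value)
                ids.append(value)
    return ids


def write_predications(records: Iterable[Predication], path: str | Path) -> None:
    rows = [[getattr(r, c) for c in PREDICATION_COLUMNS] for r in records]
    pd.DataFrame(rows, columns=PREDICATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_mesh_annotations(records: Iterable[MeshAnnotation], path: str | Path) -> None:
    rows = [
        [r.article_id, r.descriptor_id, r.descriptor_name, "Y" if r.is_major else "N"]
        for r in records
    ]
    pd.DataFrame(rows, columns=MESH_COLUMNS).to_csv(path, sep="\t", index=False)


def write_mesh_tree(tree: MeshTree, path: str | Path) -> None:
    rows = [
        [descriptor, number]
        for descriptor in sorted(tree.tree_numbers)
        for number in sorted(tree.tree_numbers[descriptor])
    ]
    pd.DataFrame(rows, columns=TREE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_pmid_list(ids: Iterable[int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for value in ids:
            handle.write(f"{value}\n")


def format_float(x: float) -> str:
    """Shortest round-trippable decimal form, stable across runs."""
    if math.isinf(x):
        return "inf"
    return repr(float(x))
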