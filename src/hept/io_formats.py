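"""Readers and writers for the tabular inputs of the essential-protein ranker.

All inputs are plain text: a two-column protein–protein interaction (PPI)
edge list, two-column annotation tables (protein → domain / GO term /
subcellular compartment), a protein → ortholog-species-count table, and a
one-ID-per-line list of known essential proteins used only for evaluation.

Identifier matching is exact-string and case-sensitive throughout; no ID
mapping or aliasing is performed.  Lines starting with ``#`` are treated as
comments in every TSV reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger("hept")

AnnotationKind = str  # one of {"domain", "go", "subcellular"}
_VALID_KINDS = ("domain", "go", "subcellular")

DEFAULT_GO_MIN = 10
DEFAULT_GO_MAX = 200


class ParseError(ValueError):
    """Raised when an input file line cannot be parsed; names the line."""


@dataclass(frozen=True)
class ProteinIndex:
    """Bijection between protein identifiers and dense indices ``0..n-1``."""

    ids: tuple[str, ...]
    index_of: dict[str, int] = field(hash=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("ProteinIndex requires at least one protein")
        mapping = {pid: i for i, pid in enumerate(self.ids)}
        if len(mapping) != len(self.ids):
            raise ValueError("duplicate protein identifiers in index")
        if any(not pid for pid in self.ids):
            raise ValueError("empty protein identifier")
        object.__setattr__(self, "index_of", mapping)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "ProteinIndex":
        return cls(ids=tuple(ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self.index_of


@dataclass
class AnnotationTable:
    """Deduplicated (protein, term) pairs of a single annotation kind."""

    kind: AnnotationKind
    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")

    @property
    def term_universe(self) -> set[str]:
        return {term for _, term in self.pairs}

    @property
    def proteins(self) -> set[str]:
        return {pid for pid, _ in self.pairs}

    def terms_of(self, protein_id: str) -> set[str]:
        return {t for p, t in self.pairs if p == protein_id}

    def restricted_to(self, index: ProteinIndex) -> "AnnotationTable":
        """Drop pairs whose protein is outside the PPI index (counted in log)."""
        kept = {(p, t) for p, t in self.pairs if p in index}
        dropped = len(self.pairs) - len(kept)
        if dropped:
            logger.info(
                "%s annotations: ignoring %d pairs for proteins outside the network",
                self.kind, dropped,
            )
        return AnnotationTable(kind=self.kind, pairs=kept)


@dataclass
class OrthologCounts:
    """Per-protein count of reference organisms with an identified ortholog."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for pid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative ortholog count for {pid!r}")


def _data_lines(path: Path):
    """Yield (line_number, stripped_line), skipping blanks and '#' comments."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_ppi_edges(path: str | Path) -> tuple[ProteinIndex, set[tuple[int, int]]]:
    """Read an undirected PPI edge list (two whitespace-separated columns).

    Self-loops are removed; duplicate and reversed-duplicate edges collapse
    to one undirected edge.  Returns the protein index (covering every
    identifier seen, in first-appearance order) and the set of unordered
    index pairs ``(i, j)`` with ``i < j``.
    """
    path = Path(path)
    ids: list[str] = []
    seen: dict[str, int] = {}
    id_edges: set[tuple[str, str]] = set()
    n_self, n_dup = 0, 0
    for lineno, line in _data_lines(path):
        cols = line.split()
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        a, b = cols
        for pid in (a, b):
            if pid not in seen:
                seen[pid] = len(ids)
                ids.append(pid)
        if a == b:
            n_self += 1
            continue
        edge = (a, b) if a < b else (b, a)
        if edge in id_edges:
            n_dup += 1
        id_edges.add(edge)
    if not ids:
        raise ParseError(f"{path}: empty PPI edge list")
    index = ProteinIndex.from_ids(ids)
    edges = set()
    for a, b in id_edges:
        i, j = index.index_of[a], index.index_of[b]
        edges.add((i, j) if i < j else (j, i))
    if n_self or n_dup:
        logger.info("PPI: removed %d self-interactions, %d duplicate edges", n_self, n_dup)
    logger.info("PPI: %d proteins, %d interactions", len(index), len(edges))
    return index, edges


def read_annotations(path: str | Path, kind: AnnotationKind) -> AnnotationTable:
    """Read a two-column (protein, term) TSV into an annotation table."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        cols = line.split()
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        pairs.add((cols[0], cols[1]))
    return AnnotationTable(kind=kind, pairs=pairs)


def read_gaf(path: str | Path) -> AnnotationTable:
    """Read GO annotations from a GAF 2.x file.

    Maps each row down to a (DB Object ID, GO ID) pair; evidence codes,
    qualifiers and aspects are ignored.  Header lines start with ``!``.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"{path}:{lineno}: GAF row has {len(cols)} columns, need >= 5")
            pairs.add((cols[1], cols[4]))
    return AnnotationTable(kind="go", pairs=pairs)


def filter_go_terms(
    table: AnnotationTable,
    min_count: int = DEFAULT_GO_MIN,
    max_count: int = DEFAULT_GO_MAX,
) -> AnnotationTable:
    """Keep only GO terms annotating between ``min_count`` and ``max_count``
    distinct proteins (inclusive) — drops terms that are too specific or too
    general to be informative.
    """
    if table.kind != "go":
        raise ValueError("GO-frequency filter applies to GO tables only")
    if not (1 <= min_count <= max_count):
        raise ValueError("require 1 <= min_count <= max_count")
    counts: dict[str, int] = {}
    for _, term in table.pairs:
        counts[term] = counts.get(term, 0) + 1
    keep = {t for t, c in counts.items() if min_count <= c <= max_count}
    kept_pairs = {(p, t) for p, t in table.pairs if t in keep}
    logger.info(
        "GO filter [%d, %d]: kept %d of %d terms", min_count, max_count,
        len(keep), len(counts),
    )
    return AnnotationTable(kind="go", pairs=kept_pairs)


def read_ortholog_counts(path: str | Path) -> OrthologCounts:
    """Read a two-column (protein, integer count) TSV of ortholog counts."""
    path = Path(path)
    counts: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        cols = line.split()
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        try:
            value = int(cols[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: count {cols[1]!r} is not an integer") from exc
        if value < 0:
            raise ParseError(f"{path}:{lineno}: negative ortholog count")
        counts[cols[0]] = value
    return OrthologCounts(counts=counts)


def read_essential_list(path: str | Path, index: ProteinIndex | None = None) -> set[str]:
    """Read a one-ID-per-line essential-protein list (evaluation labels).

    IDs absent from the network are kept in the returned set; when an index
    is supplied the number of unmatched IDs is reported in the log.
    """
    path = Path(path)
    ids: set[str] = set()
    for _, line in _data_lines(path):
        cols = line.split()
        ids.add(cols[0])
    if not ids:
        logger.warning("essential-protein list %s is empty", path)
    elif index is not None:
        unmatched = sum(1 for pid in ids if pid not in index)
        if unmatched:
            logger.info("essential list: %d of %d IDs not in the network", unmatched, len(ids))
    return ids


def write_ppi_edges(path: str | Path, index: ProteinIndex, edges: set[tuple[int, int]]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for i, j in sorted(edges):
            fh.write(f"{index.ids[i]}\t{index.ids[j]}\n")


def write_annotations(path: str | Path, table: AnnotationTable) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid, term in sorted(table.pairs):
            fh.write(f"{pid}\t{term}\n")


def write_ortholog_counts(path: str | Path, counts: OrthologCounts) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid, c in sorted(counts.counts.items()):
            fh.write(f"{pid}\t{c}\n")


def write_essential_list(path: str | Path, ids: set[str]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid in sorted(ids):
            fh.write(pid + "\n")


def write_ranking(path: str | Path, ranking: list[tuple[str, float]]) -> None:
    """Write a ranking as TSV: rank, protein_id, score (repr round-trippable)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# rank\tprotein_id\tscore\n")
        for rank, (pid, score) in enumerate(ranking, start=1):
            fh.write(f"{rank}\t{pid}\t{score!r}\n")
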