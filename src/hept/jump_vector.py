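"""Restart (jump) vector from orthology conservation and subcellular localization.

The random-walk restart distribution ``D`` personalizes the authority update
toward proteins that are evolutionarily conserved and located in populous
compartments: ``d_i = I(i) * S(i)`` where

* ``I(i) = NI(i) / max_j NI(j)`` — ortholog count normalized by the maximum,
* ``S(i) = max over compartments of protein i of F_S(c)`` with
  ``F_S(c) = |proteins in c| / max_c' |proteins in c'|``.

``D`` is L1-normalized so the restart term of the iteration mixes a proper
probability distribution; an all-zero raw vector falls back to uniform 1/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationTable, OrthologCounts, ProteinIndex

logger = logging.getLogger("hept")


@dataclass
class JumpVector:
    d: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        if np.any(self.d < 0):
            raise ValueError("jump vector entries must be non-negative")
        if self.normalized and abs(self.d.sum() - 1.0) > 1e-12:
            raise ValueError("normalized jump vector must sum to 1")


def orthology_score(counts: OrthologCounts, index: ProteinIndex) -> np.ndarray:
    """``I(i) = NI(i) / max_j NI(j)``; proteins without a count get NI = 0."""
    n = len(index)
    ni = np.zeros(n)
    for pid, c in counts.counts.items():
        if pid in index:
            ni[index.index_of[pid]] = c
    top = ni.max()
    if top == 0:
        logger.warning("all ortholog counts are zero; orthology scores set to 0")
        return np.zeros(n)
    return ni / top


def compartment_scores(table: AnnotationTable, index: ProteinIndex) -> dict[str, float]:
    """``F_S(c)``: compartment protein count over the largest compartment's."""
    if table.kind != "subcellular":
        raise ValueError("compartment_scores requires a subcellular table")
    sizes: dict[str, int] = {}
    for pid, comp in table.pairs:
        if pid in index:
            sizes[comp] = sizes.get(comp, 0) + 1
    if not sizes:
        return {}
    top = max(sizes.values())
    return {c: s / top for c, s in sizes.items()}


def subcellular_score(
    protein: int,
    table: AnnotationTable,
    f_s: dict[str, float],
    index: ProteinIndex,
) -> float:
    """``S(i)``: best compartment score of protein i; 0 if unannotated."""
    pid = index.ids[protein]
    comps = {c for p, c in table.pairs if p == pid}
    return max((f_s.get(c, 0.0) for c in comps), default=0.0)


def subcellular_scores(table: AnnotationTable, index: ProteinIndex) -> np.ndarray:
    """Vectorized ``S`` over the whole index."""
    f_s = compartment_scores(table, index)
    s = np.zeros(len(index))
    for pid, comp in table.pairs:
        if pid in index:
            i = index.index_of[pid]
            s[i] = max(s[i], f_s.get(comp, 0.0))
    return s


def build_jump_vector(i_score: np.ndarray, s_score: np.ndarray, normalize: bool = True) -> JumpVector:
    """``d_i = I(i) * S(i)``, L1-normalized; uniform fallback if all-zero."""
    if i_score.shape != s_score.shape:
        raise ValueError("orthology and subcellular score vectors differ in length")
    raw = i_score * s_score
    total = raw.sum()
    if total == 0:
        logger.warning("jump vector all-zero; falling back to uniform 1/n")
        n = raw.size
        return JumpVector(d=np.full(n, 1.0 / n), normalized=True)
    if normalize:
        return JumpVector(d=raw / total, normalized=True)
    return JumpVector(d=raw, normalized=False)


def jump_vector_from_tables(
    counts: OrthologCounts,
    subcellular: AnnotationTable,
    index: ProteinIndex,
    normalize: bool = True,
) -> JumpVector:
    """Convenience: Eq.-chain from raw tables to the final restart vector."""
    i_score = orthology_score(counts, index)
    s_score = subcellular_scores(subcellular, index)
    n_zero = int(np.sum(i_score * s_score == 0))
    if n_zero:
        logger.info(
            "jump vector: %d proteins have zero restart mass "
            "(reachable only through the tensor term)", n_zero,
        )
    return build_jump_vector(i_score, s_score, normalize=normalize)


def dump_jump_vector(path, index: ProteinIndex, i_score, s_score, jump: JumpVector) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein_id\tI\tS\td\n")
        for i, pid in enumerate(index.ids):
            fh.write(f"{pid}\t{i_score[i]!r}\t{s_score[i]!r}\t{jump.d[i]!r}\n")
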