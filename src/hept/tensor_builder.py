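"""Construction of the three-slice protein relation tensor.

The tensor ``T`` (shape n x n x m, m = 3) stacks three symmetric relation
matrices over the same protein set:

* **co-neighbor** — topological: ``|Ni ∩ Nj|^2 / ((|Ni|-1)(|Nj|-1))`` when
  both proteins have degree > 1 and at least one shared PPI neighbor,
  0 otherwise.
* **co-domain** — ``P_D(i) * P_D(j)`` for pairs sharing at least one domain
  type, where ``P_D`` is a per-protein domain score: the rarity-weighted
  domain count ``sum_d t_id / NP_d`` min–max scaled across all proteins.
* **co-annotation** — functional: ``|Fi ∩ Fj| / sqrt(|Fi| * |Fj|)`` over the
  (frequency-filtered) GO term sets.

Each slice is computed only over candidate pairs found by an inverted-index
join (shared neighbor / domain / term) — identical to an all-pairs sweep
because every formula is zero without a shared item — and stored as a
scipy.sparse matrix with an empty diagonal.  Relations are computed for any
protein pair, not only pairs that directly interact; ``restrict_to_ppi``
gives the conservative variant limited to existing PPI edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import AnnotationTable, ProteinIndex

logger = logging.getLogger("hept")

SLICE_NAMES = ("co_neighbor", "co_domain", "co_annotation")


@dataclass
class RelationTensor:
    """Sparse symmetric three-way relation tensor.

    ``slices[k]`` is an n x n symmetric CSR matrix of weights in [0, 1] for
    relation ``slice_names[k]``; diagonals are empty (the PPI network has no
    self-interactions and a self-relation would distort the transition
    normalization).
    """

    n: int
    slices: list[sp.csr_matrix]
    slice_names: tuple[str, ...] = SLICE_NAMES

    @property
    def m(self) -> int:
        return len(self.slices)

    def __post_init__(self) -> None:
        if len(self.slice_names) != len(self.slices):
            self.slice_names = tuple(f"slice_{k}" for k in range(len(self.slices)))
        for W in self.slices:
            if W.shape != (self.n, self.n):
                raise ValueError("slice shape does not match protein count")

    def to_dense(self) -> np.ndarray:
        """Dense (n, n, m) array — small-n diagnostics only."""
        return np.stack([np.asarray(W.todense()) for W in self.slices], axis=2)


def adjacency_from_edges(n: int, edges: set[tuple[int, int]]) -> sp.csr_matrix:
    """Binary symmetric adjacency matrix from unordered index pairs."""
    if not edges:
        return sp.csr_matrix((n, n))
    rows, cols = [], []
    for i, j in edges:
        if i == j:
            raise ValueError("self-loop in edge set")
        rows += [i, j]
        cols += [j, i]
    data = np.ones(len(rows))
    A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    A.data[:] = 1.0  # collapse any duplicates
    return A


def co_neighbor_weight(neighbors_i: set[int], neighbors_j: set[int], clip: bool = True) -> float:
    """Shared-neighbor weight for one protein pair."""
    ni, nj = len(neighbors_i), len(neighbors_j)
    if ni <= 1 or nj <= 1:
        return 0.0
    c = len(neighbors_i & neighbors_j)
    w = c * c / ((ni - 1) * (nj - 1))
    if clip and w > 1.0:
        return 1.0
    return w


def co_neighbor_slice(A: sp.csr_matrix, clip: bool = True) -> sp.csr_matrix:
    """Co-neighbor relation matrix from the adjacency matrix.

    ``(A @ A)[i, j]`` counts common neighbors; pairs with any common
    neighbor are exactly the candidate pairs of the inverted-index join.
    """
    n = A.shape[0]
    deg = np.asarray(A.sum(axis=1)).ravel()
    C = (A @ A).tocoo()
    mask = C.row < C.col  # strict upper triangle; also drops the diagonal
    rows, cols, common = C.row[mask], C.col[mask], C.data[mask]
    ok = (deg[rows] > 1) & (deg[cols] > 1)
    rows, cols, common = rows[ok], cols[ok], common[ok]
    w = common**2 / ((deg[rows] - 1.0) * (deg[cols] - 1.0))
    if clip:
        n_clip = int(np.sum(w > 1.0))
        if n_clip:
            logger.info("co-neighbor: clipped %d weights > 1 to 1.0", n_clip)
        np.minimum(w, 1.0, out=w)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n))
    W = (W + W.T).tocsr()
    W.eliminate_zeros()
    return W


def domain_scores(table: AnnotationTable, index: ProteinIndex) -> np.ndarray:
    """Per-protein domain score ``P_D`` in [0, 1].

    The raw score of protein i is ``sum_d t_id / NP_d`` (rare domains count
    more), min–max scaled across all n proteins.  If every raw score is
    equal (e.g. no protein has any domain) the scaling is undefined and all
    scores are set to 0 with a warning.
    """
    if table.kind != "domain":
        raise ValueError("domain_scores requires a domain annotation table")
    n = len(index)
    raw = np.zeros(n)
    np_d: dict[str, int] = {}
    indexed_pairs = [(index.index_of[p], d) for p, d in table.pairs if p in index]
    for _, d in indexed_pairs:
        np_d[d] = np_d.get(d, 0) + 1
    for i, d in indexed_pairs:
        raw[i] += 1.0 / np_d[d]
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        if n and (table.pairs or hi != 0.0):
            logger.warning("domain scores degenerate (all raw scores equal); set to 0")
        return np.zeros(n)
    return (raw - lo) / (hi - lo)


def co_domain_weight(pd_i: float, pd_j: float, share_domain: bool) -> float:
    """Co-domain weight: product of domain scores, only for sharing pairs."""
    return pd_i * pd_j if share_domain else 0.0


def co_domain_slice(table: AnnotationTable, index: ProteinIndex) -> sp.csr_matrix:
    """Co-domain relation matrix over pairs sharing >= 1 domain type."""
    n = len(index)
    pd = domain_scores(table, index)
    M = _membership_matrix(table, index)
    share = (M @ M.T).tocoo()  # co-membership counts
    mask = share.row < share.col
    rows, cols = share.row[mask], share.col[mask]
    w = pd[rows] * pd[cols]
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n))
    W = (W + W.T).tocsr()
    W.eliminate_zeros()
    return W


def co_annotation_weight(terms_i: set[str], terms_j: set[str]) -> float:
    """GO-overlap weight ``|Fi ∩ Fj| / sqrt(|Fi| |Fj|)``; 0 if either empty."""
    if not terms_i or not terms_j:
        return 0.0
    c = len(terms_i & terms_j)
    return c / np.sqrt(len(terms_i) * len(terms_j))


def co_annotation_slice(table: AnnotationTable, index: ProteinIndex) -> sp.csr_matrix:
    """Co-annotation relation matrix over pairs sharing >= 1 retained GO term."""
    n = len(index)
    M = _membership_matrix(table, index)
    sizes = np.asarray(M.sum(axis=1)).ravel()
    inter = (M @ M.T).tocoo()
    mask = inter.row < inter.col
    rows, cols, c = inter.row[mask], inter.col[mask], inter.data[mask]
    w = c / np.sqrt(sizes[rows] * sizes[cols])
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n))
    W = (W + W.T).tocsr()
    W.eliminate_zeros()
    return W


def _membership_matrix(table: AnnotationTable, index: ProteinIndex) -> sp.csr_matrix:
    """Binary protein x term membership matrix restricted to the index."""
    terms = sorted(table.term_universe)
    term_idx = {t: k for k, t in enumerate(terms)}
    rows = []
    cols = []
    for p, t in table.pairs:
        if p in index:
            rows.append(index.index_of[p])
            cols.append(term_idx[t])
    M = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(index), max(len(terms), 1))
    )
    M.data[:] = 1.0
    return M


def build_tensor(
    edges: set[tuple[int, int]],
    domains: AnnotationTable,
    go: AnnotationTable,
    index: ProteinIndex,
    *,
    clip_co_neighbor: bool = True,
    restrict_to_ppi: bool = False,
) -> RelationTensor:
    """Build the full three-slice relation tensor.

    ``restrict_to_ppi`` zeroes relation weights between proteins that do not
    directly interact in the PPI network (conservative variant; by default
    relations may connect non-interacting pairs).
    """
    n = len(index)
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError("edge index outside protein index")
    A = adjacency_from_edges(n, edges)
    slices = [
        co_neighbor_slice(A, clip=clip_co_neighbor),
        co_domain_slice(domains, index),
        co_annotation_slice(go, index),
    ]
    if restrict_to_ppi:
        mask = A.astype(bool)
        slices = [W.multiply(mask).tocsr() for W in slices]
    for name, W in zip(SLICE_NAMES, slices):
        logger.info("tensor slice %s: %d nonzero pairs", name, W.nnz // 2)
    return RelationTensor(n=n, slices=slices, slice_names=SLICE_NAMES)


def dump_tensor(tensor: RelationTensor, index: ProteinIndex, directory) -> None:
    """Write one TSV per slice (i_id, j_id, weight; i_id < j_id) + metadata."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, W in zip(tensor.slice_names, tensor.slices):
        C = W.tocoo()
        entries = []
        for i, j, w in zip(C.row, C.col, C.data):
            a, b = index.ids[i], index.ids[j]
            if a < b:
                entries.append((a, b, w))
        with open(directory / f"{name}.tsv", "wt", encoding="utf-8") as fh:
            for a, b, w in sorted(entries):
                fh.write(f"{a}\t{b}\t{w!r}\n")
    meta = {"n": tensor.n, "m": tensor.m, "slice_names": list(tensor.slice_names)}
    with open(directory / "tensor_meta.json", "wt", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
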