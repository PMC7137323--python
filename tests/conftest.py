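import numpy as np
import pytest
import scipy.sparse as sp

from hept.io_formats import AnnotationTable, ProteinIndex
from hept.tensor_builder import RelationTensor


@pytest.fixture
def tiny_index():
    return ProteinIndex.from_ids(["A", "B", "C", "D"])


def sparse_tensor_from_dense(T):
    """Package RelationTensor from a dense (n, n, m) array."""
    n, _, m = T.shape
    slices = [sp.csr_matrix(T[:, :, k]) for k in range(m)]
    return RelationTensor(n=n, slices=slices, slice_names=tuple(f"s{k}" for k in range(m)))


def random_inputs(rng, n, n_domains=6, n_terms=6, edge_prob=0.15):
    """Random edge set + annotation tables over proteins P0..P{n-1}."""
    ids = [f"P{i}" for i in range(n)]
    index = ProteinIndex.from_ids(ids)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.add((i, j))
    dom_pairs = {
        (ids[i], f"d{d}")
        for i in range(n)
        for d in range(n_domains)
        if rng.random() < 0.2
    }
    go_pairs = {
        (ids[i], f"g{t}")
        for i in range(n)
        for t in range(n_terms)
        if rng.random() < 0.25
    }
    domains = AnnotationTable(kind="domain", pairs=dom_pairs)
    go = AnnotationTable(kind="go", pairs=go_pairs)
    return index, edges, domains, go
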