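"""Self-consistent synthetic input bundles with planted essential proteins.

Generates the six inputs the ranker consumes — PPI edge list, domain / GO /
subcellular annotation tables, ortholog counts and the essential-protein
list — with a tunable amount of signal tying the planted essentials to the
features the method exploits:

* topology: a preferential-attachment (scale-free) graph in which essential
  proteins attract edges at a ``bias``-scaled rate, giving them higher
  degree and denser shared neighborhoods;
* domains: essentials carry ``bias``-scaled numbers of domain types
  (domain-rich proteins tend to be essential), so they score high on the
  rarity-weighted domain score and share domain types with each other;
* GO terms: essentials draw their annotations preferentially from a small
  "module" of terms, enriching their pairwise annotation overlap;
* orthologs: essentials are conserved in a ``bias``-scaled fraction of the
  reference genomes;
* localization: essentials preferentially occupy one favored compartment.

``essential_bias = 1`` switches every mechanism off and yields a null model
in which the essential labels are independent of all features.  A single
integer seed drives one named pseudo-random stream per data type, so e.g.
changing the number of GO terms never perturbs the topology draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AnnotationTable,
    OrthologCounts,
    ProteinIndex,
    write_annotations,
    write_essential_list,
    write_ortholog_counts,
    write_ppi_edges,
)

_STREAMS = ("labels", "topology", "domains", "go", "orthologs", "subcellular")


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults define the package's reference
    study conditions (200 proteins, 20 planted essentials, signal bias 5)."""

    n_proteins: int = 200
    n_essential: int = 20
    attachment: int = 3          # edges added per node (scale-free topology)
    n_domains: int = 40
    n_go_terms: int = 30
    n_compartments: int = 8
    n_genomes: int = 100         # reference genomes for ortholog counts
    essential_bias: float = 5.0  # 1 = null model (no signal)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_essential >= self.n_proteins:
            raise ValueError("n_essential must be < n_proteins")
        for name in ("n_proteins", "n_essential", "attachment", "n_domains",
                     "n_go_terms", "n_compartments", "n_genomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.essential_bias < 1:
            raise ValueError("essential_bias must be >= 1 (1 = null model)")


@dataclass
class SyntheticBundle:
    """In-memory counterpart of the six input files."""

    index: ProteinIndex
    edges: set[tuple[int, int]]
    domains: AnnotationTable
    go: AnnotationTable
    subcellular: AnnotationTable
    orthologs: OrthologCounts
    essential: set[str]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    # one named stream per data type, all derived from the single seed
    return np.random.default_rng([_STREAMS.index(stream), cfg.rng_seed])


def _preferential_attachment(cfg: SyntheticConfig, essential_idx: np.ndarray) -> set[tuple[int, int]]:
    """Scale-free graph; essential nodes get bias-scaled attachment fitness."""
    rng = _rng(cfg, "topology")
    n, m = cfg.n_proteins, cfg.attachment
    fitness = np.ones(n)
    fitness[essential_idx] = cfg.essential_bias
    # nodes arrive in random order so essentials are not confounded with age
    order = rng.permutation(n)
    deg = np.zeros(n)
    edges: set[tuple[int, int]] = set()
    m0 = min(m + 1, n)
    seed_nodes = order[:m0]
    for a in range(m0):
        for b in range(a + 1, m0):
            i, j = int(seed_nodes[a]), int(seed_nodes[b])
            edges.add((min(i, j), max(i, j)))
            deg[i] += 1
            deg[j] += 1
    for pos in range(m0, n):
        node = int(order[pos])
        existing = order[:pos]
        w = (deg[existing] + 1.0) * fitness[existing]
        p = w / w.sum()
        k = min(m, pos)
        targets = rng.choice(existing, size=k, replace=False, p=p)
        for t in targets:
            i, j = node, int(t)
            edges.add((min(i, j), max(i, j)))
            deg[i] += 1
            deg[j] += 1
    return edges


def _weighted_terms(rng, n_terms: int, count: int, favored: np.ndarray, bias: float) -> set[int]:
    w = np.ones(n_terms)
    w[favored] = bias
    p = w / w.sum()
    count = min(count, n_terms)
    if count == 0:
        return set()
    return set(int(t) for t in rng.choice(n_terms, size=count, replace=False, p=p))


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate the six tables; deterministic for a fixed ``rng_seed``."""
    n, bias = cfg.n_proteins, cfg.essential_bias
    ids = tuple(f"P{i:04d}" for i in range(n))
    index = ProteinIndex(ids=ids)

    essential_idx = _rng(cfg, "labels").choice(n, size=cfg.n_essential, replace=False)
    is_ess = np.zeros(n, dtype=bool)
    is_ess[essential_idx] = True
    essential = {ids[i] for i in essential_idx}

    edges = _preferential_attachment(cfg, essential_idx)

    # domains: essentials are domain-rich (bias-scaled mean count)
    rng = _rng(cfg, "domains")
    dom_pairs: set[tuple[str, str]] = set()
    for i in range(n):
        lam = 1.5 * bias if is_ess[i] else 1.5
        count = rng.poisson(lam)
        for d in _weighted_terms(rng, cfg.n_domains, count, np.array([], dtype=int), 1.0):
            dom_pairs.add((ids[i], f"PF{d:05d}"))
    domains = AnnotationTable(kind="domain", pairs=dom_pairs)

    # GO terms: essentials draw from a small favored module of terms
    rng = _rng(cfg, "go")
    module = np.arange(max(1, cfg.n_go_terms // 5))
    go_pairs: set[tuple[str, str]] = set()
    for i in range(n):
        count = rng.poisson(3.0)
        favored = module if is_ess[i] else np.array([], dtype=int)
        for t in _weighted_terms(rng, cfg.n_go_terms, count, favored, bias):
            go_pairs.add((ids[i], f"GO:{t:07d}"))
    go = AnnotationTable(kind="go", pairs=go_pairs)

    # ortholog counts: conserved in a bias-scaled fraction of genomes
    rng = _rng(cfg, "orthologs")
    p_base = 0.15
    counts: dict[str, int] = {}
    for i in range(n):
        p = min(0.95, p_base * bias) if is_ess[i] else p_base
        counts[ids[i]] = int(rng.binomial(cfg.n_genomes, p))
    orthologs = OrthologCounts(counts=counts)

    # subcellular localization: compartment popularity decays with rank;
    # essentials favor compartment C00 (bias-scaled weight)
    rng = _rng(cfg, "subcellular")
    base_w = 1.0 / (1.0 + np.arange(cfg.n_compartments))
    sub_pairs: set[tuple[str, str]] = set()
    for i in range(n):
        w = base_w.copy()
        if is_ess[i]:
            w[0] *= bias
        p = w / w.sum()
        count = 1 + rng.poisson(0.5)
        count = min(count, cfg.n_compartments)
        for c in rng.choice(cfg.n_compartments, size=count, replace=False, p=p):
            sub_pairs.add((ids[i], f"C{int(c):02d}"))
    subcellular = AnnotationTable(kind="subcellular", pairs=sub_pairs)

    return SyntheticBundle(
        index=index, edges=edges, domains=domains, go=go,
        subcellular=subcellular, orthologs=orthologs, essential=essential,
        config=cfg,
    )


BUNDLE_FILES = {
    "ppi": "ppi_edges.tsv",
    "domains": "domains.tsv",
    "go": "go_annotations.tsv",
    "subcellular": "subcellular.tsv",
    "orthologs": "ortholog_counts.tsv",
    "essential": "essential_proteins.txt",
}


def write_bundle(bundle: SyntheticBundle, directory, force: bool = False) -> dict[str, Path]:
    """Write the six files in the formats the readers consume.

    Refuses to overwrite existing files unless ``force``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in BUNDLE_FILES.items()}
    if not force:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite: {', '.join(clashes)}")
    write_ppi_edges(paths["ppi"], bundle.index, bundle.edges)
    write_annotations(paths["domains"], bundle.domains)
    write_annotations(paths["go"], bundle.go)
    write_annotations(paths["subcellular"], bundle.subcellular)
    write_ortholog_counts(paths["orthologs"], bundle.orthologs)
    write_essential_list(paths["essential"], bundle.essential)
    return paths
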