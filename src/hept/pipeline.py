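"""End-to-end pipeline: input tables -> tensor -> iteration -> ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import RankedList
from .hept_core import HeptConfig, ScoreState, rank_proteins, run_hept
from .io_formats import (
    DEFAULT_GO_MAX,
    DEFAULT_GO_MIN,
    AnnotationTable,
    OrthologCounts,
    ProteinIndex,
    filter_go_terms,
)
from .jump_vector import jump_vector_from_tables
from .tensor_builder import RelationTensor, build_tensor

logger = logging.getLogger("hept")


@dataclass
class PipelineResult:
    ranking: RankedList
    state: ScoreState
    converged: bool
    iterations: int
    tensor: RelationTensor = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def edge_type_importance(self) -> dict[str, float]:
        return {
            name: float(v)
            for name, v in zip(self.tensor.slice_names, self.state.ve)
        }


def rank_tables(
    index: ProteinIndex,
    edges: set[tuple[int, int]],
    domains: AnnotationTable,
    go: AnnotationTable,
    orthologs: OrthologCounts,
    subcellular: AnnotationTable,
    cfg: HeptConfig | None = None,
    *,
    go_min: int = DEFAULT_GO_MIN,
    go_max: int = DEFAULT_GO_MAX,
    restrict_to_ppi: bool = False,
    clip_co_neighbor: bool = True,
    normalize_jump: bool = True,
) -> PipelineResult:
    """Run the full method on in-memory tables and return the ranking.

    GO annotations are restricted to network proteins first and then
    frequency-filtered to terms annotating between ``go_min`` and ``go_max``
    proteins.
    """
    cfg = cfg or HeptConfig()
    domains_r = domains.restricted_to(index)
    go_r = filter_go_terms(go.restricted_to(index), go_min, go_max)
    sub_r = subcellular.restricted_to(index)
    tensor = build_tensor(
        edges, domains_r, go_r, index,
        clip_co_neighbor=clip_co_neighbor, restrict_to_ppi=restrict_to_ppi,
    )
    jump = jump_vector_from_tables(orthologs, sub_r, index, normalize=normalize_jump)
    state, converged, iterations = run_hept(tensor, jump, cfg)
    ranking = RankedList.from_pairs(rank_proteins(state, index), label="HEPT")
    return PipelineResult(
        ranking=ranking, state=state, converged=converged,
        iterations=iterations, tensor=tensor,
    )


def rank_bundle(bundle, cfg: HeptConfig | None = None, **kwargs) -> PipelineResult:
    """Run the full method on a synthetic bundle."""
    return rank_tables(
        bundle.index, bundle.edges, bundle.domains, bundle.go,
        bundle.orthologs, bundle.subcellular, cfg, **kwargs,
    )


def run_report(result: PipelineResult, cfg: HeptConfig) -> dict:
    """JSON-ready run metadata (iterations, convergence, VE, config echo)."""
    return {
        "iterations": result.iterations,
        "converged": bool(result.converged),
        "edge_type_importance": result.edge_type_importance,
        "n_proteins": len(result.ranking),
        "config": {
            "alpha": cfg.alpha,
            "epsilon": cfg.epsilon,
            "max_iter": cfg.max_iter,
            "normalize_state": cfg.normalize_state,
        },
    }


def scores_array(result: PipelineResult) -> np.ndarray:
    return result.state.va
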