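"""Tensor-extended HITS power iteration over the protein relation tensor.

The relation tensor ``T`` is normalized into three transition tensors, one
per score vector:

* authority: ``ta(i,j,k) = t(i,j,k) / sum_i t(i,j,k)``, or uniform ``1/n``
  for (j, k) fibers whose sum is zero;
* hub: ``th(i,j,k) = t(i,j,k) / sum_j t(i,j,k)``, uniform ``1/n`` fallback;
* edge-type: ``te(i,j,k) = t(i,j,k) / sum_k t(i,j,k)``, uniform ``1/m``
  fallback.

One iteration updates, in sequence (each update uses the vectors just
computed):

    VA_t(i) = (1 - alpha) * D(i) + alpha * sum_{j,k} ta(i,j,k) VH(j) VE(k)
    VH_t(j) = sum_{i,k} th(i,j,k) VA_t(i) VE(k)
    VE_t(k) = sum_{i,j} te(i,j,k) VA_t(i) VH_t(j)

and stops when the summed L1 change of the three vectors drops below
``epsilon``.  Authority scores VA give the final protein ranking; VE weighs
how much each relation type (co-neighbor / co-domain / co-annotation)
contributed.

Uniform fallback fibers are never materialized: because a uniform fiber
contributes the same value to every output coordinate, its total effect is
a scalar computed analytically from fiber-sum masks (e.g. for the authority
update, ``(1/n) * sum_k VE(k) * sum_{j in zero-columns of slice k} VH(j)``).
This keeps the contraction cost proportional to the number of stored tensor
entries rather than ``n^2 m``, and is exactly equal to the dense form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import ProteinIndex
from .jump_vector import JumpVector
from .tensor_builder import RelationTensor

logger = logging.getLogger("hept")


@dataclass
class HeptConfig:
    """Iteration parameters.

    alpha : float
        Restart mixing weight in [0, 1] on the tensor term of the authority
        update; ``1 - alpha`` goes to the jump vector.  Default 0.3.
    epsilon : float
        Convergence threshold on the summed L1 change of VA, VH, VE.
    max_iter : int
        Iteration cap; hitting it yields ``converged=False`` (warning, not
        an exception).
    normalize_state : bool
        L1-normalize each score vector after its update (default), keeping
        all three interpretable as probability distributions.
    """

    alpha: float = 0.3
    epsilon: float = 1e-8
    max_iter: int = 1000
    normalize_state: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ScoreState:
    """Authority (VA), hub (VH) and edge-type importance (VE) vectors."""

    va: np.ndarray
    vh: np.ndarray
    ve: np.ndarray
    iteration: int = 0

    @classmethod
    def initial(cls, n: int, m: int) -> "ScoreState":
        return cls(va=np.full(n, 1.0 / n), vh=np.full(n, 1.0 / n), ve=np.full(m, 1.0 / m))


@dataclass
class TransitionTensors:
    """Mode-normalized transition structure of a relation tensor.

    The per-slice matrices hold the explicitly normalized entries; the masks
    mark the fibers whose sum was zero and whose uniform ``1/n`` (or ``1/m``)
    entries are applied analytically during contraction.
    """

    n: int
    m: int
    authority: list[sp.csr_matrix]       # column-normalized slices
    hub: list[sp.csr_matrix]             # row-normalized slices
    edge: list[sp.csr_matrix]            # slice-normalized entries (per pair)
    zero_cols: list[np.ndarray]          # per slice: bool mask of all-zero (j,k) fibers
    zero_rows: list[np.ndarray]          # per slice: bool mask of all-zero (i,k) fibers
    pair_support: sp.csr_matrix = field(default=None)  # type: ignore[assignment]
    # pair_support: 1 where some slice has weight for (i,j); the complement
    # (incl. the diagonal) is the uniform 1/m region of the edge tensor.


def normalize_tensor(tensor: RelationTensor, mode: str):
    """Normalize one mode of the tensor (Eq.-style fiber normalization).

    Returns ``(matrices, zero_fiber_masks)`` for modes ``authority`` and
    ``hub`` and ``(matrices, pair_support)`` for mode ``edge``; uniform
    fibers are represented implicitly by the masks/support complement.
    """
    n, m = tensor.n, tensor.m
    if mode == "authority":
        mats, masks = [], []
        for W in tensor.slices:
            colsum = np.asarray(W.sum(axis=0)).ravel()
            zero = colsum == 0
            inv = np.zeros(n)
            inv[~zero] = 1.0 / colsum[~zero]
            mats.append((W @ sp.diags(inv)).tocsr())
            masks.append(zero)
        return mats, masks
    if mode == "hub":
        mats, masks = [], []
        for W in tensor.slices:
            rowsum = np.asarray(W.sum(axis=1)).ravel()
            zero = rowsum == 0
            inv = np.zeros(n)
            inv[~zero] = 1.0 / rowsum[~zero]
            mats.append((sp.diags(inv) @ W).tocsr())
            masks.append(zero)
        return mats, masks
    if mode == "edge":
        S = tensor.slices[0].copy()
        for W in tensor.slices[1:]:
            S = S + W
        S = S.tocsr()
        S.eliminate_zeros()
        recip = S.copy()
        recip.data = 1.0 / recip.data
        mats = [W.multiply(recip).tocsr() for W in tensor.slices]
        support = S.copy()
        support.data = np.ones_like(support.data)
        return mats, support
    raise ValueError(f"unknown normalization mode {mode!r}")


def build_transition_tensors(tensor: RelationTensor) -> TransitionTensors:
    authority, zero_cols = normalize_tensor(tensor, "authority")
    hub, zero_rows = normalize_tensor(tensor, "hub")
    edge, support = normalize_tensor(tensor, "edge")
    return TransitionTensors(
        n=tensor.n, m=tensor.m,
        authority=authority, hub=hub, edge=edge,
        zero_cols=zero_cols, zero_rows=zero_rows, pair_support=support,
    )


def _check_finite(v: np.ndarray, step: str) -> None:
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"non-finite value in {step} update")


def iterate_once(
    state: ScoreState,
    tt: TransitionTensors,
    jump: JumpVector,
    cfg: HeptConfig,
) -> ScoreState:
    """One sequential VA → VH → VE update (fresh vectors feed forward)."""
    n, m = tt.n, tt.m
    va_prev, vh_prev, ve_prev = state.va, state.vh, state.ve
    alpha = cfg.alpha

    va = np.zeros(n)
    for k in range(m):
        va += ve_prev[k] * (tt.authority[k] @ vh_prev)
        va += ve_prev[k] * vh_prev[tt.zero_cols[k]].sum() / n  # uniform fibers
    va = (1.0 - alpha) * jump.d + alpha * va
    _check_finite(va, "authority (VA)")
    if cfg.normalize_state:
        va = va / va.sum()

    vh = np.zeros(n)
    for k in range(m):
        vh += ve_prev[k] * (tt.hub[k].T @ va)
        vh += ve_prev[k] * va[tt.zero_rows[k]].sum() / n
    _check_finite(vh, "hub (VH)")
    if cfg.normalize_state:
        vh = vh / vh.sum()

    ve = np.empty(m)
    uniform_pairs = va.sum() * vh.sum() - va @ (tt.pair_support @ vh)
    for k in range(m):
        ve[k] = va @ (tt.edge[k] @ vh) + uniform_pairs / m
    _check_finite(ve, "edge-type (VE)")
    if cfg.normalize_state:
        ve = ve / ve.sum()

    return ScoreState(va=va, vh=vh, ve=ve, iteration=state.iteration + 1)


def run_hept(
    tensor: RelationTensor,
    jump: JumpVector,
    cfg: HeptConfig | None = None,
) -> tuple[ScoreState, bool, int]:
    """Run the power iteration to convergence (or ``max_iter``).

    Returns ``(final_state, converged, iterations)``.  Deterministic: the
    algorithm has no random element.
    """
    cfg = cfg or HeptConfig()
    if jump.d.size != tensor.n:
        raise ValueError("jump vector length does not match tensor")
    tt = build_transition_tensors(tensor)
    state = ScoreState.initial(tensor.n, tensor.m)
    for _ in range(cfg.max_iter):
        new = iterate_once(state, tt, jump, cfg)
        change = (
            np.abs(new.va - state.va).sum()
            + np.abs(new.vh - state.vh).sum()
            + np.abs(new.ve - state.ve).sum()
        )
        state = new
        if change < cfg.epsilon:
            logger.info("converged after %d iterations (L1 change %.3g)", state.iteration, change)
            return state, True, state.iteration
    logger.warning("no convergence within %d iterations (L1 change %.3g)", cfg.max_iter, change)
    return state, False, state.iteration


def rank_proteins(state: ScoreState, index: ProteinIndex) -> list[tuple[str, float]]:
    """Proteins in descending VA order; ties broken by ascending protein ID."""
    pairs = [(index.ids[i], float(state.va[i])) for i in range(len(index))]
    return sorted(pairs, key=lambda pair: (-pair[1], pair[0]))


__all__ = [
    "HeptConfig", "ScoreState", "TransitionTensors",
    "normalize_tensor", "build_transition_tensors",
    "iterate_once", "run_hept", "rank_proteins",
]
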