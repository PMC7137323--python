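"""Scoring a protein ranking against a known essential-protein list.

Rankings are evaluated the way centrality-based essential-protein studies
report results: true-essential counts among the top-K candidates, a
precision–recall curve swept over every cutoff K = 1..n, a jackknife curve
(cumulative count of essentials encountered while walking down the ranking)
with its area, and pairwise overlap analysis between two methods' top-K
candidate sets.  A degree-centrality ranking is provided as the classical
topology-only baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RankedList:
    """An ordered protein ranking with scores and a method label."""

    ids: list[str]
    scores: list[float]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate protein IDs in ranking")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, float]], label: str = "") -> "RankedList":
        return cls(ids=[p for p, _ in pairs], scores=[s for _, s in pairs], label=label)

    def top(self, k: int) -> list[str]:
        return self.ids[:k]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class JackknifeResult:
    """Cumulative essential counts and curve areas for one ranking.

    ``auc`` is the raw trapezoid area of the cumulative-count curve over
    ranks 0..n; ``auc_normalized`` divides by the perfect ranking's area so
    a perfect ranking scores 1.0.  ``random_curve`` is the expected curve of
    a uniformly random ranking (the diagonal), for plotting/reference.
    """

    cumulative: np.ndarray
    auc: float
    auc_normalized: float
    perfect_auc: float
    random_curve: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    random_auc_normalized: float = float("nan")


def topk_essential_count(ranking: RankedList, essential: set[str], k: int) -> int:
    """How many of the top-K ranked proteins are truly essential."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"K must be in [1, {len(ranking)}]")
    return sum(1 for pid in ranking.top(k) if pid in essential)


def _essential_mask(ranking: RankedList, essential: set[str]) -> np.ndarray:
    return np.array([pid in essential for pid in ranking.ids], dtype=bool)


def pr_curve(ranking: RankedList, essential: set[str]) -> list[tuple[float, float]]:
    """(recall, precision) at every cutoff K = 1..n, in increasing K.

    precision = TP(K)/K and recall = TP(K)/|essential ∩ ranked|; no
    interpolation is applied.
    """
    hits = _essential_mask(ranking, essential)
    total = int(hits.sum())
    if total == 0:
        raise ValueError("no essential protein appears in the ranking")
    tp = np.cumsum(hits)
    ks = np.arange(1, len(ranking) + 1)
    precision = tp / ks
    recall = tp / total
    return list(zip(recall.tolist(), precision.tolist()))


def jackknife_curve(ranking: RankedList, essential: set[str]) -> JackknifeResult:
    """Cumulative essential count vs. rank, with raw and normalized areas."""
    hits = _essential_mask(ranking, essential)
    total = int(hits.sum())
    if total == 0:
        raise ValueError("no essential protein appears in the ranking")
    n = len(ranking)
    x = np.arange(n + 1)
    cum = np.concatenate([[0], np.cumsum(hits)])
    perfect = np.minimum(x, total)
    random_curve = x * (total / n)
    auc = float(np.trapezoid(cum, x))
    perfect_auc = float(np.trapezoid(perfect, x))
    random_auc = float(np.trapezoid(random_curve, x))
    return JackknifeResult(
        cumulative=cum,
        auc=auc,
        auc_normalized=auc / perfect_auc,
        perfect_auc=perfect_auc,
        random_curve=random_curve,
        random_auc_normalized=random_auc / perfect_auc,
    )


def jackknife_improvement(auc_a: float, auc_b: float) -> float:
    """Relative area improvement of method a over method b: (a - b) / b."""
    return (auc_a - auc_b) / auc_b


def overlap_analysis(
    ranking_a: RankedList,
    ranking_b: RankedList,
    essential: set[str],
    k: int,
) -> tuple[int, int, int]:
    """Top-K overlap between two methods.

    Returns ``(|A ∩ B|, |B − A|, non-essential count in B − A)`` over the
    top-K candidate sets of the two rankings.
    """
    top_a = set(ranking_a.top(k))
    top_b = set(ranking_b.top(k))
    b_minus_a = top_b - top_a
    non_ess = sum(1 for pid in b_minus_a if pid not in essential)
    return len(top_a & top_b), len(b_minus_a), non_ess


def low_score_fraction(
    ranking: RankedList, ids: set[str], top_fraction: float = 0.25
) -> float:
    """Fraction of ``ids`` ranked outside the top ``top_fraction`` of a ranking.

    Interpretation of a "low" score as a rank percentile (default: below the
    top 25%, i.e. in the bottom 75%); proteins absent from the ranking count
    as low.
    """
    if not ids:
        return float("nan")
    cutoff = int(np.ceil(top_fraction * len(ranking)))
    top = set(ranking.top(cutoff))
    return sum(1 for pid in ids if pid not in top) / len(ids)


def degree_centrality_baseline(edges: set[tuple[int, int]], index) -> RankedList:
    """Ranking by PPI degree (descending; ties broken by ascending ID)."""
    n = len(index)
    deg = np.zeros(n)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    pairs = sorted(
        ((index.ids[i], float(deg[i])) for i in range(n)),
        key=lambda pair: (-pair[1], pair[0]),
    )
    return RankedList.from_pairs(pairs, label="DC")


def evaluation_report(
    ranking: RankedList,
    essential: set[str],
    ks: tuple[int, ...] = (100, 200, 300, 400, 500, 600),
) -> dict:
    """JSON-ready summary: top-K counts, PR points and jackknife areas."""
    n = len(ranking)
    jack = jackknife_curve(ranking, essential)
    return {
        "method": ranking.label,
        "n": n,
        "n_essential_in_ranking": int(_essential_mask(ranking, essential).sum()),
        "topk_counts": {k: topk_essential_count(ranking, essential, k) for k in ks if k <= n},
        "pr_points": pr_curve(ranking, essential),
        "jackknife_auc": jack.auc,
        "jackknife_auc_normalized": jack.auc_normalized,
    }


def plot_curves(reports: list[dict], path) -> None:
    """Optional PR-curve plot for a list of evaluation reports (convenience)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for rep in reports:
        pts = rep["pr_points"]
        ax.plot([r for r, _ in pts], [p for _, p in pts], label=rep.get("method") or "method")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
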