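"""Edge-restricted AUROC/AUPR scoring of rankings against a gold standard.

A re-ranker cannot introduce links, so scoring the full candidate space
would mix re-ranking quality with the upstream method's recall.  The
protocol here therefore restricts the gold standard to the true edges
present in the *original* ranking's top ``x`` before computing curves; both
the original and the re-ranked list are scored against that same restricted
gold.  The resulting scores depend on the original prediction and are only
meaningful for before/after comparisons, not across inference methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .ranking import GoldStandard, Ranking


@dataclass(frozen=True)
class EvalResult:
    """Scores of one ranking against a restricted gold standard."""

    auroc: float
    aupr: float
    tp_at_k: tuple[int, ...] = field(repr=False)
    restricted_gold_size: int


def restrict_gold(gold: GoldStandard, original_top_x: Ranking) -> GoldStandard:
    """Drop gold edges absent from the original top-``x`` ranking."""
    present = set(original_top_x.links)
    return GoldStandard(gold.true_links & present)


def score(r: Ranking, gold: GoldStandard) -> EvalResult:
    """AUROC and step-wise AUPR of a strict ranking.

    AUROC is the probability a true link outranks a false one (rank ties are
    impossible); AUPR is the step-wise area ``sum_k (R_k - R_{k-1}) * P_k``
    with no interpolation.  ``gold`` must be nonempty and a strict subset of
    the ranked links.
    """
    labels = np.fromiter(
        (link in gold for link in r.links), dtype=bool, count=len(r)
    )
    n_true = int(labels.sum())
    if n_true == 0:
        raise ValueError("restricted gold standard is empty; curves undefined")
    if n_true == len(r):
        raise ValueError("every ranked link is true; curves undefined")
    # higher score = better rank
    scores = np.arange(len(r), 0, -1, dtype=float)
    auroc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    tp_at_k = tuple(int(v) for v in np.cumsum(labels))
    return EvalResult(auroc, aupr, tp_at_k, n_true)


@dataclass(frozen=True)
class ComparisonReport:
    """Before/after comparison of a re-ranking at equal link sets."""

    original: EvalResult
    reranked: EvalResult
    delta_auroc: float
    delta_aupr: float
    tp_difference: tuple[int, ...] = field(repr=False)  # reranked TP@k - original TP@k
    overlap_k: int
    shared_links: int
    tp_retained: int
    tp_among_entrants: int


def compare(
    original: Ranking,
    reranked: Ranking,
    gold: GoldStandard,
    overlap_k: int = 75,
) -> ComparisonReport:
    """Score both rankings on the same restricted gold and diff them.

    ``tp_difference[k-1]`` is the surplus of true links the re-ranked list
    has discovered at threshold ``k``.  Overlap statistics describe the
    top-``overlap_k`` prefixes: links shared by both, true links retained
    from the original prefix, and true links among the entrants.
    """
    if set(original.links) != set(reranked.links):
        raise ValueError("original and re-ranked lists cover different links")
    restricted = restrict_gold(gold, original)
    res_orig = score(original, restricted)
    res_new = score(reranked, restricted)
    tp_diff = tuple(
        b - a for a, b in zip(res_orig.tp_at_k, res_new.tp_at_k)
    )
    k = min(overlap_k, len(original))
    top_orig = set(original.links[:k])
    top_new = set(reranked.links[:k])
    entrants = top_new - top_orig
    return ComparisonReport(
        original=res_orig,
        reranked=res_new,
        delta_auroc=res_new.auroc - res_orig.auroc,
        delta_aupr=res_new.aupr - res_orig.aupr,
        tp_difference=tp_diff,
        overlap_k=k,
        shared_links=len(top_orig & top_new),
        tp_retained=sum(1 for l in top_orig & top_new if l in restricted),
        tp_among_entrants=sum(1 for l in entrants if l in restricted),
    )
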