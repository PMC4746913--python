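"""Ensemble of independent annealing runs, aggregated rank-wise.

The total cost landscape is non-convex with many local optima, so a single
annealing run is unreliable.  The final output averages many independent
runs rank-wise: each link's aggregate score is its mean rank across runs,
and the final ranking sorts by that mean (ties broken toward the original
rank).  Runs are embarrassingly parallel; per-run seeds derive
deterministically from a master seed, so neither worker count nor
completion order affects the result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .annealing import AnnealConfig, AnnealResult, run_annealing
from .penalties import StructuralConfig
from .ranking import DirectedLink, Ranking, extract_top_x

_SEED_MOD = 2**31


@dataclass(frozen=True)
class EnsembleConfig:
    """Number of independent optimization runs and how to schedule them."""

    runs: int = 100
    workers: int = 1
    master_seed: int = 0

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def derive_seed(master_seed: int, run_index: int) -> int:
    """Deterministic, well-mixed per-run seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed) % _SEED_MOD, run_index])
    return int(ss.generate_state(1)[0]) % _SEED_MOD


def average_rankings(runs: Sequence[Ranking]) -> Ranking:
    """Aggregate output rankings rank-wise into the final ranking.

    Each link's score is the mean of its ranks across runs; sorting is by
    ascending mean with ties broken by original rank (conservative toward
    the input prediction).
    """
    if not runs:
        raise ValueError("need at least one ranking to average")
    first = runs[0]
    link_set = set(first.links)
    mean_rank = dict.fromkeys(first.links, 0.0)
    for r in runs:
        if set(r.links) != link_set:
            raise ValueError("rankings cover different link sets")
        for rank, link in enumerate(r.links, start=1):
            mean_rank[link] += rank
    n = len(runs)
    orig = first.original_rank
    final = sorted(link_set, key=lambda l: (mean_rank[l] / n, orig[l]))
    return first.with_order(final)


def _one_run(
    r0: Ranking, scfg: StructuralConfig, acfg: AnnealConfig, n: int, seed: int
) -> AnnealResult:
    return run_annealing(r0, scfg, replace(acfg, seed=seed), n=n)


def rerank(
    r0: Ranking,
    scfg: StructuralConfig,
    acfg: AnnealConfig,
    ecfg: EnsembleConfig,
    n: int = 25,
    return_runs: bool = False,
):
    """Re-rank an extracted top-``x`` ranking with an ensemble of runs.

    Returns the averaged :class:`~netter.ranking.Ranking`, or
    ``(ranking, [AnnealResult, ...])`` with ``return_runs``.
    """
    seeds = [derive_seed(ecfg.master_seed, i) for i in range(ecfg.runs)]
    if ecfg.workers == 1:
        results = [_one_run(r0, scfg, acfg, n, s) for s in seeds]
    else:
        results = Parallel(n_jobs=ecfg.workers)(
            delayed(_one_run)(r0, scfg, acfg, n, s) for s in seeds
        )
    final = average_rankings([res.ranking for res in results])
    if return_runs:
        return final, results
    return final


def run_netter(
    pred: Sequence[tuple[DirectedLink, float]],
    scfg: StructuralConfig,
    acfg: AnnealConfig,
    ecfg: EnsembleConfig,
    x: int = 750,
    n: int = 25,
) -> Ranking:
    """Full pipeline: extract the top ``x`` links, optimize, average."""
    r0 = extract_top_x(pred, x)
    return rerank(r0, scfg, acfg, ecfg, n=n)
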