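"""Simulated-annealing optimization of a single ranking.

One optimization run walks the space of permutations of the top-``x`` links.
A step draws ``gamma ~ U{1..Gamma}`` distinct links and displaces each by
``theta ~ U{-Theta..Theta} \\ {0}`` positions (targets clamped to ``[1, x]``,
applied sequentially).  The mutated ranking is kept if it lowers the total
cost ``f(l) = s(l) + alpha * Delta(l)``, or with Metropolis probability
``exp(-(f(l') - f(l)) / T)`` otherwise; the temperature follows an
exponential schedule ``T <- mu * T``.

Manual temperature tuning is replaced by an automatic restart: if the
acceptance ratio of cost-increasing ("bad") mutations over the starting
window is outside the configured band, ``T0`` is doubled (ratio too low) or
halved (too high) and the run restarts from the input ranking.
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .penalties import StructuralConfig, total_cost, total_cost_fresh
from .ranking import DirectedLink, Ranking
from .subnetworks import SubnetworkConfig, SubnetworkStack, build


@dataclass(frozen=True)
class AnnealConfig:
    """Mutation bounds, schedule and thermostat of one annealing run.

    ``gamma_max`` bounds how many links a step moves; ``theta_max`` bounds
    each link's displacement in positions.  ``mu`` defaults to a decay of
    four orders of magnitude over the schedule, ``10**(-4/iterations)``;
    ``t0`` defaults to the mean ``|delta-cost|`` of 100 probe moves.  Both
    are then corrected by the restart calibration, which targets a
    ``bad_accept_range`` acceptance ratio of cost-increasing moves over the
    first ``start_window_fraction`` of iterations.
    """

    gamma_max: int = 50
    theta_max: int = 70
    iterations: int = 30000
    start_window_fraction: float = 0.1
    bad_accept_range: tuple[float, float] = (0.05, 0.15)
    mu: float | None = None
    t0: float | None = None
    seed: int | None = None
    max_restarts: int = 10
    calibrate: bool = True
    min_calibration_samples: int = 30
    force_accept: bool = False

    def __post_init__(self):
        if self.gamma_max < 1 or self.theta_max < 1:
            raise ValueError("gamma_max and theta_max must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.start_window_fraction < 1.0:
            raise ValueError("start_window_fraction must lie in (0, 1)")
        if self.mu is not None and not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")

    @property
    def effective_mu(self) -> float:
        return self.mu if self.mu is not None else 10.0 ** (-4.0 / self.iterations)


@dataclass
class AnnealResult:
    """Outcome of one run: the optimized ranking plus diagnostics."""

    ranking: Ranking
    final_cost: float
    t0: float
    restarts: int
    bad_accept_ratio: float | None  # over the start window; None if no bad moves
    proposed: int
    accepted: int
    trajectory: list[tuple] | None = field(default=None, repr=False)


def scaled_anneal_config(x: int, reference_x: int = 750, **overrides) -> AnnealConfig:
    """Defaults with mutation bounds scaled to a ranking of length ``x``.

    The stock bounds (50 links, 70 positions) are sized for ``x = 750``;
    on smaller problems the same proportions keep the walk's mixing time
    comparable.  Lower bounds of 3 links / 5 positions apply.
    """
    scale = x / reference_x
    cfg = dict(
        gamma_max=max(3, round(50 * scale)),
        theta_max=max(5, round(70 * scale)),
    )
    cfg.update(overrides)
    return AnnealConfig(**cfg)


def propose_move(
    stack: SubnetworkStack, cfg: AnnealConfig, rng: random.Random
) -> list[tuple[DirectedLink, int]]:
    """Draw a mutation: ``gamma`` distinct links with clamped target ranks."""
    x = stack.x
    if x < 2:
        raise ValueError("ranking must contain at least 2 links")
    gamma = rng.randint(1, min(cfg.gamma_max, x))
    lids = rng.sample(range(x), gamma)
    theta_max = cfg.theta_max
    move = []
    rank = stack.rank
    links = stack.links
    for lid in lids:
        theta = rng.randint(1, theta_max)
        if rng.random() < 0.5:
            theta = -theta
        target = rank[lid] + theta
        if target < 1:
            target = 1
        elif target > x:
            target = x
        move.append((links[lid], target))
    return move


def accept(delta_cost: float, temperature: float, draw: float) -> bool:
    """Metropolis rule: downhill always, uphill with ``exp(-delta/T)``."""
    if delta_cost < 0:
        return True
    arg = delta_cost / temperature
    if arg > 700.0:  # exp underflow guard
        return False
    return draw < math.exp(-arg)


def _probe_t0(
    stack: SubnetworkStack,
    scfg: StructuralConfig,
    acfg: AnnealConfig,
    rng: random.Random,
    n_probe: int = 100,
) -> float:
    """Mean |delta-cost| over probe moves (applied and reverted)."""
    base = total_cost(stack, scfg)
    acc = 0.0
    for _ in range(n_probe):
        move = propose_move(stack, acfg, rng)
        record = stack.apply_move(move)
        acc += abs(total_cost(stack, scfg) - base)
        stack.revert(record)
    mean = acc / n_probe
    return mean if mean > 0 else 1.0


def run_annealing(
    r0: Ranking,
    scfg: StructuralConfig,
    acfg: AnnealConfig,
    n: int = 25,
    log_trajectory_every: int = 0,
    verify_cost_each_step: bool = False,
) -> AnnealResult:
    """Run one full annealing schedule on ``r0`` and return the result.

    ``n`` is the subnetwork step size.  With a fixed ``acfg.seed`` the output
    is bit-reproducible.  ``verify_cost_each_step`` recomputes the total cost
    from scratch after every step and asserts agreement within 1e-9 (debug).
    """
    if len(r0) < 2:
        raise ValueError("ranking must contain at least 2 links")
    rng = random.Random(acfg.seed)
    mu = acfg.effective_mu
    track_structure = any(p.weight > 0 for p in scfg.penalties)
    sub_cfg = SubnetworkConfig(n=n, x=len(r0))

    def fresh_stack() -> SubnetworkStack:
        return build(
            r0,
            sub_cfg,
            track_structure=track_structure,
            track_graphlets=scfg.needs_graphlets,
        )

    stack = fresh_stack()
    if acfg.t0 is not None:
        t0 = acfg.t0
    else:
        t0 = _probe_t0(stack, scfg, acfg, rng)

    window = max(1, int(acfg.start_window_fraction * acfg.iterations))
    lo, hi = acfg.bad_accept_range
    calibrating = acfg.calibrate and not acfg.force_accept
    restarts = 0

    while True:
        temperature = t0
        cur_cost = total_cost(stack, scfg)
        proposed = accepted = 0
        bad_proposed = bad_accepted = 0
        ratio: float | None = None
        trajectory: list[tuple] | None = [] if log_trajectory_every else None
        aborted = False
        for it in range(acfg.iterations):
            move = propose_move(stack, acfg, rng)
            record = stack.apply_move(move)
            new_cost = total_cost(stack, scfg)
            delta = new_cost - cur_cost
            proposed += 1
            if acfg.force_accept:
                ok = True
            else:
                ok = accept(delta, temperature, rng.random())
            if it < window and delta > 0:
                bad_proposed += 1
                if ok:
                    bad_accepted += 1
            if ok:
                cur_cost = new_cost
                accepted += 1
            else:
                stack.revert(record)
            if verify_cost_each_step:
                fresh = total_cost_fresh(stack.current_ranking(), scfg, n)
                cached = total_cost(stack, scfg)
                if abs(cached - fresh) > 1e-9:
                    raise AssertionError(
                        f"incremental cost {cached!r} != fresh cost {fresh!r} "
                        f"at iteration {it}"
                    )
            if trajectory is not None and it % log_trajectory_every == 0:
                trajectory.append(
                    (it, temperature, cur_cost, cur_cost - scfg.alpha
                     * stack.divergence, stack.divergence, ok)
                )
            temperature *= mu
            if calibrating and it == window - 1:
                # too few uphill proposals cannot resolve the band
                if bad_proposed < acfg.min_calibration_samples:
                    ratio = None
                else:
                    ratio = bad_accepted / bad_proposed
                if ratio is not None and not lo <= ratio <= hi:
                    if restarts >= acfg.max_restarts:
                        raise RuntimeError(
                            f"temperature calibration failed after "
                            f"{restarts} restarts; last bad-acceptance "
                            f"ratio {ratio:.3f} outside [{lo}, {hi}]"
                        )
                    t0 = t0 * 2.0 if ratio < lo else t0 / 2.0
                    restarts += 1
                    stack = fresh_stack()
                    aborted = True
                    break
        if aborted:
            continue
        if ratio is None and bad_proposed:
            ratio = bad_accepted / bad_proposed
        return AnnealResult(
            ranking=stack.current_ranking(),
            final_cost=cur_cost,
            t0=t0,
            restarts=restarts,
            bad_accept_ratio=ratio,
            proposed=proposed,
            accepted=accepted,
            trajectory=trajectory,
        )


def write_trajectory(trajectory: Sequence[tuple], path) -> None:
    """Write a trajectory log as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["iteration", "temperature", "total_cost", "structural_cost",
             "divergence", "accepted"]
        )
        writer.writerows(trajectory)
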