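"""Structural cost machinery: v-shaped penalties over subnetwork statistics.

Each penalty maps a structural statistic ``y`` of a subnetwork to a cost
through the v-shaped function ``s(y) = |a*y + b|`` and carries a relative
weight.  The structural cost of a ranking is the doubly weighted sum

    s(l) = sum_i  pi_i * sum_p  weight_p * |a_p * y_p(g_i) + b_p|

over the nested prefix subnetworks ``g_i``, with coefficients
``pi_i = pi_base**i`` decreasing in subnetwork size so that the top of the
ranking dominates.  The total objective adds the divergence regularizer:
``f(l) = s(l) + alpha * Delta(l)``.

Three statistics ship by default, each targeting a known pathology of
expression-based network inference:

``g4_frequency``
    Share of 3-star graphlets among connected 4-node graphlets; rewarded
    (zero cost at 1) because hub-and-spoke modularity is typical of
    transcriptional networks while inferred networks tend toward full mesh.
``regulator_fraction``
    Fraction of genes with at least one outgoing link; penalized because
    indirect effects make nearly every gene look like a regulator.
``max_outdegree_share``
    Largest share of links claimed by a single regulator; penalized above a
    threshold so one hub cannot monopolize the top of the ranking.  Costs
    left of the intercept are clamped to zero -- spreading across modules
    must never be discouraged.

New statistics register through :func:`register_statistic`; they receive the
per-subnetwork cached state and must be cheap, as they are evaluated after
every mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import yaml

from .ranking import Ranking
from .subnetworks import SubnetworkStack


# ---------------------------------------------------------------------------
# Statistics registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _StatDef:
    fn: Callable  # _Subnet -> float
    needs_graphlets: bool


_REGISTRY: dict[str, _StatDef] = {}


def register_statistic(
    name: str, fn: Callable, needs_graphlets: bool = False
) -> None:
    """Register a named subnetwork statistic usable by penalties."""
    _REGISTRY[name] = _StatDef(fn, needs_graphlets)


def _out_degree(g):
    """(gene, out-degree) pairs of a directed graph (networkx or similar)."""
    return g.out_degree()


def regulatory_y(g) -> float:
    """Fraction of genes with at least one outgoing link.

    ``g`` is a directed graph (e.g. ``networkx.DiGraph``).  Empty graph -> 0.
    """
    degs = list(_out_degree(g))
    if not degs:
        return 0.0
    return sum(1 for _, d in degs if d >= 1) / len(degs)


def antidominating_y(g) -> float:
    """Largest out-degree divided by the total number of links.

    Measures how strongly a single regulator dominates.  Zero links -> 0.
    """
    degs = [d for _, d in _out_degree(g)]
    n_links = sum(degs)
    if n_links == 0:
        return 0.0
    return max(degs) / n_links


def _stat_g4(sub) -> float:
    from .graphlets import g4_relative_frequency

    return g4_relative_frequency(sub.glc.counts)


def _stat_regulator_fraction(sub) -> float:
    n = sub.n_nodes
    return sub.n_regulators / n if n else 0.0


def _stat_max_outdegree_share(sub) -> float:
    return sub.max_out_degree / sub.n_links if sub.n_links else 0.0


register_statistic("g4_frequency", _stat_g4, needs_graphlets=True)
register_statistic("regulator_fraction", _stat_regulator_fraction)
register_statistic("max_outdegree_share", _stat_max_outdegree_share)


# ---------------------------------------------------------------------------
# Penalty and configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VShapePenalty:
    """A weighted v-shaped mapping ``weight * |a*y + b|`` of a statistic.

    With ``clamp_below_zero`` the negative branch ``a*y + b < 0`` costs
    nothing instead of folding upward (used where only one direction of the
    statistic is meaningful).
    """

    name: str
    y_fn: str
    a: float
    b: float
    weight: float
    clamp_below_zero: bool = False

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("penalty weight must be >= 0")
        if self.y_fn not in _REGISTRY:
            raise ValueError(f"unknown statistic {self.y_fn!r}")


def vshape(p: VShapePenalty, y: float) -> float:
    """Evaluate the (unweighted) v-shaped cost of statistic value ``y``."""
    v = p.a * y + p.b
    if p.clamp_below_zero:
        return v if v > 0.0 else 0.0
    return abs(v)


@dataclass(frozen=True)
class StructuralConfig:
    """Penalty set plus the global knobs of the structural cost.

    ``alpha`` balances structure against divergence from the original
    ranking; ``pi_base**i`` weights subnetwork ``g_i`` (strictly decreasing).
    """

    penalties: tuple[VShapePenalty, ...]
    alpha: float = 1e-5
    pi_base: float = 0.5

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 < self.pi_base < 1.0:
            raise ValueError("pi_base must lie in (0, 1)")

    @property
    def needs_graphlets(self) -> bool:
        return any(
            _REGISTRY[p.y_fn].needs_graphlets and p.weight > 0
            for p in self.penalties
        )

    def pi(self, i: int) -> float:
        """Coefficient of subnetwork ``g_i`` (1-based)."""
        return self.pi_base ** i


def default_penalties() -> tuple[VShapePenalty, ...]:
    return (
        VShapePenalty("graphlet", "g4_frequency", a=1.0, b=-1.0, weight=25.0),
        VShapePenalty("regulatory", "regulator_fraction", a=1.0, b=0.0, weight=2.0),
        VShapePenalty(
            "antidominating",
            "max_outdegree_share",
            a=1.0,
            b=-0.1,
            weight=75.0,
            clamp_below_zero=True,
        ),
    )


def default_config(alpha: float = 1e-5, pi_base: float = 0.5) -> StructuralConfig:
    """The shipped defaults: graphlet 25, regulatory 2, anti-dominating 75."""
    return StructuralConfig(default_penalties(), alpha=alpha, pi_base=pi_base)


# ---------------------------------------------------------------------------
# Cost evaluation
# ---------------------------------------------------------------------------

def subnetwork_penalty(sub, penalties: Sequence[VShapePenalty]) -> float:
    """Weighted penalty of a single subnetwork (no pi coefficient)."""
    total = 0.0
    for p in penalties:
        if p.weight == 0.0:
            continue
        y = _REGISTRY[p.y_fn].fn(sub)
        total += p.weight * vshape(p, y)
    return total


def structural_cost(stack: SubnetworkStack, cfg: StructuralConfig) -> float:
    """``s(l)``: pi-weighted penalties over all subnetworks.

    Per-subnetwork terms are cached on the stack and recomputed only for
    subnetworks the last moves touched.
    """
    if not stack.track_structure:
        if any(p.weight > 0 for p in cfg.penalties):
            raise ValueError(
                "stack was built without structure tracking but the "
                "configuration has active penalties"
            )
        return 0.0
    key = id(cfg)
    if stack.cache_key != key:
        stack.penalty_cache.clear()
        stack.dirty = set(range(len(stack.subnets)))
        stack.cache_key = key
    cache = stack.penalty_cache
    for j in stack.dirty:
        cache[j] = subnetwork_penalty(stack.subnets[j], cfg.penalties)
    stack.dirty.clear()
    total = 0.0
    for j in range(len(stack.subnets)):
        total += cfg.pi(j + 1) * cache[j]
    return total


def total_cost(stack: SubnetworkStack, cfg: StructuralConfig) -> float:
    """``f(l) = s(l) + alpha * Delta(l)`` of the stack's current ranking."""
    return structural_cost(stack, cfg) + cfg.alpha * stack.divergence


def total_cost_fresh(current: Ranking, cfg: StructuralConfig, n: int) -> float:
    """From-scratch total cost (oracle for the incremental path)."""
    from . import subnetworks

    stack = subnetworks.build(
        current,
        subnetworks.SubnetworkConfig(n=n, x=len(current)),
        track_graphlets=cfg.needs_graphlets,
    )
    return total_cost(stack, cfg)


# ---------------------------------------------------------------------------
# Config file I/O (YAML)
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[StructuralConfig, dict]:
    """Load a structural configuration from YAML.

    Returns ``(StructuralConfig, extras)`` where ``extras`` holds any
    run-level settings present in the file (``n``, ``x``, annealing keys...).

    Schema::

        alpha: 1.0e-5
        pi_base: 0.5
        n: 25
        x: 750
        penalties:
          - {name: graphlet, y_fn: g4_frequency, a: 1.0, b: -1.0, weight: 25.0}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    pen_specs = data.pop("penalties", None)
    if pen_specs is None:
        penalties = default_penalties()
    else:
        penalties = tuple(
            VShapePenalty(
                name=p["name"],
                y_fn=p["y_fn"],
                a=float(p["a"]),
                b=float(p["b"]),
                weight=float(p["weight"]),
                clamp_below_zero=bool(p.get("clamp_below_zero", False)),
            )
            for p in pen_specs
        )
    cfg = StructuralConfig(
        penalties,
        alpha=float(data.pop("alpha", 1e-5)),
        pi_base=float(data.pop("pi_base", 0.5)),
    )
    return cfg, data


def save_config(cfg: StructuralConfig, extras: dict, path: str | Path) -> None:
    data = dict(extras)
    data["alpha"] = cfg.alpha
    data["pi_base"] = cfg.pi_base
    data["penalties"] = [
        {
            "name": p.name,
            "y_fn": p.y_fn,
            "a": p.a,
            "b": p.b,
            "weight": p.weight,
            "clamp_below_zero": p.clamp_below_zero,
        }
        for p in cfg.penalties
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def with_weights(cfg: StructuralConfig, **weights: float) -> StructuralConfig:
    """Copy of ``cfg`` with selected penalty weights replaced by name."""
    new = tuple(
        replace(p, weight=weights[p.name]) if p.name in weights else p
        for p in cfg.penalties
    )
    unknown = set(weights) - {p.name for p in cfg.penalties}
    if unknown:
        raise KeyError(f"no penalties named {sorted(unknown)}")
    return replace(cfg, penalties=new)
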