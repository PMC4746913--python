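"""Synthetic gold-standard networks and degraded prediction rankings.

The re-ranker assumes transcriptional networks with an approximately
scale-free out-degree distribution (few regulators, heavy-tailed hub sizes)
organised into co-regulated modules, and predictions whose errors follow the
known pathologies of expression-based inference: indirect effects (if A
regulates B and C, a spurious B-C link is predicted nearby) and
direction-ambiguous near-duplicate reversed links.  This module generates
exactly that: a modular hub network, then a noisy ranking in which true
links concentrate near the top and the injected false positives interleave
with their parent true links.

Everything is seeded and generation is performed in gene-index space with
names applied last, so permuting gene names commutes with generation.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Sequence

from .ranking import DirectedLink, GoldStandard

logger = logging.getLogger("netter")


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Shape of a ground-truth regulatory network.

    ``module_size_power`` sets the heavy tail of module sizes (weights
    ``k**-power``); larger values concentrate targets in fewer hubs.
    """

    n_genes: int = 100
    n_regulators: int = 10
    modules: int = 8
    module_size_power: float = 1.0
    secondary_prob: float = 0.4
    reg_chain_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_regulators >= self.n_genes:
            raise ValueError("need n_regulators < n_genes")
        if self.modules > self.n_regulators:
            raise ValueError("each module needs its own primary regulator")
        if self.modules < 1:
            raise ValueError("need at least one module")


@dataclass(frozen=True)
class CorruptionSpec:
    """How to degrade a gold standard into a plausible noisy prediction.

    ``indirect_fp_rate`` is the probability that a co-regulated target pair
    contributes a spurious target-target link; ``bidir_dup_rate`` the
    probability that a true link's reversal is inserted just below it.
    """

    noise_sd: float = 0.2
    indirect_fp_rate: float = 0.1
    bidir_dup_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("indirect_fp_rate", "bidir_dup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def _generate_structure(spec: SyntheticNetworkSpec, rng: random.Random):
    """True links in index space, in a deterministic generation order."""
    n_reg = spec.n_regulators
    targets = list(range(n_reg, spec.n_genes))
    m = spec.modules
    weights = [(k + 1) ** -spec.module_size_power for k in range(m)]
    membership = rng.choices(range(m), weights=weights, k=len(targets))
    module_targets: list[list[int]] = [[] for _ in range(m)]
    for tgt, mod in zip(targets, membership):
        module_targets[mod].append(tgt)
    links: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()

    def add(reg: int, tgt: int) -> None:
        if reg != tgt and (reg, tgt) not in seen:
            seen.add((reg, tgt))
            links.append((reg, tgt))

    spare_regs = list(range(m, n_reg))
    for mod in range(m):
        primary = mod
        # 0-2 secondary regulators co-drive the module (1-3 dominant genes)
        pool = [r for r in spare_regs + list(range(m)) if r != primary]
        n_secondary = rng.choices((0, 1, 2), weights=(4, 4, 2))[0]
        secondaries = rng.sample(pool, min(n_secondary, len(pool)))
        for tgt in module_targets[mod]:
            add(primary, tgt)
            for sec in secondaries:
                if rng.random() < spec.secondary_prob:
                    add(sec, tgt)
        # occasional upstream regulator -> primary hierarchy edge
        if rng.random() < spec.reg_chain_prob:
            upstream = rng.choice([r for r in range(n_reg) if r != primary])
            add(upstream, primary)
    return links


def generate_network(
    spec: SyntheticNetworkSpec, gene_names: Sequence[str] | None = None
) -> GoldStandard:
    """Generate a modular, hub-containing ground-truth network.

    Only the first ``n_regulators`` genes can have outgoing links; every
    other gene receives at least one incoming link from its module's primary
    regulator.  Identical seeds yield identical networks.
    """
    names = list(gene_names) if gene_names is not None else _default_names(spec.n_genes)
    if len(names) != spec.n_genes:
        raise ValueError("gene_names length must equal n_genes")
    rng = random.Random(spec.seed)
    links = _generate_structure(spec, rng)
    return GoldStandard(DirectedLink(names[a], names[b]) for a, b in links)


def _corrupt(
    true_links: Sequence[tuple],
    spec: CorruptionSpec,
    x: int,
    all_ids: Sequence,
    rng: random.Random,
) -> list[tuple[tuple, float]]:
    """Corruption core over hashable gene ids; ``true_links`` order matters."""
    scores: dict[tuple, float] = {}
    for link in true_links:
        scores[link] = 0.7 + rng.gauss(0.0, spec.noise_sd)
    # near-duplicate reversed links just below their parent
    for reg, tgt in true_links:
        if rng.random() < spec.bidir_dup_rate:
            rev = (tgt, reg)
            if rev not in scores:
                scores[rev] = scores[(reg, tgt)] - abs(rng.gauss(0.0, 0.03))
    # indirect effects: co-regulated targets acquire spurious links
    by_reg: dict = {}
    for reg, tgt in true_links:
        by_reg.setdefault(reg, []).append(tgt)
    for reg, tgts in by_reg.items():
        for i, b in enumerate(tgts):
            for c in tgts[i + 1:]:
                if rng.random() < spec.indirect_fp_rate:
                    pair = (b, c) if rng.random() < 0.5 else (c, b)
                    if pair not in scores:
                        parent = 0.5 * (scores[(reg, b)] + scores[(reg, c)])
                        scores[pair] = parent - abs(rng.gauss(0.0, 0.1))
    # random false links fill the tail of the ranking
    n_fill = x - len(scores)
    attempts = 0
    while n_fill > 0 and attempts < 100 * x:
        attempts += 1
        a = all_ids[rng.randrange(len(all_ids))]
        b = all_ids[rng.randrange(len(all_ids))]
        if a == b or (a, b) in scores:
            continue
        # background noise sits below the clean true-signal level
        scores[(a, b)] = min(0.35 + rng.gauss(0.0, 0.15), 0.65)
        n_fill -= 1
    ranked = sorted(
        scores.items(), key=lambda kv: -kv[1]
    )[:x]
    return [(link, max(s, 1e-4)) for link, s in ranked]


def corrupt_to_ranking(
    gold: GoldStandard, spec: CorruptionSpec, x: int
) -> list[tuple[DirectedLink, float]]:
    """Degrade a gold standard into a scored prediction of ``x`` links.

    True links receive high, noisy scores; indirect and reversed false
    positives are injected with scores interleaved near their parents;
    random false links fill the remainder.  Output is sorted by decreasing
    score.
    """
    true_links = sorted(gold.true_links)
    if x < len(true_links):
        logger.warning(
            "x=%d is smaller than the %d true links; ranking is truncated",
            x,
            len(true_links),
        )
    genes = sorted({g for l in gold.true_links for g in l})
    rng = random.Random(spec.seed)
    ranked = _corrupt(true_links, spec, x, genes, rng)
    return [(DirectedLink(*pair), s) for pair, s in ranked]


def fixture_battery(
    count: int = 10, base_seed: int = 0, x: int = 150
) -> list[tuple[GoldStandard, list[tuple[DirectedLink, float]], "object"]]:
    """A battery of varied small benchmark fixtures for end-to-end checks.

    Yields ``(gold, prediction, r0_length)`` tuples over networks of 50-95
    genes with default corruption; seeds derive from ``base_seed`` so the
    battery is reproducible.
    """
    out = []
    for i in range(count):
        genes = 50 + 5 * (i % 10)
        n_reg = max(6, genes // 8)
        modules = max(4, n_reg - 2)
        net = SyntheticNetworkSpec(
            n_genes=genes, n_regulators=n_reg, modules=modules,
            seed=base_seed * 10_000 + 1000 + i,
        )
        corr = CorruptionSpec(seed=base_seed * 10_000 + 2000 + i)
        gold, pred = simulate_prediction(net, corr, x=x)
        out.append((gold, pred, x))
    return out


def simulate_prediction(
    net_spec: SyntheticNetworkSpec,
    corr_spec: CorruptionSpec,
    x: int,
    gene_names: Sequence[str] | None = None,
) -> tuple[GoldStandard, list[tuple[DirectedLink, float]]]:
    """Generate a gold standard and its corrupted prediction in one pass.

    Both stages run in gene-index space, so renaming genes permutes the
    output without changing its structure.
    """
    names = (
        list(gene_names) if gene_names is not None else _default_names(net_spec.n_genes)
    )
    if len(names) != net_spec.n_genes:
        raise ValueError("gene_names length must equal n_genes")
    rng_net = random.Random(net_spec.seed)
    links = _generate_structure(net_spec, rng_net)
    rng_corr = random.Random(corr_spec.seed)
    ranked = _corrupt(links, corr_spec, x, list(range(net_spec.n_genes)), rng_corr)
    gold = GoldStandard(DirectedLink(names[a], names[b]) for a, b in links)
    pred = [(DirectedLink(names[a], names[b]), s) for (a, b), s in ranked]
    return gold, pred
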