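"""Nested prefix subnetworks of a ranking, maintained incrementally.

The structural cost of a ranking is evaluated on the graphs induced by its
prefixes: subnetworks ``g_1, g_2, ..., g_{(x/n)-1}`` built from the first
``n, 2n, ..., x-n`` links.  A proposed mutation displaces a handful of links,
so only the subnetworks whose cut point lies between a mover's old and new
rank change membership -- and then only by swapping one link in and one out.
The :class:`SubnetworkStack` exploits this: it keeps per-cut directed degree
statistics and an undirected graphlet census up to date under such swaps and
can revert the most recent move exactly.

Directed links are collapsed to undirected edges for graphlet counting
(antiparallel pairs map to a single edge); degree-based statistics use the
directed view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .graphlets import IncrementalGraphletCounter
from .ranking import DirectedLink, Ranking


@dataclass(frozen=True)
class SubnetworkConfig:
    """Cut-point layout: subnetworks at ranks ``n, 2n, ...`` strictly below ``x``."""

    n: int
    x: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("subnetwork step n must be >= 1")
        if self.n >= self.x:
            raise ValueError(f"need n < x, got n={self.n}, x={self.x}")

    @property
    def cut_points(self) -> list[int]:
        return list(range(self.n, self.x, self.n))


class _Subnet:
    """Statistics of one prefix subnetwork: directed degrees + graphlets."""

    __slots__ = ("n_links", "out_deg", "deg_hist", "incident", "und", "glc")

    def __init__(self, n_links: int, track_graphlets: bool):
        self.n_links = n_links  # prefix length; constant for a given cut
        self.out_deg: dict[str, int] = {}
        self.deg_hist: dict[int, int] = {}  # out-degree -> number of genes
        self.incident: dict[str, int] = {}  # gene -> number of incident links
        self.und: dict[tuple[str, str], int] = {}  # undirected edge multiplicity
        self.glc = IncrementalGraphletCounter() if track_graphlets else None

    # Genes exist in a subnetwork only while incident to a contained link.

    @property
    def n_nodes(self) -> int:
        return len(self.incident)

    @property
    def n_regulators(self) -> int:
        return len(self.out_deg)

    @property
    def max_out_degree(self) -> int:
        return max(self.deg_hist) if self.deg_hist else 0

    def add_link(self, link: DirectedLink) -> None:
        reg, tgt = link
        d = self.out_deg.get(reg, 0)
        if d:
            h = self.deg_hist
            h[d] -= 1
            if not h[d]:
                del h[d]
        self.out_deg[reg] = d + 1
        self.deg_hist[d + 1] = self.deg_hist.get(d + 1, 0) + 1
        self.incident[reg] = self.incident.get(reg, 0) + 1
        self.incident[tgt] = self.incident.get(tgt, 0) + 1
        key = (reg, tgt) if reg < tgt else (tgt, reg)
        mult = self.und.get(key, 0)
        self.und[key] = mult + 1
        if mult == 0 and self.glc is not None:
            self.glc.add_edge(*key)

    def remove_link(self, link: DirectedLink) -> None:
        reg, tgt = link
        d = self.out_deg[reg]
        h = self.deg_hist
        h[d] -= 1
        if not h[d]:
            del h[d]
        if d == 1:
            del self.out_deg[reg]
        else:
            self.out_deg[reg] = d - 1
            h[d - 1] = h.get(d - 1, 0) + 1
        for gene in (reg, tgt):
            c = self.incident[gene]
            if c == 1:
                del self.incident[gene]
            else:
                self.incident[gene] = c - 1
        key = (reg, tgt) if reg < tgt else (tgt, reg)
        mult = self.und[key]
        if mult == 1:
            del self.und[key]
            if self.glc is not None:
                self.glc.remove_edge(*key)
        else:
            self.und[key] = mult - 1

    def snapshot(self) -> dict:
        return {
            "out_deg": dict(self.out_deg),
            "deg_hist": dict(self.deg_hist),
            "incident": dict(self.incident),
            "und": dict(self.und),
            "graphlets": None if self.glc is None else self.glc.counts,
        }


@dataclass
class ChangeRecord:
    """Everything needed to undo one applied move exactly."""

    relocations: list[tuple[int, int, int]]  # (link id, old rank, new rank)
    seq: int
    reverted: bool = field(default=False, compare=False)


class SubnetworkStack:
    """The mutable ranking state plus its nested subnetwork statistics.

    Built once from a :class:`~netter.ranking.Ranking`, then driven through
    :meth:`apply_move` / :meth:`revert` by the optimizer.  Also tracks the
    squared-displacement divergence from the original ranking incrementally.
    """

    def __init__(
        self,
        ranking: Ranking,
        cfg: SubnetworkConfig,
        track_structure: bool = True,
        track_graphlets: bool = True,
    ):
        if cfg.x != len(ranking):
            raise ValueError(
                f"config x={cfg.x} does not match ranking length {len(ranking)}"
            )
        self.cfg = cfg
        self.links: list[DirectedLink] = list(ranking.links)
        self.link_id: dict[DirectedLink, int] = {
            l: i for i, l in enumerate(self.links)
        }
        self.order: list[int] = list(range(len(self.links)))
        self.rank: list[int] = list(range(1, len(self.links) + 1))
        self.orig: list[int] = [ranking.original_rank[l] for l in self.links]
        self.divergence: int = sum(
            (self.orig[lid] - self.rank[lid]) ** 2 for lid in self.order
        )
        self._original_rank = dict(ranking.original_rank)
        self.cuts: list[int] = cfg.cut_points
        self.track_structure = track_structure
        self.track_graphlets = track_structure and track_graphlets
        self.subnets: list[_Subnet] = []
        if track_structure:
            for c in self.cuts:
                sub = _Subnet(c, self.track_graphlets)
                self.subnets.append(sub)
            for pos, lid in enumerate(self.order):
                rank = pos + 1
                for sub, c in zip(self.subnets, self.cuts):
                    if rank <= c:
                        sub.add_link(self.links[lid])
        # penalty-cache bookkeeping (owned by penalties.structural_cost)
        self.dirty: set[int] = set(range(len(self.cuts)))
        self.penalty_cache: dict[int, float] = {}
        self.cache_key = None
        self._next_seq = 0
        self._last_record: ChangeRecord | None = None

    @property
    def x(self) -> int:
        return len(self.links)

    # -- move application ----------------------------------------------------

    def _relocate(self, lid: int, r2: int) -> None:
        """Move link ``lid`` to rank ``r2``; intervening links shift by one."""
        order = self.order
        rank = self.rank
        orig = self.orig
        r1 = rank[lid]
        if r1 == r2:
            return
        swaps: list[tuple[int, int]] = []  # (subnet index, entering/leaving lid)
        if self.track_structure:
            n = self.cfg.n
            if r2 < r1:
                # cuts c with r2 <= c < r1: mover enters, link at rank c leaves
                j = (r2 + n - 1) // n - 1  # first cut >= r2
                c = (j + 1) * n
                while c < r1 and j < len(self.cuts):
                    swaps.append((j, order[c - 1]))
                    j += 1
                    c += n
            else:
                # cuts c with r1 <= c < r2: mover leaves, link at rank c+1 enters
                j = (r1 + n - 1) // n - 1
                c = (j + 1) * n
                while c < r2 and j < len(self.cuts):
                    swaps.append((j, order[c]))
                    j += 1
                    c += n
        i1, i2 = r1 - 1, r2 - 1
        order.pop(i1)
        order.insert(i2, lid)
        lo, hi = (i2, i1) if i2 < i1 else (i1, i2)
        div = self.divergence
        for i in range(lo, hi + 1):
            l2 = order[i]
            old = rank[l2]
            new = i + 1
            d_old = orig[l2] - old
            d_new = orig[l2] - new
            div += d_new * d_new - d_old * d_old
            rank[l2] = new
        self.divergence = div
        if swaps:
            links = self.links
            mover = links[lid]
            subnets = self.subnets
            dirty = self.dirty
            if r2 < r1:
                for j, out_lid in swaps:
                    sub = subnets[j]
                    sub.remove_link(links[out_lid])
                    sub.add_link(mover)
                    dirty.add(j)
            else:
                for j, in_lid in swaps:
                    sub = subnets[j]
                    sub.remove_link(mover)
                    sub.add_link(links[in_lid])
                    dirty.add(j)

    def apply_move(
        self, move: Sequence[tuple[DirectedLink, int]]
    ) -> ChangeRecord:
        """Apply relocations ``(link, target_rank)`` sequentially.

        Targets are clamped to ``[1, x]``.  Returns a change record for
        :meth:`revert`.
        """
        x = len(self.links)
        relocations: list[tuple[int, int, int]] = []
        for link, target in move:
            lid = self.link_id.get(link)
            if lid is None:
                raise KeyError(f"move references unknown link {link!r}")
            r2 = 1 if target < 1 else (x if target > x else target)
            r1 = self.rank[lid]
            if r1 == r2:
                continue
            self._relocate(lid, r2)
            relocations.append((lid, r1, r2))
        record = ChangeRecord(relocations, self._next_seq)
        self._next_seq += 1
        self._last_record = record
        return record

    def revert(self, record: ChangeRecord) -> None:
        """Undo ``record``; state becomes identical to before the move."""
        if record.reverted:
            raise RuntimeError("change record already reverted")
        if record is not self._last_record:
            raise RuntimeError("can only revert the most recent unreverted move")
        for lid, r1, _r2 in reversed(record.relocations):
            self._relocate(lid, r1)
        record.reverted = True
        self._last_record = None

    # -- views ---------------------------------------------------------------

    def current_ranking(self) -> Ranking:
        return Ranking(
            tuple(self.links[lid] for lid in self.order),
            dict(self._original_rank),
        )

    def snapshot(self) -> dict:
        """Canonical state for equality checks against a fresh build."""
        return {
            "order": tuple(self.links[lid] for lid in self.order),
            "divergence": self.divergence,
            "subnets": [s.snapshot() for s in self.subnets],
        }


def build(
    r: Ranking,
    cfg: SubnetworkConfig,
    track_structure: bool = True,
    track_graphlets: bool = True,
) -> SubnetworkStack:
    """Build the nested subnetwork stack of ranking ``r``."""
    return SubnetworkStack(r, cfg, track_structure, track_graphlets)
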