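"""Exact 3- and 4-node graphlet census with incremental edge updates.

Graphlets are small connected non-isomorphic *induced* subgraphs of an
undirected network.  The nine classes on 3 and 4 nodes follow the standard
numbering:

========  ==========================================
``G0``    edge (2 nodes)
``G1``    2-path (3 nodes)
``G2``    triangle
``G3``    4-path
``G4``    3-star (claw) -- promoted by hub structure
``G5``    4-cycle
``G6``    tailed triangle (paw)
``G7``    diamond (4-cycle with one chord)
``G8``    complete graph K4
========  ==========================================

The re-ranker evaluates graphlet counts thousands of times per second on
slowly-changing subnetworks, so the central object here is an
:class:`IncrementalGraphletCounter` whose single-edge add/remove updates
touch only the distance-2 neighbourhood of the toggled edge.  A brute-force
enumerator over all 3- and 4-node subsets serves as the independent oracle.
"""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Iterable, Mapping

GRAPHLET_NAMES = ("G0", "G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8")

# indices into the internal count vector
_G0, _G1, _G2, _G3, _G4, _G5, _G6, _G7, _G8 = range(9)


def _classify4_bits(uv: int, uw: int, uz: int, vw: int, vz: int, wz: int):
    """Class index of the induced graph on {u,v,w,z}, or None if disconnected."""
    m = uv + uw + uz + vw + vz + wz
    if m < 3:
        return None
    du = uv + uw + uz
    dv = uv + vw + vz
    dw = uw + vw + wz
    dz = uz + vz + wz
    if min(du, dv, dw, dz) == 0:  # triangle + isolated node
        return None
    mx = max(du, dv, dw, dz)
    if m == 3:
        return _G4 if mx == 3 else _G3
    if m == 4:
        return _G6 if mx == 3 else _G5
    if m == 5:
        return _G7
    return _G8


def _build_toggle_table():
    """For each pattern of the five non-toggled edges of a quadruple
    {u,v,w,z}, the (class-without-uv, class-with-uv) pair.

    Bit layout of the mask: uw | uz<<1 | vw<<2 | vz<<3 | wz<<4.
    """
    table = []
    for mask in range(32):
        uw = mask & 1
        uz = (mask >> 1) & 1
        vw = (mask >> 2) & 1
        vz = (mask >> 3) & 1
        wz = (mask >> 4) & 1
        before = _classify4_bits(0, uw, uz, vw, vz, wz)
        after = _classify4_bits(1, uw, uz, vw, vz, wz)
        table.append((before, after))
    return tuple(table)


_TOGGLE4 = _build_toggle_table()


class IncrementalGraphletCounter:
    """Maintains exact G0-G8 counts of an undirected simple graph under
    single-edge insertions and deletions.

    Nodes are created implicitly; isolated nodes do not affect any count.
    """

    __slots__ = ("_adj", "_counts")

    def __init__(self):
        self._adj: dict[Hashable, set] = {}
        self._counts = [0] * 9

    @property
    def counts(self) -> dict[str, int]:
        return dict(zip(GRAPHLET_NAMES, self._counts))

    def count(self, name: str) -> int:
        return self._counts[GRAPHLET_NAMES.index(name)]

    @property
    def n_edges(self) -> int:
        return self._counts[_G0]

    def has_edge(self, u, v) -> bool:
        return v in self._adj.get(u, ())

    def edges(self):
        seen = set()
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if (v, u) not in seen:
                    seen.add((u, v))
        return seen

    # -- incremental updates -------------------------------------------------

    def _apply_toggle(self, u, v, sign: int) -> None:
        """Add (sign=+1) the count delta of inserting edge (u, v), computed on
        the current adjacency in which (u, v) is absent."""
        adj = self._adj
        counts = self._counts
        nu = adj.get(u, set())
        nv = adj.get(v, set())
        s = (nu | nv) - {u, v}
        counts[_G0] += sign
        # 3-node classes: only w adjacent to u or v can matter
        for w in s:
            k = (w in nu) + (w in nv)
            if k == 1:
                counts[_G1] += sign
            else:  # k == 2: a 2-path closes into a triangle
                counts[_G1] -= sign
                counts[_G2] += sign
        # 4-node classes: pairs {w,z} with w in s and z in s or adjacent to w
        table = _TOGGLE4
        s_list = list(s)
        for i, w in enumerate(s_list):
            w_u = w in nu
            w_v = w in nv
            nw = adj.get(w, set())
            base = (1 if w_u else 0) | (4 if w_v else 0)
            for z in s_list[i + 1:]:
                mask = base
                if z in nu:
                    mask |= 2
                if z in nv:
                    mask |= 8
                if z in nw:
                    mask |= 16
                before, after = table[mask]
                if before is not None:
                    counts[before] -= sign
                if after is not None:
                    counts[after] += sign
            # z outside N(u)|N(v) but adjacent to w: pendant attachments
            mask = base | 16
            before, after = table[mask]
            for z in nw:
                if z not in s and z != u and z != v:
                    if before is not None:
                        counts[before] -= sign
                    if after is not None:
                        counts[after] += sign

    def add_edge(self, u, v) -> dict[str, int]:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if v in self._adj.get(u, ()):
            raise ValueError(f"edge ({u!r}, {v!r}) already present")
        self._apply_toggle(u, v, +1)
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)
        return self.counts

    def remove_edge(self, u, v) -> dict[str, int]:
        if v not in self._adj.get(u, ()):
            raise ValueError(f"edge ({u!r}, {v!r}) not present")
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._apply_toggle(u, v, -1)
        return self.counts


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def count_bruteforce(g) -> dict[str, int]:
    """Exact graphlet census by enumerating every 3- and 4-node subset.

    ``g`` is an undirected simple graph: a ``networkx.Graph`` or any object
    with ``nodes`` and an ``has_edge(u, v)`` method, or a mapping
    node -> iterable of neighbours.
    """
    if isinstance(g, Mapping):
        adj = {u: set(nbrs) for u, nbrs in g.items()}
        for u, nbrs in list(adj.items()):
            for v in nbrs:
                adj.setdefault(v, set()).add(u)
        nodes = list(adj)
        has = lambda a, b: b in adj[a]  # noqa: E731
    else:
        nodes = list(g.nodes)
        has = g.has_edge
    counts = dict.fromkeys(GRAPHLET_NAMES, 0)
    counts["G0"] = sum(1 for a, b in combinations(nodes, 2) if has(a, b))
    for a, b, c in combinations(nodes, 3):
        m = has(a, b) + has(a, c) + has(b, c)
        if m == 2:
            counts["G1"] += 1
        elif m == 3:
            counts["G2"] += 1
    for a, b, c, d in combinations(nodes, 4):
        cls = _classify4_bits(
            has(a, b), has(a, c), has(a, d), has(b, c), has(b, d), has(c, d)
        )
        if cls is not None:
            counts[GRAPHLET_NAMES[cls]] += 1
    return counts


def g4_relative_frequency(counts: Mapping[str, int]) -> float:
    """Share of 3-star (G4) graphlets among all connected 4-node graphlets.

    Hub-rich, modular topologies drive this toward 1; mesh-like topologies
    toward 0.  A graph with no connected 4-node subgraph returns 0, so tiny
    subnetworks report the maximal "too few hubs" signal.
    """
    denom = sum(counts[n] for n in ("G3", "G4", "G5", "G6", "G7", "G8"))
    if denom == 0:
        return 0.0
    return counts["G4"] / denom
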