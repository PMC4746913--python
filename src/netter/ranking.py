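"""Rankings of candidate regulatory links.

A gene regulatory network (GRN) inference method outputs a list of candidate
directed links (regulator -> target) sorted by decreasing confidence.  This
module holds the data model for such rankings: reading DREAM-style prediction
files, extracting the top-``x`` links that the re-ranker is allowed to touch,
the squared-displacement divergence cost that anchors a re-ranking to its
source prediction, and gold-standard edge lists for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

logger = logging.getLogger("netter")


class DirectedLink(NamedTuple):
    """An ordered regulator -> target pair.  ``(A, B) != (B, A)``."""

    regulator: str
    target: str


class GoldStandard:
    """A set of true directed regulatory links (no self-loops)."""

    def __init__(self, true_links: Iterable[DirectedLink]):
        links = set(true_links)
        for link in links:
            if link.regulator == link.target:
                raise ValueError(f"gold standard contains self-loop {link!r}")
        self.true_links: frozenset[DirectedLink] = frozenset(links)

    def __len__(self) -> int:
        return len(self.true_links)

    def __contains__(self, link: DirectedLink) -> bool:
        return link in self.true_links

    def __eq__(self, other) -> bool:
        return isinstance(other, GoldStandard) and self.true_links == other.true_links

    def __repr__(self) -> str:
        return f"GoldStandard({len(self.true_links)} links)"


@dataclass(frozen=True)
class Ranking:
    """An ordered sequence of distinct directed links, rank 1 = most confident.

    ``original_rank`` maps every link to its 1-based rank in the source
    prediction; re-ranking never adds or removes links, so the key set always
    equals the link set.
    """

    links: tuple[DirectedLink, ...]
    original_rank: dict[DirectedLink, int] = field(compare=False)

    def __post_init__(self):
        if len(set(self.links)) != len(self.links):
            raise ValueError("ranking contains duplicate links")
        for link in self.links:
            if link.regulator == link.target:
                raise ValueError(f"ranking contains self-loop {link!r}")
        if set(self.links) != set(self.original_rank):
            raise ValueError("original_rank keys must equal the link set")

    def __len__(self) -> int:
        return len(self.links)

    def rank_of(self, link: DirectedLink) -> int:
        """Current 1-based rank of ``link`` (O(n); use sparingly)."""
        return self.links.index(link) + 1

    @property
    def rank_map(self) -> dict[DirectedLink, int]:
        return {link: i + 1 for i, link in enumerate(self.links)}

    def with_order(self, links: Sequence[DirectedLink]) -> "Ranking":
        """A new ranking with the same original ranks but a new order."""
        return Ranking(tuple(links), dict(self.original_rank))


def identity_ranking(links: Sequence[DirectedLink]) -> Ranking:
    """A ranking whose current order is its original order."""
    return Ranking(tuple(links), {l: i + 1 for i, l in enumerate(links)})


def all_candidate_links(genes: Sequence[str]) -> list[DirectedLink]:
    """Every ordered gene pair excluding self-loops.

    A network of ``G`` genes yields ``G * (G - 1)`` candidate directed
    regulatory links (9,900 for 100 genes).
    """
    return [
        DirectedLink(a, b) for a in genes for b in genes if a != b
    ]


# ---------------------------------------------------------------------------
# I/O: DREAM-style 3-column TSV (regulator <TAB> target <TAB> score)
# ---------------------------------------------------------------------------

def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_prediction(
    path: str | Path, fmt: str = "dream_tsv"
) -> list[tuple[DirectedLink, float]]:
    """Read a scored prediction, sorted by strictly decreasing score.

    Ties are broken by file order; self-loops are dropped with a warning;
    duplicate ordered pairs keep their higher-scored occurrence.  An optional
    header line is detected by a non-numeric third field.
    """
    if fmt != "dream_tsv":
        raise ValueError(f"unknown prediction format {fmt!r}")
    path = Path(path)
    rows: list[tuple[DirectedLink, float, int]] = []  # link, score, file order
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].rstrip("\n").split("\t")
        if len(first) >= 3 and not _is_number(first[2]):
            start = 1  # header
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3 or not _is_number(parts[2]):
            raise ValueError(f"{path}:{lineno}: malformed prediction row {raw!r}")
        reg, tgt, score = parts[0].strip(), parts[1].strip(), float(parts[2])
        if not reg or not tgt:
            raise ValueError(f"{path}:{lineno}: empty gene identifier")
        if reg == tgt:
            logger.warning("%s:%d: dropping self-loop %s -> %s", path, lineno, reg, tgt)
            continue
        rows.append((DirectedLink(reg, tgt), score, lineno))
    if not rows:
        raise ValueError(f"{path}: no valid prediction rows")
    # duplicates keep the best score (earliest occurrence wins exact ties)
    best: dict[DirectedLink, tuple[float, int]] = {}
    for link, score, order in rows:
        if link not in best or score > best[link][0]:
            best[link] = (score, order)
    ordered = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
    return [(link, score) for link, (score, _) in ordered]


def read_gold(path: str | Path) -> GoldStandard:
    """Read a gold standard: 2-column edge list or 3-column with {0,1} labels."""
    path = Path(path)
    links: set[DirectedLink] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) == 2:
                reg, tgt, label = parts[0], parts[1], "1"
            elif len(parts) >= 3:
                reg, tgt, label = parts[0], parts[1], parts[2].strip()
                if label not in ("0", "1"):
                    raise ValueError(
                        f"{path}:{lineno}: gold label must be 0 or 1, got {label!r}"
                    )
            else:
                raise ValueError(f"{path}:{lineno}: malformed gold row {raw!r}")
            if label == "1":
                if reg.strip() == tgt.strip():
                    logger.warning("%s:%d: dropping gold self-loop", path, lineno)
                    continue
                links.add(DirectedLink(reg.strip(), tgt.strip()))
    return GoldStandard(links)


def extract_top_x(
    pred: Sequence[tuple[DirectedLink, float]], x: int
) -> Ranking:
    """Extract the top ``x`` most confident links as a fresh ranking.

    Only links with a non-zero score participate; links beyond position
    ``x`` keep their original ranks and are never touched by the optimizer.
    """
    if x < 1:
        raise ValueError(f"x must be >= 1, got {x}")
    nonzero = [link for link, score in pred if score != 0.0]
    top = nonzero[: min(x, len(nonzero))]
    return identity_ranking(top)


def divergence_cost(current: Ranking) -> int:
    """Sum of squared rank displacements versus the original prediction.

    This is the regularizer that keeps a re-ranking anchored to its source:
    zero iff the permutation is the identity.
    """
    return sum(
        (current.original_rank[link] - rank) ** 2
        for rank, link in enumerate(current.links, start=1)
    )


def write_ranking(r: Ranking, path: str | Path) -> None:
    """Write a ranking as TSV rows ``regulator  target  rank`` in rank order."""
    if len(r) == 0:
        raise ValueError("refusing to write an empty ranking")
    path = Path(path)
    with open(path, "w") as fh:
        for rank, link in enumerate(r.links, start=1):
            fh.write(f"{link.regulator}\t{link.target}\t{rank}\n")


def read_ranking(path: str | Path) -> Ranking:
    """Read a ranking written by :func:`write_ranking`.

    The third column holds the 1-based rank; inducing a score ``x - rank + 1``
    and re-reading through :func:`read_prediction` yields the same order.
    """
    rows = read_prediction(path)  # sorted by decreasing third column
    links = [link for link, _ in reversed(rows)]  # ascending rank
    return identity_ranking(links)


def write_prediction(
    pred: Sequence[tuple[DirectedLink, float]], path: str | Path
) -> None:
    """Write a scored prediction as DREAM-style 3-column TSV."""
    if not pred:
        raise ValueError("refusing to write an empty prediction")
    with open(Path(path), "w") as fh:
        for link, score in pred:
            fh.write(f"{link.regulator}\t{link.target}\t{score:.10g}\n")
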