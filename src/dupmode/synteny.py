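"""Collinear-block detection by chaining in gene-rank space.

Homolog pairs are plotted as points (query rank, subject rank) per
chromosome pair, and runs of points that are strictly monotone on both
axes — with consecutive rank gaps bounded by ``max_gap`` — are chained by
dynamic programming. Chains are extracted greedily (best first, points
removed, repeat) and chains shorter than ``min_anchors`` are discarded.
Anchor-count scoring, no distance penalties: this reproduces the behavior
of classic collinearity detectors (MCScanX-class) with an exactly testable
core.

Used intragenomically to call segmental duplicates, and between a query
species and outgroup species to identify ancestral loci for the transposed
duplicate test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .model import DupmodeError, GeneIndex, canonical_pair


@dataclass(frozen=True)
class AnchorPoint:
    """One homolog pair placed in rank space."""

    q_gene: str
    s_gene: str
    q_rank: int
    s_rank: int
    q_chrom: str
    s_chrom: str


@dataclass(frozen=True)
class SyntenyParams:
    """Chaining parameters.

    min_anchors: minimum anchors per reported block (default 5).
    max_gap: maximum rank gap between consecutive anchors, both axes
        (default 25).
    diag_band: intragenomic only — half-width of the self-diagonal band
        |q_rank - s_rank| excluded from match points on a chromosome vs
        itself, so tandem arrays cannot self-chain (default 1).
    """

    min_anchors: int = 5
    max_gap: int = 25
    diag_band: int = 1

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class CollinearBlock:
    """A chained run of anchor pairs between two chromosomes."""

    anchors: list[AnchorPoint]
    orientation: str  # "parallel" | "antiparallel"
    q_chrom: str
    s_chrom: str

    def __len__(self) -> int:
        return len(self.anchors)

    def pair_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(a.q_gene, a.s_gene) for a in self.anchors}


def match_points(pairs: Iterable[tuple[str, str]], q_index: GeneIndex,
                 s_index: GeneIndex,
                 diag_band: Optional[int] = 1) -> list[AnchorPoint]:
    """Place homolog pairs as rank-space points, grouped by chromosome pair.

    Intragenomic use (``q_index is s_index``): each unordered pair
    contributes two mirrored points, and points within ``diag_band`` of the
    self-diagonal on a chromosome vs itself are excluded (self points always
    are).
    """
    intra = q_index is s_index
    points: list[AnchorPoint] = []
    for a, b in pairs:
        if intra:
            ga, gb = q_index[a], q_index[b]
            for gq, gs in ((ga, gb), (gb, ga)):
                if gq.id == gs.id:
                    continue
                if (gq.chrom == gs.chrom and diag_band is not None
                        and abs(gq.rank - gs.rank) <= diag_band):
                    continue
                points.append(AnchorPoint(gq.id, gs.id, gq.rank, gs.rank,
                                          gq.chrom, gs.chrom))
        else:
            if a in q_index and b in s_index:
                gq, gs = q_index[a], s_index[b]
            elif b in q_index and a in s_index:
                gq, gs = q_index[b], s_index[a]
            else:
                raise DupmodeError(
                    f"pair ({a}, {b}) not resolvable in indices "
                    f"{q_index.species}/{s_index.species}")
            points.append(AnchorPoint(gq.id, gs.id, gq.rank, gs.rank,
                                      gq.chrom, gs.chrom))
    points.sort(key=lambda p: (p.q_chrom, p.s_chrom, p.q_rank, p.s_rank))
    return points


def _best_chain(points: list[AnchorPoint], params: SyntenyParams,
                orientation: str) -> list[AnchorPoint]:
    """Longest strictly monotone chain under the gap constraint.

    Ties broken by smaller starting (q_rank, s_rank), then by the
    lexicographically smallest (q_rank, s_rank) sequence. Returns [] for
    empty input.
    """
    if not points:
        return []
    sign = 1 if orientation == "parallel" else -1
    pts = sorted(points, key=lambda p: (p.q_rank, sign * p.s_rank))
    n = len(pts)
    q = np.fromiter((p.q_rank for p in pts), dtype=np.int64, count=n)
    s = np.fromiter((sign * p.s_rank for p in pts), dtype=np.int64, count=n)

    def _succ(i: int, j: int) -> bool:
        dq, ds = q[j] - q[i], s[j] - s[i]
        return 1 <= dq <= params.max_gap and 1 <= ds <= params.max_gap

    # F[i]: length of the longest valid chain starting at i (reverse DP)
    F = np.ones(n, dtype=np.int64)
    for i in range(n - 2, -1, -1):
        dq = q[i + 1:] - q[i]
        ds = s[i + 1:] - s[i]
        valid = ((dq >= 1) & (dq <= params.max_gap)
                 & (ds >= 1) & (ds <= params.max_gap))
        if valid.any():
            F[i] = 1 + F[i + 1:][valid].max()
    target = max(F)
    # lexicographically smallest maximum chain: greedy walk on F
    starts = [i for i in range(n) if F[i] == target]
    cur = min(starts, key=lambda i: (pts[i].q_rank, pts[i].s_rank))
    chain = [pts[cur]]
    need = target - 1
    while need > 0:
        nxt = min((j for j in range(cur + 1, n)
                   if _succ(cur, j) and F[j] == need),
                  key=lambda j: (pts[j].q_rank, pts[j].s_rank))
        chain.append(pts[nxt])
        cur, need = nxt, need - 1
    return chain


def chain_blocks(points: list[AnchorPoint],
                 params: SyntenyParams = SyntenyParams()) -> list[CollinearBlock]:
    """Greedy extraction of collinear blocks from one chromosome pair's points.

    Repeatedly takes the best chain over both orientations (longest; ties by
    smaller starting q_rank, then s_rank, parallel before antiparallel),
    removes its points, and stops when the best chain falls below
    ``min_anchors``.
    """
    if not points:
        return []
    chroms = {(p.q_chrom, p.s_chrom) for p in points}
    if len(chroms) > 1:
        raise DupmodeError("chain_blocks expects points from one chromosome "
                           "pair; use chain_all for mixed input")
    q_chrom, s_chrom = next(iter(chroms))
    remaining = list(points)
    blocks: list[CollinearBlock] = []
    while remaining:
        candidates = []
        for rank_o, orient in enumerate(("parallel", "antiparallel")):
            chain = _best_chain(remaining, params, orient)
            if chain:
                candidates.append((-len(chain), chain[0].q_rank,
                                   chain[0].s_rank, rank_o, chain, orient))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[:4])
        _, _, _, _, chain, orient = candidates[0]
        if len(chain) < params.min_anchors:
            break
        blocks.append(CollinearBlock(anchors=chain, orientation=orient,
                                     q_chrom=q_chrom, s_chrom=s_chrom))
        used = {id(p) for p in chain}
        remaining = [p for p in remaining if id(p) not in used]
    return blocks


def chain_all(points: list[AnchorPoint],
              params: SyntenyParams = SyntenyParams()) -> list[CollinearBlock]:
    """Chain blocks across all chromosome pairs present in ``points``."""
    groups: dict[tuple[str, str], list[AnchorPoint]] = {}
    for p in points:
        groups.setdefault((p.q_chrom, p.s_chrom), []).append(p)
    blocks: list[CollinearBlock] = []
    for key in sorted(groups):
        blocks.extend(chain_blocks(groups[key], params))
    return blocks


def intragenomic_anchor_pairs(paranome, index: GeneIndex,
                              params: SyntenyParams = SyntenyParams()
                              ) -> set[tuple[str, str]]:
    """Paralog pairs that are anchors in any intragenomic collinear block
    (the segmental-duplicate evidence set)."""
    points = match_points(paranome.pair_set(), index, index,
                          diag_band=params.diag_band)
    anchors: set[tuple[str, str]] = set()
    for block in chain_all(points, params):
        anchors |= block.pair_set()
    return anchors


def ancestral_loci(query_vs_outgroup_pairs: Iterable[tuple[str, str]],
                   q_index: GeneIndex, o_index: GeneIndex,
                   params: SyntenyParams = SyntenyParams()) -> set[str]:
    """Query genes that are anchors in >= 1 query-vs-outgroup collinear
    block, i.e. genes occupying ancestral loci."""
    points = match_points(list(query_vs_outgroup_pairs), q_index, o_index,
                          diag_band=None)
    loci: set[str] = set()
    for block in chain_all(points, params):
        for anchor in block.anchors:
            loci.add(anchor.q_gene)
    return loci


def write_blocks(blocks: list[CollinearBlock], path) -> None:
    """Plain-text block report: one anchor per line."""
    with open(path, "w") as fh:
        for i, block in enumerate(blocks, start=1):
            fh.write(f"# block {i}: {block.q_chrom} vs {block.s_chrom} "
                     f"({block.orientation}, {len(block)} anchors)\n")
            for a in block.anchors:
                fh.write(f"{i}\t{a.q_gene}\t{a.s_gene}\t{a.q_rank}\t"
                         f"{a.s_rank}\n")
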