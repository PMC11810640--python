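"""Stepwise classification of duplicate pairs by duplication mode.

Four nested schemes:

* ``binary``    — SD (anchor pair in an intragenomic collinear block) vs SSD.
* ``standard``  — SSD refined into TD (rank distance 1 on the same
  chromosome), PD (distance 2..proximal_max) and DD.
* ``extended``  — DD pairs with exactly one member at an ancestral locus
  (syntenic with an outgroup) in at least ``outgroup_fraction`` of the
  supplied outgroups become TRD.
* ``full``      — TRD pairs with exactly one intronless member become rTRD
  (retrotransposed); the rest become dTRD (DNA-transposon-derived).

Pairs are tested in the order above, so a pair that is both an anchor and
rank-adjacent is SD. Gene-level modes follow the hierarchy
SD > TD > PD > rTRD > dTRD > DD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (DupmodeError, DuplicatePair, GeneClassification,
                    GeneIndex, Paranome)

SCHEMES = ("binary", "standard", "extended", "full")

#: Pair-label sets emitted per scheme.
SCHEME_MODES: dict[str, tuple[str, ...]] = {
    "binary": ("SD", "SSD"),
    "standard": ("SD", "TD", "PD", "DD"),
    "extended": ("SD", "TD", "PD", "TRD", "DD"),
    "full": ("SD", "TD", "PD", "rTRD", "dTRD", "DD"),
}

#: Gene-level hierarchy per scheme (highest priority first).
SCHEME_HIERARCHY: dict[str, tuple[str, ...]] = {
    "binary": ("SD", "SSD"),
    "standard": ("SD", "TD", "PD", "DD"),
    "extended": ("SD", "TD", "PD", "TRD", "DD"),
    "full": ("SD", "TD", "PD", "rTRD", "dTRD", "DD"),
}


@dataclass(frozen=True)
class ClassifyParams:
    """Classification parameters.

    scheme: one of binary | standard | extended | full.
    proximal_max: largest rank distance still called proximal (default 10);
        tandem occupies distance 1, so proximal spans 2..proximal_max.
    outgroup_fraction: minimum fraction of outgroups for which a dispersed
        pair must look transposed to be called TRD (default 0.70).
    """

    scheme: str = "standard"
    proximal_max: int = 10
    outgroup_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; "
                             f"choose from {SCHEMES}")
        if self.proximal_max < 2:
            raise ValueError("proximal_max must be >= 2")
        if not (0.0 < self.outgroup_fraction <= 1.0):
            raise ValueError("outgroup_fraction must be in (0, 1]")


def classify_pairs(paranome: Paranome, index: GeneIndex,
                   anchor_pairs: set[tuple[str, str]],
                   params: ClassifyParams = ClassifyParams(),
                   outgroup_ancestral: Optional[Mapping[str, set[str]]] = None
                   ) -> list[DuplicatePair]:
    """Assign exactly one duplication-mode label to every paranome pair."""
    scheme = params.scheme
    if scheme in ("extended", "full") and not outgroup_ancestral:
        raise DupmodeError(
            f"scheme {scheme!r} requires ancestral-locus sets for at least "
            "one outgroup species")
    out: list[DuplicatePair] = []
    for g1, g2 in paranome:
        if g1 not in index or g2 not in index:
            missing = g1 if g1 not in index else g2
            raise DupmodeError(f"gene id {missing!r} missing from index")
        if (g1, g2) in anchor_pairs:
            out.append(DuplicatePair(g1, g2, "SD"))
            continue
        if scheme == "binary":
            out.append(DuplicatePair(g1, g2, "SSD"))
            continue
        dist = index.rank_distance(g1, g2)
        if dist == 1:
            out.append(DuplicatePair(g1, g2, "TD"))
            continue
        if dist is not None and 2 <= dist <= params.proximal_max:
            out.append(DuplicatePair(g1, g2, "PD"))
            continue
        mode = "DD"
        if scheme in ("extended", "full"):
            n_transposed = sum(
                1 for loci in outgroup_ancestral.values()
                if (g1 in loci) != (g2 in loci))
            if n_transposed / len(outgroup_ancestral) >= params.outgroup_fraction:
                if scheme == "extended":
                    mode = "TRD"
                else:
                    intronless = ((index[g1].exon_count == 1)
                                  + (index[g2].exon_count == 1))
                    mode = "rTRD" if intronless == 1 else "dTRD"
        out.append(DuplicatePair(g1, g2, mode))
    return out


def classify_genes(pairs: Sequence[DuplicatePair],
                   scheme: str = "standard") -> list[GeneClassification]:
    """Assign each duplicated gene the highest-priority mode among its
    pairs (genes with no pairs are omitted; see :func:`singletons`)."""
    hierarchy = SCHEME_HIERARCHY.get(scheme)
    if hierarchy is None:
        raise DupmodeError(f"unknown scheme {scheme!r}")
    priority = {mode: i for i, mode in enumerate(hierarchy)}
    best: dict[str, int] = {}
    for pair in pairs:
        if pair.mode not in priority:
            raise DupmodeError(
                f"pair mode {pair.mode!r} is not valid under scheme "
                f"{scheme!r} (expected one of {hierarchy})")
        for gene in (pair.gene1, pair.gene2):
            p = priority[pair.mode]
            if gene not in best or p < best[gene]:
                best[gene] = p
    return [GeneClassification(gene=g, mode=hierarchy[p])
            for g, p in sorted(best.items())]


def singletons(index: GeneIndex, pairs: Sequence[DuplicatePair]) -> list[str]:
    """Genes with no paralog pair at all."""
    dup = {g for p in pairs for g in (p.gene1, p.gene2)}
    return sorted(g.id for g in index if g.id not in dup)


def duplicate_frequencies(items: Iterable[Union[DuplicatePair,
                                                GeneClassification]],
                          by: str = "pair",
                          scheme: Optional[str] = None) -> pd.DataFrame:
    """Absolute and relative duplication-mode frequencies.

    Returns a DataFrame with columns ``mode``, ``n``, ``fraction``. With a
    ``scheme``, all of that scheme's modes are listed (zeros included) in
    hierarchy order; otherwise observed modes in hierarchy-ish order.
    Fractions sum to 1 (all zeros for empty input).
    """
    if by not in ("pair", "gene"):
        raise ValueError("by must be 'pair' or 'gene'")
    counts: dict[str, int] = {}
    for item in items:
        counts[item.mode] = counts.get(item.mode, 0) + 1
    if scheme is not None:
        modes = list(SCHEME_HIERARCHY[scheme])
    else:
        order = ("SD", "SSD", "TD", "PD", "TRD", "rTRD", "dTRD", "DD")
        modes = [m for m in order if m in counts]
    total = sum(counts.get(m, 0) for m in modes)
    rows = [{"mode": m, "n": counts.get(m, 0),
             "fraction": (counts.get(m, 0) / total) if total else 0.0}
            for m in modes]
    return pd.DataFrame(rows, columns=["mode", "n", "fraction"])
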