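"""Core domain types for duplicate-gene classification.

Coordinates follow the GFF3 convention (1-based, inclusive); gene ranks are
0-based positions among all annotated genes on a chromosome, ordered by start
coordinate. "Adjacent" and "separated by k genes" throughout the package are
expressed in this all-genes rank space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

#: Duplication-mode labels, in hierarchy order (highest priority first).
#: SD  - segmental duplication (anchor pair in an intragenomic collinear block)
#: SSD - small-scale duplication (binary scheme only: anything not SD)
#: TD  - tandem duplication (same chromosome, rank distance 1)
#: PD  - proximal duplication (same chromosome, a few genes apart)
#: TRD - transposed duplication (exactly one copy at an ancestral locus)
#: rTRD/dTRD - TRD attributed to retrotransposons / DNA transposons
#: DD  - dispersed duplication (residual; mechanism unknown)
MODES = ("SD", "SSD", "TD", "PD", "TRD", "rTRD", "dTRD", "DD")


class DupmodeError(Exception):
    """Base error for this package."""


@dataclass(frozen=True)
class Gene:
    """One annotated gene with its position in rank space."""

    id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    rank: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"gene {self.id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.exon_count < 1:
            raise ValueError(f"gene {self.id}: exon_count must be >= 1")
        if self.rank < 0:
            raise ValueError(f"gene {self.id}: rank must be >= 0")

    @property
    def intronless(self) -> bool:
        return self.exon_count == 1


class GeneIndex:
    """Ordered per-species gene catalog.

    Ranks on each chromosome form the permutation 0..n-1, consistent with
    start coordinates (ties broken by end, then id).
    """

    def __init__(self, species: str, genes: Mapping[str, Gene],
                 chrom_order: Mapping[str, list[str]]):
        self.species = species
        self.genes = dict(genes)
        self.chrom_order = {c: list(ids) for c, ids in chrom_order.items()}

    @classmethod
    def build(cls, species: str,
              records: Iterable[tuple[str, str, int, int, str, int]]) -> "GeneIndex":
        """Build from (id, chrom, start, end, strand, exon_count) records,
        assigning ranks per chromosome."""
        by_chrom: dict[str, list[tuple[str, str, int, int, str, int]]] = {}
        seen: set[str] = set()
        for rec in records:
            gid = rec[0]
            if gid in seen:
                raise DupmodeError(f"duplicate gene ID: {gid}")
            seen.add(gid)
            by_chrom.setdefault(rec[1], []).append(rec)
        genes: dict[str, Gene] = {}
        chrom_order: dict[str, list[str]] = {}
        for chrom in sorted(by_chrom):
            recs = sorted(by_chrom[chrom], key=lambda r: (r[2], r[3], r[0]))
            order = []
            for rank, (gid, c, start, end, strand, nexon) in enumerate(recs):
                genes[gid] = Gene(id=gid, species=species, chrom=c, start=start,
                                  end=end, strand=strand, exon_count=nexon,
                                  rank=rank)
                order.append(gid)
            chrom_order[chrom] = order
        return cls(species, genes, chrom_order)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise DupmodeError(
                f"unknown gene id {gene_id!r} in species {self.species!r}"
            ) from None

    def __iter__(self) -> Iterator[Gene]:
        for chrom in sorted(self.chrom_order):
            for gid in self.chrom_order[chrom]:
                yield self.genes[gid]

    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_order)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [self.genes[g] for g in self.chrom_order.get(chrom, [])]

    def rank(self, gene_id: str) -> int:
        return self[gene_id].rank

    def rank_distance(self, a: str, b: str) -> Optional[int]:
        """Rank distance between two genes, or None if on different chromosomes."""
        ga, gb = self[a], self[b]
        if ga.chrom != gb.chrom:
            return None
        return abs(ga.rank - gb.rank)


@dataclass(frozen=True)
class HomologyHit:
    """One row of a tabular all-vs-all similarity search."""

    query: str
    subject: str
    pct_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query}/{self.subject}")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(
                f"pct_identity out of [0,100] for {self.query}/{self.subject}")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairEvidence:
    """Best similarity-search evidence for one paralog pair."""

    evalue: float
    bitscore: float


@dataclass
class Paranome:
    """All paralogous gene pairs within one genome.

    Pairs are stored canonically (smaller id first) with the best (minimum)
    E-value and best (maximum) bitscore observed across redundant hits.
    """

    species: str
    pairs: dict[tuple[str, str], PairEvidence] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def add_hit(self, query: str, subject: str, evalue: float,
                bitscore: float) -> None:
        if query == subject:
            return
        key = canonical_pair(query, subject)
        prev = self.pairs.get(key)
        if prev is None:
            self.pairs[key] = PairEvidence(evalue, bitscore)
        else:
            self.pairs[key] = PairEvidence(min(prev.evalue, evalue),
                                           max(prev.bitscore, bitscore))


@dataclass
class DuplicatePair:
    """Unordered paralog pair carrying a duplication-mode label and,
    optionally, substitution rates."""

    gene1: str
    gene2: str
    mode: str
    ka: Optional[float] = None
    ks: Optional[float] = None
    ka_ks: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown duplication mode {self.mode!r}")
        if self.gene1 > self.gene2:
            self.gene1, self.gene2 = self.gene2, self.gene1

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


@dataclass(frozen=True)
class GeneClassification:
    """Unique duplication mode assigned to one gene."""

    gene: str
    mode: str
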