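"""Ka/Ks estimation per duplicate pair: protein-guided codon alignment and
Nei–Gojobori (1986) counting with Jukes–Cantor correction.

The NG86 model counts, for every codon, how many of its three sites are
synonymous (a fraction, since a site can be partly synonymous), and, for
every aligned codon pair differing at k positions, averages synonymous and
nonsynonymous change counts over all k! orderings of single-base steps.
Pathways through stop codons are excluded (and the average renormalized);
changes to stop codons are likewise excluded from site counting with the
denominator renormalized. Proportions of synonymous (Sd/S) and
nonsynonymous (Nd/N) differences are corrected for multiple hits with the
one-parameter Jukes–Cantor formula.

Only the NG86 model ships; the API takes a model name so that other codon
models can be added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from multiprocessing import Pool
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .model import DupmodeError, DuplicatePair

SUPPORTED_MODELS = ("NG86",)

_STANDARD_TABLE = unambiguous_dna_by_id[1]
NUCLEOTIDES = ("A", "C", "G", "T")


class SaturationError(DupmodeError):
    """Observed difference proportion >= 3/4: distance undefined."""


def _code_maps(table=None) -> tuple[dict[str, str], frozenset]:
    table = table or _STANDARD_TABLE
    return dict(table.forward_table), frozenset(table.stop_codons)


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free, stop-free, unambiguous aligned codon columns."""

    codons1: tuple[str, ...]
    codons2: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise ValueError("aligned codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons1)


@dataclass
class KaKsResult:
    """NG86 rate estimates for one aligned pair.

    S, N: synonymous / nonsynonymous site counts (S + N = 3 * n_codons);
    Sd, Nd: synonymous / nonsynonymous differences; ka, ks: Jukes–Cantor
    corrected rates, None when saturated; ka_ks defined iff ks > 0.
    """

    ka: Optional[float]
    ks: Optional[float]
    ka_ks: Optional[float]
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    ka_saturated: bool = False
    ks_saturated: bool = False


def ng86_sites(codon: str, table=None) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Per position, s is the fraction of the single-base changes that are
    synonymous among those not creating a stop codon; n = 3 - s summed.
    """
    codon = codon.upper()
    if table is None:
        return _ng86_sites_cached(codon)
    return _ng86_sites_impl(codon, table)


@lru_cache(maxsize=64)
def _ng86_sites_cached(codon: str) -> tuple[float, float]:
    return _ng86_sites_impl(codon, None)


def _ng86_sites_impl(codon: str, table) -> tuple[float, float]:
    forward, stops = _code_maps(table)
    if codon in stops:
        raise DupmodeError(f"stop codon {codon} has no site counts")
    if codon not in forward:
        raise DupmodeError(f"not a sense codon: {codon!r}")
    aa = forward[codon]
    s_total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1:]
            if neighbor in stops:
                continue
            valid += 1
            if forward[neighbor] == aa:
                syn += 1
        if valid:
            s_total += syn / valid
    return s_total, 3.0 - s_total


@lru_cache(maxsize=4096)
def _ng86_differences_cached(c1: str, c2: str) -> tuple[float, float]:
    forward, stops = _code_maps()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0

    def _walk(count_blocked: bool):
        results = []
        for perm in permutations(diff_pos):
            cur, sd, nd, blocked = c1, 0, 0, False
            for pos in perm:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in stops or cur in stops:
                    if not count_blocked:
                        blocked = True
                        break
                    nd += 1  # steps into/out of a stop count as nonsynonymous
                elif forward[cur] == forward[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if not blocked:
                results.append((sd, nd))
        return results

    paths = _walk(count_blocked=False)
    if not paths:
        # every ordering passes through a stop codon: fall back to counting
        # all orderings, stop steps as nonsynonymous
        paths = _walk(count_blocked=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_differences(c1: str, c2: str, table=None) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons; sd + nd equals the number of differing positions."""
    forward, stops = _code_maps(table)
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if c in stops:
            raise DupmodeError(f"stop codon {c} not allowed")
        if c not in forward:
            raise DupmodeError(f"not a sense codon: {c!r}")
    if table is None or table is _STANDARD_TABLE:
        return _ng86_differences_cached(c1, c2)
    raise NotImplementedError("pathway counting implemented for the "
                              "standard genetic code only")


def jukes_cantor(p: float) -> float:
    """One-parameter multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError(f"negative difference proportion: {p}")
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion {p:.4f} >= 3/4: distance saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # normalize -0.0


def _default_aligner(open_gap: float = -10.0,
                     extend_gap: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = "global"
    return aligner


def _strip_stop(cds: str, stops: frozenset) -> str:
    if len(cds) >= 3 and cds[-3:] in stops:
        return cds[:-3]
    return cds


def align_codon_pair(cds1: str, cds2: str, prot1: Optional[str] = None,
                     prot2: Optional[str] = None,
                     aligner: Optional[PairwiseAligner] = None,
                     min_codons: int = 10) -> CodonAlignment:
    """Globally align the translations, back-translate to codons, and drop
    columns with a gap, an ambiguous base, or a stop codon in either
    sequence."""
    _, stops = _code_maps()
    cds1 = _strip_stop(cds1.upper().replace("U", "T"), stops)
    cds2 = _strip_stop(cds2.upper().replace("U", "T"), stops)
    for i, cds in enumerate((cds1, cds2), start=1):
        if len(cds) % 3 != 0:
            raise DupmodeError(
                f"CDS {i} length {len(cds)} not divisible by 3")
    t1 = str(Seq(cds1).translate())
    t2 = str(Seq(cds2).translate())
    for prot, trans, i in ((prot1, t1, 1), (prot2, t2, 2)):
        if prot is not None and prot.upper().rstrip("*") != trans.rstrip("*"):
            raise DupmodeError(
                f"supplied protein {i} inconsistent with CDS translation")
    aligner = aligner or _default_aligner()
    alignment = aligner.align(t1, t2)[0]
    a1, a2 = str(alignment[0]), str(alignment[1])
    codons1, codons2 = [], []
    i1 = i2 = 0
    for r1, r2 in zip(a1, a2):
        c1 = cds1[3 * i1:3 * i1 + 3] if r1 != "-" else None
        c2 = cds2[3 * i2:3 * i2 + 3] if r2 != "-" else None
        if r1 != "-":
            i1 += 1
        if r2 != "-":
            i2 += 1
        if c1 is None or c2 is None:
            continue
        if any(b not in NUCLEOTIDES for b in c1 + c2):
            continue
        if c1 in stops or c2 in stops:
            continue
        codons1.append(c1)
        codons2.append(c2)
    if len(codons1) < min_codons:
        raise DupmodeError(
            f"insufficient alignable codons: {len(codons1)} < {min_codons}")
    return CodonAlignment(tuple(codons1), tuple(codons2))


def pair_kaks(alignment: CodonAlignment, model: str = "NG86") -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for one codon alignment.

    Site counts are averaged over the two sequences; differences are
    pathway-averaged per column. Saturated rates are flagged and reported
    as None; the pair is retained.
    """
    if model not in SUPPORTED_MODELS:
        raise DupmodeError(
            f"unknown model {model!r}; supported models: "
            f"{', '.join(SUPPORTED_MODELS)}")
    s1 = sum(ng86_sites(c)[0] for c in alignment.codons1)
    s2 = sum(ng86_sites(c)[0] for c in alignment.codons2)
    S = (s1 + s2) / 2.0
    N = 3.0 * alignment.n_codons - S
    Sd = Nd = 0.0
    for c1, c2 in zip(alignment.codons1, alignment.codons2):
        sd, nd = ng86_differences(c1, c2)
        Sd += sd
        Nd += nd
    ks = ka = None
    ks_sat = ka_sat = False
    try:
        ks = jukes_cantor(Sd / S) if S > 0 else None
    except SaturationError:
        ks_sat = True
    try:
        ka = jukes_cantor(Nd / N) if N > 0 else None
    except SaturationError:
        ka_sat = True
    ka_ks = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(ka=ka, ks=ks, ka_ks=ka_ks, S=S, N=N, Sd=Sd, Nd=Nd,
                      n_codons=alignment.n_codons, ka_saturated=ka_sat,
                      ks_saturated=ks_sat)


def _kaks_one(args: tuple[str, str, str, str, str]) -> tuple:
    g1, g2, mode, cds1, cds2 = args
    aln = align_codon_pair(cds1, cds2)
    r = pair_kaks(aln)
    return (g1, g2, mode, r.ka, r.ks, r.ka_ks, r.S, r.N, r.Sd, r.Nd)


KAKS_COLUMNS = ["gene1", "gene2", "mode", "Ka", "Ks", "Ka_Ks",
                "S", "N", "Sd", "Nd"]


def pairs2kaks(pairs: Sequence[DuplicatePair], cds: Mapping[str, str],
               model: str = "NG86", threads: int = 1) -> pd.DataFrame:
    """Ka/Ks for every pair with CDS available, as a tidy table.

    Pairs missing a CDS are skipped with a warning count (attribute
    ``df.attrs["n_skipped"]``). Output is bitwise-identical for any thread
    count: per-pair computation is pure and results are merged in input
    order.
    """
    if model not in SUPPORTED_MODELS:
        raise DupmodeError(
            f"unknown model {model!r}; supported models: "
            f"{', '.join(SUPPORTED_MODELS)}")
    jobs, skipped = [], 0
    for p in pairs:
        if p.gene1 not in cds or p.gene2 not in cds:
            skipped += 1
            continue
        jobs.append((p.gene1, p.gene2, p.mode, cds[p.gene1], cds[p.gene2]))
    if threads > 1 and len(jobs) > 1:
        with Pool(processes=threads) as pool:
            rows = pool.map(_kaks_one, jobs)
    else:
        rows = [_kaks_one(j) for j in jobs]
    df = pd.DataFrame(rows, columns=KAKS_COLUMNS)
    df.attrs["n_skipped"] = skipped
    return df
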