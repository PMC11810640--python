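"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration, sharing no code with
the package: codon translation goes through Bio.Seq rather than the
package's code-table maps, and chain search enumerates every monotone
chain instead of running dynamic programming.
"""

from __future__ import annotations

from itertools import permutations, product

from Bio.Seq import Seq

BASES = "ACGT"


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


SENSE = tuple(sorted("".join(c) for c in product(BASES, repeat=3)
                     if translate("".join(c)) != "*"))


def sites_bruteforce(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts by neighbor
    enumeration (stop-codon changes excluded, denominator renormalized)."""
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        outcomes = []
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            alt_aa = translate(alt)
            if alt_aa != "*":
                outcomes.append(alt_aa == aa)
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def diffs_bruteforce(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences by explicit
    enumeration of every ordering of single-base steps."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    surviving, all_paths = [], []
    for perm in permutations(positions):
        steps, cur, hits_stop = [], c1, False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if translate(nxt) == "*":
                hits_stop = True
            cur = nxt
        counted = []
        for a, b in steps:
            aa_a, aa_b = translate(a), translate(b)
            if "*" in (aa_a, aa_b):
                counted.append("n")  # stop step: nonsynonymous fallback
            elif aa_a == aa_b:
                counted.append("s")
            else:
                counted.append("n")
        pair = (counted.count("s"), counted.count("n"))
        all_paths.append(pair)
        if not hits_stop:
            surviving.append(pair)
    paths = surviving if surviving else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def best_chain_bruteforce(points: list[tuple[int, int]], max_gap: int,
                          orientation: str) -> list[tuple[int, int]]:
    """Best monotone chain by enumerating every chain.

    Tie-break: longest, then smallest start (q, s), then lexicographically
    smallest (q, s) sequence.
    """
    sign = 1 if orientation == "parallel" else -1
    best: list | None = None

    def consider(chain: list[tuple[int, int]]) -> None:
        nonlocal best
        key = (-len(chain), chain[0][0], chain[0][1], tuple(chain))
        if best is None or key < best[0]:
            best = [key, list(chain)]

    def extend(chain: list[tuple[int, int]]) -> None:
        consider(chain)
        last = chain[-1]
        for p in points:
            if p in chain:
                continue
            dq = p[0] - last[0]
            ds = sign * (p[1] - last[1])
            if 1 <= dq <= max_gap and 1 <= ds <= max_gap:
                extend(chain + [p])

    for p in points:
        extend([p])
    return best[1] if best else []


def chain_cover_bruteforce(points: list[tuple[int, int]], min_anchors: int,
                           max_gap: int) -> int:
    """Total anchors covered by greedy extraction of exhaustive best chains
    (parallel preferred on full ties, matching the chaining contract)."""
    remaining = list(points)
    total = 0
    while remaining:
        candidates = []
        for rank_o, orient in enumerate(("parallel", "antiparallel")):
            chain = best_chain_bruteforce(remaining, max_gap, orient)
            if chain:
                candidates.append((-len(chain), chain[0][0], chain[0][1],
                                   rank_o, chain))
        if not candidates:
            break
        chain = min(candidates)[4]
        if len(chain) < min_anchors:
            break
        total += len(chain)
        for p in chain:
            remaining.remove(p)
    return total
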