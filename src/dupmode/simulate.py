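"""Synthetic genomes with planted duplication events of every mode.

The generator builds an ancestral gene order, plants duplication events
(segmental blocks, tandem/proximal insertions, transposed copies with or
without introns, dispersed copies), and emits everything the pipeline
consumes — annotation, similarity-search tables for the species itself and
against outgroup species, and diverged coding sequences — together with
ground-truth labels. Events are placed in disjoint windows so that, at the
default separations, classification recovers every planted label.

Outgroup species mirror the ancestral gene order, so ancestral query genes
are anchors in query-vs-outgroup collinear blocks while planted copies are
not. The last query chromosome carries no outgroup orthologs: dispersed
events are planted there so neither member is an ancestral locus.

What this emulates: rank-space geometry of duplication modes, homology
evidence with controlled noise, and codon-level divergence with exact
synonymous/nonsynonymous change counts. What it does not: indel processes,
rate heterogeneity, gene loss, or WGD-scale genome doubling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import DupmodeError, GeneIndex, HomologyHit, canonical_pair
from .rates import _code_maps

_FORWARD, _STOPS = _code_maps()
SENSE_CODONS = tuple(sorted(_FORWARD))

MODES_PLANTABLE = ("SD", "TD", "PD", "rTRD", "dTRD", "DD")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted duplication event with its ground-truth pairs."""

    mode: str
    source_genes: tuple[str, ...]
    copy_genes: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def pairs(self) -> list[tuple[str, str]]:
        return [canonical_pair(s, c)
                for s, c in zip(self.source_genes, self.copy_genes)]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic genome.

    Defaults: 4 chromosomes x 300 genes, 3 events per duplication mode,
    3 outgroup species, segmental blocks of 8 genes, proximal copies 5
    ranks downstream, dispersed copies 15 ranks downstream (past the
    proximal limit), 100-codon CDS diverged by 8 synonymous + 2
    nonsynonymous changes per pair. ``window_margin`` exceeds the default
    chaining ``max_gap`` (25) so that points from different planted events
    can never join one collinear chain.
    """

    species: str = "query"
    n_chroms: int = 4
    genes_per_chrom: int = 300
    mode_counts: dict = field(default_factory=lambda: {
        "SD": 3, "TD": 3, "PD": 3, "rTRD": 3, "dTRD": 3, "DD": 3})
    sd_block_len: int = 8
    proximal_offset: int = 5
    dispersed_offset: int = 15
    n_outgroups: int = 3
    n_codons: int = 100
    divergence: tuple[int, int] = (8, 2)   # (synonymous, nonsynonymous)
    rng_seed: int = 0
    window_margin: int = 30

    def __post_init__(self) -> None:
        unknown = set(self.mode_counts) - set(MODES_PLANTABLE)
        if unknown:
            raise ValueError(f"unknown modes in mode_counts: {sorted(unknown)}")
        if self.sd_block_len < 5:
            raise ValueError("sd_block_len must be >= 5 (synteny default "
                             "min_anchors)")
        if not (2 <= self.proximal_offset <= 10):
            raise ValueError("proximal_offset must lie in [2, 10]")
        if self.dispersed_offset <= 10:
            raise ValueError("dispersed_offset must exceed the default "
                             "proximal limit (10)")
        non_dd = sum(v for m, v in self.mode_counts.items() if m != "DD")
        if non_dd and self.n_chroms < 3:
            raise ValueError("need >= 3 chromosomes: two syntenic ones plus "
                             "the outgroup-free chromosome")

    @property
    def stripped_chrom(self) -> str:
        """Chromosome without outgroup orthologs (hosts dispersed events)."""
        return f"chr{self.n_chroms}"


@dataclass
class SynthDataset:
    """Everything the pipeline consumes, plus ground truth."""

    config: SynthConfig
    query: GeneIndex
    events: list[PlantedEvent]
    outgroups: dict[str, GeneIndex]
    ortholog_maps: dict[str, dict[str, str]]
    intraspecies_rows: list[list]
    outgroup_rows: dict[str, list[list]]
    cds: dict[str, str]
    outgroup_cds: dict[str, dict[str, str]]

    def truth(self) -> dict[tuple[str, str], str]:
        """Planted mode per ground-truth pair."""
        return {p: e.mode for e in self.events for p in e.pairs()}

    def intraspecies_hits(self) -> list[HomologyHit]:
        return hits_from_rows(self.intraspecies_rows)

    def outgroup_hits(self) -> dict[str, list[HomologyHit]]:
        return {name: hits_from_rows(rows)
                for name, rows in self.outgroup_rows.items()}

    def proteins(self) -> dict[str, str]:
        from Bio.Seq import Seq
        return {g: str(Seq(s).translate()).rstrip("*")
                for g, s in self.cds.items()}


class _WindowAllocator:
    """Disjoint-window bookkeeping so planted events never interact."""

    def __init__(self, chroms: Sequence[str], capacity: int, margin: int):
        self.cursors = {c: 3 for c in chroms}
        self.capacity = capacity
        self.margin = margin

    def allocate(self, width: int, exclude: Optional[str] = None) -> tuple[str, int]:
        candidates = [c for c in self.cursors if c != exclude]
        if not candidates:
            raise DupmodeError("no chromosome available for event placement")
        chrom = min(candidates, key=lambda c: (self.cursors[c], c))
        pos = self.cursors[chrom]
        end = pos + width + self.margin
        if end > self.capacity - 3:
            raise DupmodeError(
                "infeasible config: planted events do not fit on "
                f"{len(self.cursors)} chromosome(s) of {self.capacity} genes")
        self.cursors[chrom] = end
        return chrom, pos


def generate_genome(config: SynthConfig = SynthConfig()
                    ) -> tuple[GeneIndex, list[PlantedEvent]]:
    """Build the query genome with planted events (deterministic per seed)."""
    rng = np.random.default_rng(config.rng_seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    stripped = config.stripped_chrom
    synt_chroms = [c for c in chroms if c != stripped] or chroms

    ancestral = {c: [f"{config.species}_{ci + 1:02d}g{i + 1:03d}"
                     for i in range(config.genes_per_chrom)]
                 for ci, c in enumerate(chroms)}
    exon_counts = {g: int(rng.integers(2, 9))
                   for c in chroms for g in ancestral[c]}

    alloc = _WindowAllocator(synt_chroms, config.genes_per_chrom,
                             config.window_margin)
    alloc_dd = _WindowAllocator([stripped], config.genes_per_chrom,
                                config.window_margin)
    # insertions[(chrom, ancestral position)] -> copies appended after it
    insertions: dict[tuple[str, int], list[str]] = {}
    events: list[PlantedEvent] = []
    serial = 0

    def _copy_id(src: str) -> str:
        nonlocal serial
        serial += 1
        return f"{src}_cp{serial}"

    def _insert(chrom: str, pos: int, gid: str, nexon: int) -> None:
        insertions.setdefault((chrom, pos), []).append(gid)
        exon_counts[gid] = nexon

    for mode in MODES_PLANTABLE:
        for _ in range(config.mode_counts.get(mode, 0)):
            if mode == "SD":
                src_chrom, src_pos = alloc.allocate(config.sd_block_len)
                dst_chrom, dst_pos = alloc.allocate(1, exclude=src_chrom)
                sources = tuple(ancestral[src_chrom][src_pos + k]
                                for k in range(config.sd_block_len))
                copies = tuple(_copy_id(s) for s in sources)
                for k, cp in enumerate(copies):
                    # all appended after the same host, in block order
                    _insert(dst_chrom, dst_pos, cp,
                            exon_counts[sources[k]])
                events.append(PlantedEvent("SD", sources, copies,
                                           {"src": (src_chrom, src_pos),
                                            "dst": (dst_chrom, dst_pos)}))
            elif mode in ("TD", "PD"):
                offset = 1 if mode == "TD" else config.proximal_offset
                chrom, pos = alloc.allocate(offset + 1)
                src = ancestral[chrom][pos]
                cp = _copy_id(src)
                _insert(chrom, pos + offset - 1, cp, exon_counts[src])
                events.append(PlantedEvent(mode, (src,), (cp,),
                                           {"chrom": chrom, "offset": offset}))
            elif mode in ("rTRD", "dTRD"):
                src_chrom, src_pos = alloc.allocate(1)
                dst_chrom, dst_pos = alloc.allocate(1, exclude=src_chrom)
                src = ancestral[src_chrom][src_pos]
                cp = _copy_id(src)
                nexon = 1 if mode == "rTRD" else exon_counts[src]
                _insert(dst_chrom, dst_pos, cp, nexon)
                events.append(PlantedEvent(mode, (src,), (cp,),
                                           {"src": (src_chrom, src_pos),
                                            "dst": (dst_chrom, dst_pos)}))
            else:  # DD: both members on the outgroup-free chromosome
                chrom, pos = alloc_dd.allocate(config.dispersed_offset + 1)
                src = ancestral[chrom][pos]
                cp = _copy_id(src)
                _insert(chrom, pos + config.dispersed_offset - 1, cp,
                        exon_counts[src])
                events.append(PlantedEvent("DD", (src,), (cp,),
                                           {"chrom": chrom,
                                            "offset": config.dispersed_offset}))

    records = []
    for c in chroms:
        order: list[str] = []
        for pos, gid in enumerate(ancestral[c]):
            order.append(gid)
            order.extend(insertions.get((c, pos), []))
        for idx, gid in enumerate(order):
            start = 1 + idx * 5000
            nexon = exon_counts[gid]
            end = start + nexon * 200 + 99
            strand = "+" if rng.integers(2) else "-"
            records.append((gid, c, start, end, strand, nexon))
    index = GeneIndex.build(config.species, records)
    return index, events


def generate_outgroups(config: SynthConfig
                       ) -> tuple[dict[str, GeneIndex],
                                  dict[str, dict[str, str]]]:
    """Outgroup genomes mirroring the ancestral order of the syntenic
    chromosomes, plus query-gene -> ortholog maps."""
    stripped = config.stripped_chrom
    outgroups: dict[str, GeneIndex] = {}
    ortholog_maps: dict[str, dict[str, str]] = {}
    for o in range(config.n_outgroups):
        name = f"out{o + 1}"
        records, omap = [], {}
        for ci in range(config.n_chroms):
            chrom = f"chr{ci + 1}"
            if chrom == stripped:
                continue
            for i in range(config.genes_per_chrom):
                qid = f"{config.species}_{ci + 1:02d}g{i + 1:03d}"
                oid = f"{name}_{ci + 1:02d}g{i + 1:03d}"
                start = 1 + i * 5000
                records.append((oid, f"{name}_{chrom}", start, start + 499,
                                "+", 2))
                omap[qid] = oid
        outgroups[name] = GeneIndex.build(name, records)
        ortholog_maps[name] = omap
    return outgroups, ortholog_maps


def _hit_row(query: str, subject: str, pident: float = 90.0,
             evalue: float = 1e-50, bitscore: float = 500.0) -> list:
    aln_len = 300
    mismatch = int(round(aln_len * (100.0 - pident) / 100.0))
    return [query, subject, pident, aln_len, mismatch, 0, 1, aln_len, 1,
            aln_len, evalue, bitscore]


def hits_from_rows(rows: Sequence[Sequence]) -> list[HomologyHit]:
    return [HomologyHit(query=str(r[0]), subject=str(r[1]),
                        pct_identity=float(r[2]), evalue=float(r[10]),
                        bitscore=float(r[11])) for r in rows]


def generate_homology(query_index: GeneIndex, events: Sequence[PlantedEvent],
                      ortholog_maps: dict[str, dict[str, str]],
                      noise: int = 0, rng_seed: int = 0
                      ) -> tuple[list[list], dict[str, list[list]]]:
    """Similarity-search tables: one hit per planted pair, one per
    query-vs-outgroup ortholog pair (ancestral loci only); optional noise
    hits above the default E-value threshold to exercise filtering."""
    rng = np.random.default_rng(rng_seed)
    intraspecies = [_hit_row(a, b) for e in events for a, b in e.pairs()]
    if noise:
        ids = sorted(query_index.genes)
        for _ in range(noise):
            a, b = rng.choice(len(ids), size=2, replace=False)
            intraspecies.append(_hit_row(ids[a], ids[b], pident=35.0,
                                         evalue=1e-5, bitscore=40.0))
    outgroup_rows = {
        name: [_hit_row(q, o) for q, o in sorted(omap.items())]
        for name, omap in ortholog_maps.items()}
    return intraspecies, outgroup_rows


# ---------------------------------------------------------------------------
# codon-level simulation


def _neighbors(codon: str, synonymous: bool) -> list[str]:
    aa = _FORWARD[codon]
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in _STOPS:
                continue
            if (_FORWARD[alt] == aa) == synonymous:
                out.append(alt)
    return sorted(out)


def _random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _apply_changes(codons: Sequence[str], n_syn: int, n_nonsyn: int,
                   rng: np.random.Generator) -> list[str]:
    """Mutate exactly n_syn synonymous and n_nonsyn nonsynonymous single
    bases at distinct codons, never creating stops."""
    if n_syn + n_nonsyn > len(codons):
        raise DupmodeError(
            f"requested {n_syn + n_nonsyn} changes over {len(codons)} codons")
    order = list(rng.permutation(len(codons)))
    result = list(codons)
    used: set[int] = set()
    for synonymous, count in ((True, n_syn), (False, n_nonsyn)):
        done = 0
        for i in order:
            if done == count:
                break
            if i in used:
                continue
            options = _neighbors(codons[i], synonymous)
            if not options:
                continue
            result[i] = options[int(rng.integers(len(options)))]
            used.add(i)
            done += 1
        if done < count:
            kind = "synonymous" if synonymous else "nonsynonymous"
            raise DupmodeError(f"could not place {count} {kind} changes")
    return result


def simulate_codon_pair(n_codons: int, n_syn_changes: int,
                        n_nonsyn_changes: int,
                        rng_seed: int = 0) -> tuple[str, str]:
    """A random sense-codon sequence and a copy carrying exactly the
    requested synonymous and nonsynonymous single-base changes."""
    rng = np.random.default_rng(rng_seed)
    codons = _random_sense_codons(n_codons, rng)
    mutated = _apply_changes(codons, n_syn_changes, n_nonsyn_changes, rng)
    return "".join(codons), "".join(mutated)


def generate_cds(index: GeneIndex, events: Sequence[PlantedEvent],
                 config: SynthConfig,
                 rng: Optional[np.random.Generator] = None) -> dict[str, str]:
    """CDS per query gene; planted copies diverge from their source by the
    configured (synonymous, nonsynonymous) change counts."""
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    n_syn, n_nonsyn = config.divergence
    copy_source = {c: s for e in events
                   for s, c in zip(e.source_genes, e.copy_genes)}
    cds: dict[str, str] = {}
    for gene in index:
        if gene.id in copy_source:
            continue
        cds[gene.id] = "".join(_random_sense_codons(config.n_codons, rng))
    for cp, src in sorted(copy_source.items()):
        source_codons = [cds[src][i:i + 3]
                         for i in range(0, len(cds[src]), 3)]
        cds[cp] = "".join(_apply_changes(source_codons, n_syn, n_nonsyn, rng))
    return cds


def generate_dataset(config: SynthConfig = SynthConfig(),
                     noise: int = 0) -> SynthDataset:
    """Full fixture bundle: genome, outgroups, homology tables and CDS."""
    query, events = generate_genome(config)
    outgroups, ortholog_maps = generate_outgroups(config)
    intraspecies, outgroup_rows = generate_homology(
        query, events, ortholog_maps, noise=noise,
        rng_seed=config.rng_seed + 2)
    cds = generate_cds(query, events, config)
    rng = np.random.default_rng(config.rng_seed + 3)
    outgroup_cds = {}
    for name, omap in ortholog_maps.items():
        per = {}
        for qid, oid in sorted(omap.items()):
            codons = [cds[qid][i:i + 3] for i in range(0, len(cds[qid]), 3)]
            per[oid] = "".join(_apply_changes(codons, 10, 4, rng))
        outgroup_cds[name] = per
    return SynthDataset(config=config, query=query, events=events,
                        outgroups=outgroups, ortholog_maps=ortholog_maps,
                        intraspecies_rows=intraspecies,
                        outgroup_rows=outgroup_rows, cds=cds,
                        outgroup_cds=outgroup_cds)


def sample_ks_mixture(n: int, weights: Sequence[float],
                      modes: Sequence[float], sigmas: Sequence[float],
                      rng_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draws from a lognormal mixture parameterized by component modes.

    mu = ln(mode) + sigma^2 so that exp(mu - sigma^2) equals the requested
    mode. Returns (values, component labels).
    """
    if not (len(weights) == len(modes) == len(sigmas)):
        raise ValueError("weights, modes and sigmas must have equal length")
    rng = np.random.default_rng(rng_seed)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    labels = rng.choice(len(w), size=n, p=w)
    mus = np.log(np.asarray(modes, dtype=float)) + np.asarray(sigmas) ** 2
    values = np.exp(rng.normal(mus[labels], np.asarray(sigmas)[labels]))
    return values, labels


# ---------------------------------------------------------------------------
# fixture bundle on disk


def write_gff3(index: GeneIndex, path) -> None:
    """GFF3 with gene -> mRNA -> exon rows encoding exon counts."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in index:
            fh.write(f"{gene.chrom}\tsynth\tgene\t{gene.start}\t{gene.end}\t"
                     f".\t{gene.strand}\t.\tID={gene.id}\n")
            tid = f"{gene.id}.t1"
            fh.write(f"{gene.chrom}\tsynth\tmRNA\t{gene.start}\t{gene.end}\t"
                     f".\t{gene.strand}\t.\tID={tid};Parent={gene.id}\n")
            span = gene.end - gene.start + 1
            width = max(span // gene.exon_count, 1)
            for e in range(gene.exon_count):
                es = gene.start + e * width
                ee = gene.end if e == gene.exon_count - 1 else min(
                    es + width - 21, gene.end)
                fh.write(f"{gene.chrom}\tsynth\texon\t{es}\t{max(ee, es)}\t"
                         f".\t{gene.strand}\t.\tID={tid}.e{e + 1};"
                         f"Parent={tid}\n")


def write_dataset(dataset: SynthDataset, outdir) -> dict[str, str]:
    """Write the bundle (GFF3 + FASTA + homology TSV + manifest) and return
    the path map."""
    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    paths = {}
    p = outdir / f"{cfg.species}.gff3"
    write_gff3(dataset.query, p)
    paths["annotation"] = str(p)
    p = outdir / f"{cfg.species}_cds.fasta"
    dio.write_fasta(dataset.cds, p)
    paths["cds"] = str(p)
    p = outdir / f"{cfg.species}_proteins.fasta"
    dio.write_fasta(dataset.proteins(), p)
    paths["proteins"] = str(p)
    p = outdir / f"{cfg.species}_self.tsv"
    dio.write_homology(dataset.intraspecies_rows, p)
    paths["intraspecies_hits"] = str(p)
    paths["outgroups"] = {}
    for name, index in dataset.outgroups.items():
        gp = outdir / f"{name}.gff3"
        write_gff3(index, gp)
        hp = outdir / f"{cfg.species}_vs_{name}.tsv"
        dio.write_homology(dataset.outgroup_rows[name], hp)
        paths["outgroups"][name] = {"annotation": str(gp), "hits": str(hp)}
    manifest = {
        "species": cfg.species,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()
                   if not isinstance(v, dict)},
        "mode_counts": cfg.mode_counts,
        "events": [{"mode": e.mode, "source_genes": list(e.source_genes),
                    "copy_genes": list(e.copy_genes)}
                   for e in dataset.events],
        "paths": paths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
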