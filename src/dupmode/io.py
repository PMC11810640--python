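"""Readers and writers for the standard formats the pipeline touches.

Inputs: GFF3 gene annotation, FASTA protein/CDS sequences, and 12-column
tab-separated similarity-search tables (BLAST/DIAMOND ``outfmt 6`` dialect).
Outputs: TSV tables for classified pairs, per-gene modes and frequencies.
"""

from __future__ import annotations

import urllib.parse
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .model import (DupmodeError, DuplicatePair, GeneClassification, GeneIndex,
                    HomologyHit, Paranome)

PathLike = Union[str, Path]

#: Column order of the 12-column tabular similarity-search format.
OUTFMT6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                   "bitscore")


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_annotation(path: PathLike, species: str,
                    feature: str = "gene") -> GeneIndex:
    """Read a GFF3 file into a :class:`GeneIndex` with per-chromosome ranks.

    ``exon_count`` is the number of exon rows of the gene's primary
    (first-listed) transcript; exons parented directly on the gene are the
    fallback, and genes with no exon records at all get ``exon_count = 1``.
    Both GFF3 dialects (exon -> transcript -> gene and exon -> gene) are
    accepted.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}
    tx_rows: list[tuple[str, list[str]]] = []       # (tx id, parent ids)
    exon_rows: list[list[str]] = []                 # parent id lists
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise DupmodeError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns, "
                    f"got {len(cols)}")
            ftype = cols[2]
            attrs = _parse_gff_attributes(cols[8])
            if ftype == feature:
                gid = attrs.get("ID")
                if gid is None:
                    raise DupmodeError(
                        f"{path}: line {lineno}: {feature} record without "
                        f"an ID attribute")
                if gid in genes:
                    raise DupmodeError(f"{path}: duplicate gene ID: {gid}")
                try:
                    start, end = int(cols[3]), int(cols[4])
                except ValueError:
                    raise DupmodeError(
                        f"{path}: line {lineno}: non-integer coordinates"
                    ) from None
                genes[gid] = (cols[0], start, end, cols[6])
            elif ftype == "exon":
                parents = attrs.get("Parent", "")
                if parents:
                    exon_rows.append(parents.split(","))
            else:
                tid, parents = attrs.get("ID"), attrs.get("Parent", "")
                if tid and parents:
                    tx_rows.append((tid, parents.split(",")))

    # first-listed transcript per gene (file order), exon counts per parent
    tx_gene: dict[str, str] = {}
    primary_tx: dict[str, str] = {}
    for tid, parents in tx_rows:
        for p in parents:
            if p in genes:
                tx_gene.setdefault(tid, p)
                primary_tx.setdefault(p, tid)
    exon_of_tx: dict[str, int] = {}
    exon_of_gene: dict[str, int] = {}
    for parents in exon_rows:
        for p in parents:
            if p in tx_gene:
                exon_of_tx[p] = exon_of_tx.get(p, 0) + 1
            elif p in genes:
                exon_of_gene[p] = exon_of_gene.get(p, 0) + 1

    records = []
    for gid, (chrom, start, end, strand) in genes.items():
        count = 0
        if gid in primary_tx:
            count = exon_of_tx.get(primary_tx[gid], 0)
        if count == 0:
            count = exon_of_gene.get(gid, 0)
        records.append((gid, chrom, start, end,
                        strand if strand in ("+", "-", ".") else ".",
                        max(count, 1)))
    return GeneIndex.build(species, records)


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase-sequence mapping.

    The id is the header token before the first whitespace. Duplicate ids
    raise; an empty file yields an empty mapping with a warning.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise DupmodeError(f"{path}: duplicate sequence id: {record.id}")
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return seqs


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_homology(path: PathLike) -> list[HomologyHit]:
    """Read a 12-column tabular similarity-search file (``outfmt 6``).

    Lines starting with ``#`` are skipped; extra trailing columns are
    ignored; fewer than 12 columns or unparsable numeric fields raise with
    the offending line number.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise DupmodeError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(cols)}")
            try:
                hit = HomologyHit(query=cols[0], subject=cols[1],
                                  pct_identity=float(cols[2]),
                                  evalue=float(cols[10]),
                                  bitscore=float(cols[11]))
            except ValueError as exc:
                raise DupmodeError(
                    f"{path}: line {lineno}: unparsable numeric field "
                    f"({exc})") from None
            hits.append(hit)
    return hits


def write_homology(rows: Iterable[Sequence], path: PathLike) -> None:
    """Write full 12-column rows (any sequence of 12+ fields) as outfmt 6."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def build_paranome(hits: Iterable[HomologyHit], index: GeneIndex,
                   max_evalue: float = 1e-10,
                   min_identity: Optional[float] = None) -> Paranome:
    """Collapse filtered hits into the set of within-genome paralog pairs.

    Hits above ``max_evalue`` and self hits are dropped; reciprocal
    duplicates collapse to one canonical pair keeping the minimum E-value
    and maximum bitscore. ``min_identity`` is an optional extra stringency
    filter, off by default.
    """
    paranome = Paranome(species=index.species)
    for hit in hits:
        if hit.query not in index:
            raise DupmodeError(f"hit references unknown gene id: {hit.query}")
        if hit.subject not in index:
            raise DupmodeError(f"hit references unknown gene id: {hit.subject}")
        if hit.evalue > max_evalue:
            continue
        if min_identity is not None and hit.pct_identity < min_identity:
            continue
        paranome.add_hit(hit.query, hit.subject, hit.evalue, hit.bitscore)
    return paranome


_PAIR_COLUMNS = ["gene1", "gene2", "mode", "ka", "ks", "ka_ks"]


def write_pairs(pairs: Sequence[DuplicatePair], path: PathLike) -> None:
    """Write classified pairs as TSV (empty strings for absent rates)."""
    rows = [{"gene1": p.gene1, "gene2": p.gene2, "mode": p.mode,
             "ka": p.ka, "ks": p.ks, "ka_ks": p.ka_ks} for p in pairs]
    df = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_pairs(path: PathLike) -> list[DuplicatePair]:
    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str,
                                            "mode": str})
    pairs = []
    for row in df.itertuples(index=False):
        def _opt(x):
            return None if pd.isna(x) else float(x)
        pairs.append(DuplicatePair(gene1=row.gene1, gene2=row.gene2,
                                   mode=row.mode, ka=_opt(row.ka),
                                   ks=_opt(row.ks), ka_ks=_opt(row.ka_ks)))
    return pairs


def write_gene_classifications(classes: Sequence[GeneClassification],
                               path: PathLike) -> None:
    df = pd.DataFrame([{"gene": c.gene, "mode": c.mode} for c in classes],
                      columns=["gene", "mode"])
    df.to_csv(path, sep="\t", index=False)


def write_frequencies(freq: pd.DataFrame, path: PathLike) -> None:
    freq.to_csv(path, sep="\t", index=False)
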