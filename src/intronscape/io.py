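"""Reading/writing standard formats and deriving the intron inventory.

FASTA is parsed with Biopython, GFF3 with gffutils (in-memory database).
One representative mRNA per gene is kept: the longest CDS, ties broken by
lexicographically smallest mRNA id, so reruns are reproducible.
"""
from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .features import gc_percent
from .model import AnnotationSet, GeneModel, Intron, SequenceRecord, revcomp

INTRON_TSV_COLUMNS = [
    "id",
    "gene_id",
    "seq_id",
    "strand",
    "start",
    "end",
    "ordinal",
    "length",
    "coding_offset",
    "phase",
    "donor2",
    "acceptor2",
    "gc_percent",
    "class_label",
    "family_id",
    "seq",
]

MIN_INTRON_LEN = 4


class MissingSequenceError(KeyError):
    """A GFF3 feature references a sequence id absent from the FASTA."""


def read_fasta(path: str | os.PathLike) -> dict[str, SequenceRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate_cds(cds: str) -> str:
    """Standard-code translation with a trailing stop (if encoded) removed."""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def load_annotation(fasta_path: str | os.PathLike, gff3_path: str | os.PathLike) -> AnnotationSet:
    """Load genome + gene models; keep one representative mRNA per gene.

    Genes whose joined CDS length is not divisible by 3 are excluded from
    intron derivation and reported in ``AnnotationSet.warnings``.
    """
    sequences = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    a = AnnotationSet(sequences=sequences)
    for gene in db.features_of_type("gene"):
        if gene.seqid not in sequences:
            raise MissingSequenceError(
                f"GFF3 references sequence '{gene.seqid}' absent from FASTA"
            )
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            a.warnings.append(f"gene {gene.id}: no mRNA, skipped")
            continue
        best = None
        for m in mrnas:
            cds_len = sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
            key = (-cds_len, m.id)
            if best is None or key < best[0]:
                best = (key, m)
        mrna = best[1]
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")),
            key=lambda t: t[0],
        )
        cds = sorted(
            ((c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")),
            key=lambda t: t[0],
        )
        if not cds:
            a.warnings.append(f"gene {gene.id}: no CDS, skipped")
            continue
        if not exons:
            exons = list(cds)
        cds_len = sum(e - s for s, e in cds)
        g = GeneModel(
            id=gene.id,
            seq_id=gene.seqid,
            strand=gene.strand,
            exon_intervals=exons,
            cds_intervals=cds,
            mrna_id=mrna.id,
        )
        if cds_len % 3 != 0:
            a.warnings.append(f"gene {gene.id}: CDS length {cds_len} not divisible by 3, excluded")
            continue
        seq = sequences[gene.seqid].seq
        joined = "".join(seq[s:e] for s, e in cds)
        if gene.strand == "-":
            joined = revcomp(joined)
        g.protein = translate_cds(joined)
        a.genes[g.id] = g
    return a


def extract_introns(a: AnnotationSet) -> AnnotationSet:
    """Populate ``a.introns``: one intron per gap between consecutive CDS intervals.

    Gaps shorter than 4 nt are logged and skipped.
    """
    a.introns = []
    for g in a.genes.values():
        if len(g.cds_intervals) < 2:
            continue
        seq = a.sequences[g.seq_id].seq
        gaps = []
        for (s1, e1), (s2, e2) in zip(g.cds_intervals, g.cds_intervals[1:]):
            gaps.append((e1, s2))
        if g.strand == "-":
            gaps = gaps[::-1]
        # coding nt 5' of each intron, in transcript order
        cds_sorted = g.cds_intervals if g.strand == "+" else g.cds_intervals[::-1]
        offset = 0
        for ordinal, (gs, ge) in enumerate(gaps, start=1):
            offset += cds_sorted[ordinal - 1][1] - cds_sorted[ordinal - 1][0]
            if ge - gs < MIN_INTRON_LEN:
                a.warnings.append(f"gene {g.id}: intron gap {gs}-{ge} shorter than {MIN_INTRON_LEN} nt, skipped")
                continue
            raw = seq[gs:ge]
            sense = raw if g.strand == "+" else revcomp(raw)
            a.introns.append(
                Intron(
                    id=f"{g.id}.i{ordinal}",
                    gene_id=g.id,
                    seq_id=g.seq_id,
                    strand=g.strand,
                    start=gs,
                    end=ge,
                    ordinal=ordinal,
                    seq=sense,
                    coding_offset=offset,
                    gc_percent=gc_percent(sense),
                )
            )
    return a


def intron_table(a: AnnotationSet) -> pd.DataFrame:
    rows = []
    for i in a.introns:
        rows.append(
            {
                "id": i.id,
                "gene_id": i.gene_id,
                "seq_id": i.seq_id,
                "strand": i.strand,
                "start": i.start,
                "end": i.end,
                "ordinal": i.ordinal,
                "length": i.length,
                "coding_offset": i.coding_offset,
                "phase": i.phase,
                "donor2": i.donor2,
                "acceptor2": i.acceptor2,
                "gc_percent": round(i.gc_percent, 4),
                "class_label": i.class_label,
                "family_id": i.family_id if i.family_id is not None else "",
                "seq": i.seq,
            }
        )
    return pd.DataFrame(rows, columns=INTRON_TSV_COLUMNS)


def write_gff3(a: AnnotationSet, path: str | os.PathLike) -> None:
    """Echo gene models as minimal gene/mRNA/exon/CDS GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, rec in a.sequences.items():
            fh.write(f"##sequence-region {sid} 1 {rec.length}\n")
        for g in sorted(a.genes.values(), key=lambda g: (g.seq_id, g.span[0], g.id)):
            s, e = g.span
            mrna = g.mrna_id or f"{g.id}.m1"
            fh.write(
                f"{g.seq_id}\tintronscape\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            fh.write(
                f"{g.seq_id}\tintronscape\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={mrna};Parent={g.id}\n"
            )
            for j, (xs, xe) in enumerate(g.exon_intervals, 1):
                fh.write(
                    f"{g.seq_id}\tintronscape\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\tID={mrna}.e{j};Parent={mrna}\n"
                )
            # CDS phase column: leading coding nt of this CDS piece mod 3 complement
            pieces = g.cds_intervals if g.strand == "+" else g.cds_intervals[::-1]
            acc = 0
            phases = {}
            for (cs, ce) in pieces:
                phases[(cs, ce)] = (3 - acc % 3) % 3
                acc += ce - cs
            for j, (cs, ce) in enumerate(g.cds_intervals, 1):
                fh.write(
                    f"{g.seq_id}\tintronscape\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{phases[(cs, ce)]}\t"
                    f"ID={mrna}.c{j};Parent={mrna}\n"
                )


def write_tables(a: AnnotationSet, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write intron TSV, intron FASTA, genome FASTA and a GFF3 echo.

    Returns a mapping of artifact name to path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "introns_tsv": os.path.join(out_dir, "introns.tsv"),
        "introns_fasta": os.path.join(out_dir, "introns.fa"),
        "genome_fasta": os.path.join(out_dir, "genome.fa"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
    }
    intron_table(a).to_csv(paths["introns_tsv"], sep="\t", index=False)
    write_fasta(((i.id, i.seq) for i in a.introns), paths["introns_fasta"])
    write_fasta(((r.id, r.seq) for r in a.sequences.values()), paths["genome_fasta"])
    write_gff3(a, paths["gff3"])
    return paths


def read_intron_table(path: str | os.PathLike) -> list[Intron]:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str}, keep_default_na=False)
    introns = []
    for row in df.itertuples(index=False):
        introns.append(
            Intron(
                id=row.id,
                gene_id=row.gene_id,
                seq_id=row.seq_id,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                ordinal=int(row.ordinal),
                seq=row.seq,
                coding_offset=int(row.coding_offset),
                gc_percent=float(row.gc_percent),
                class_label=row.class_label,
                family_id=row.family_id or None,
            )
        )
    return introns
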