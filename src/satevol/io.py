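"""Readers/writers for the plain-text formats the pipeline exchanges:
FASTA/FASTQ (via Biopython), GFF3 gene models, BED intervals and square
distance-matrix TSVs.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_fastq(path, reads: list[tuple[str, str, list[int]]]) -> None:
    recs = []
    for rid, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_gff3(path, genes: list[GeneModel]) -> None:
    """Emit gene/mRNA/exon features, 1-based inclusive per the GFF3 spec."""
    lines = ["##gff-version 3"]
    for gene in genes:
        gid = gene.gene_id
        lines.append(
            "\t".join(
                [
                    gene.scaffold,
                    "satevol",
                    "gene",
                    str(gene.start + 1),
                    str(gene.end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gid}",
                ]
            )
        )
        lines.append(
            "\t".join(
                [
                    gene.scaffold,
                    "satevol",
                    "mRNA",
                    str(gene.start + 1),
                    str(gene.end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gid}.t1;Parent={gid}",
                ]
            )
        )
        for i, (es, ee) in enumerate(sorted(gene.exons)):
            lines.append(
                "\t".join(
                    [
                        gene.scaffold,
                        "satevol",
                        "exon",
                        str(es + 1),
                        str(ee),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gid}.e{i + 1};Parent={gid}.t1",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse the gene/mRNA/exon subset written by :func:`write_gff3`
    (coordinates converted back to 0-based half-open)."""
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            continue
        scaffold, _, ftype, start, end, _, strand, _, attrs = fields[:9]
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = GeneModel(
                gene_id=gid,
                scaffold=scaffold,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
            )
        elif ftype == "mRNA":
            mrna_to_gene[attr["ID"]] = attr["Parent"]
        elif ftype == "exon":
            gid = mrna_to_gene.get(attr.get("Parent", ""), attr.get("Parent"))
            if gid in genes:
                genes[gid].exons.append((int(start) - 1, int(end)))
    return list(genes.values())


def write_bed(path, intervals: list[tuple]) -> None:
    """BED6 rows: (scaffold, start, end, name, score, strand)."""
    lines = []
    for row in intervals:
        scaffold, start, end = row[:3]
        name = row[3] if len(row) > 3 else "."
        score = row[4] if len(row) > 4 else 0
        strand = row[5] if len(row) > 5 else "+"
        lines.append(f"{scaffold}\t{start}\t{end}\t{name}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        out.append(
            (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[3] if len(fields) > 3 else ".",
                int(float(fields[4])) if len(fields) > 4 else 0,
                fields[5] if len(fields) > 5 else "+",
            )
        )
    return out
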