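"""File input/output: FASTQ, FASTA, BED and TSV."""

from __future__ import annotations

import os

from Bio import SeqIO

from .genome import DonorGenome
from .reads import FastqRead


def write_fastq(records, path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_bed(intervals, path: str) -> None:
    """Write (contig, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = (parts[0], int(parts[1]), int(parts[2]), *parts[3:])
            out.append(row)
    return out


def write_genome(genome: DonorGenome, outdir: str, prefix: str = "genome") -> None:
    os.makedirs(outdir, exist_ok=True)
    write_fasta(genome.contigs, os.path.join(outdir, f"{prefix}.fa"))
    write_bed(
        [(c, s, e, cat) for c, s, e, cat in genome.annotations],
        os.path.join(outdir, f"{prefix}_annotations.bed"),
    )
    write_bed(genome.masked, os.path.join(outdir, f"{prefix}_masked.bed"))
    for track, ivs in genome.features.items():
        write_bed(ivs, os.path.join(outdir, f"{prefix}_{track}.bed"))
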