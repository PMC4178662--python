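"""Genome bundle: reference sequences, gene annotation, CNS intervals.

All internal coordinates are 0-based half-open regardless of source format;
the readers/writers here are the only place +-1 adjustments happen (GFF3 is
1-based inclusive, BED already half-open).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Feature", "CnsInterval", "GenomeBundle", "load_genome_bundle",
           "write_genome_bundle", "FEATURE_TYPES"]

FEATURE_TYPES = ("gene", "CDS", "five_prime_UTR", "three_prime_UTR", "exon")


class Feature(NamedTuple):
    contig: str
    start: int           # 0-based
    end: int             # half-open
    strand: str          # '+' or '-'
    ftype: str
    gene_id: str
    phase: int           # 0 for non-CDS


class CnsInterval(NamedTuple):
    contig: str
    start: int
    end: int
    category: str        # intergenic_cns, intronic_cns, utr5_cns, utr3_cns, snc_cns


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    features: list[Feature]
    cns_intervals: list[CnsInterval] = field(default_factory=list)

    def __post_init__(self):
        for f in self.features:
            if f.contig not in self.sequences:
                raise ValueError(f"feature on unknown contig {f.contig}")
            if not (0 <= f.start < f.end <= len(self.sequences[f.contig])):
                raise ValueError(
                    f"feature {f.ftype} {f.gene_id} [{f.start},{f.end}) "
                    f"outside contig {f.contig}")

    def features_of(self, gene_id: str, ftype: str | None = None
                    ) -> list[Feature]:
        out = [f for f in self.features if f.gene_id == gene_id]
        if ftype is not None:
            out = [f for f in out if f.ftype == ftype]
        return out

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            if f.ftype == "gene":
                seen.setdefault(f.gene_id)
        return list(seen)

    def contig_length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def coding_sequence(self, gene_id: str) -> str:
        """CDS segments concatenated in transcription order (reverse
        complemented for minus-strand genes)."""
        segs = sorted(self.features_of(gene_id, "CDS"), key=lambda f: f.start)
        if not segs:
            return ""
        strand = segs[0].strand
        parts = [self.sequences[f.contig][f.start:f.end] for f in segs]
        cds = "".join(parts)
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_genome_bundle(fasta_path, gff3_path, bed_path=None) -> GenomeBundle:
    """Read FASTA + GFF3 (+ optional CNS BED) into a GenomeBundle.

    GFF3 coordinates (1-based inclusive) and BED (0-based half-open) are
    normalized to internal 0-based half-open.
    """
    sequences = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(fasta_path), "fasta")}
    features: list[Feature] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{gff3_path}:{lineno}: expected 9 GFF3 columns, "
                    f"got {len(cols)}")
            contig, _src, ftype, start, end, _score, strand, phase, attr = cols
            if ftype not in FEATURE_TYPES:
                continue
            try:
                start_i = int(start) - 1   # to 0-based
                end_i = int(end)           # inclusive end == half-open end
            except ValueError as exc:
                raise ValueError(
                    f"{gff3_path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gff3_attributes(attr)
            gene_id = attrs.get("ID") or attrs.get("Parent") or ""
            gene_id = gene_id.split(".")[0]
            ph = int(phase) if phase not in (".", "") else 0
            if contig not in sequences:
                raise ValueError(
                    f"{gff3_path}:{lineno}: unknown contig {contig}")
            if not (0 <= start_i < end_i <= len(sequences[contig])):
                raise ValueError(
                    f"{gff3_path}:{lineno}: feature outside contig bounds")
            features.append(Feature(contig, start_i, end_i, strand, ftype,
                                    gene_id, ph))
    cns: list[CnsInterval] = []
    if bed_path is not None and os.path.exists(str(bed_path)):
        with open(bed_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{bed_path}:{lineno}: short BED line")
                category = cols[3] if len(cols) > 3 else "intergenic_cns"
                cns.append(CnsInterval(cols[0], int(cols[1]), int(cols[2]),
                                       category))
    return GenomeBundle(sequences, features, cns)


def write_genome_bundle(bundle: GenomeBundle, fasta_path, gff3_path,
                        bed_path=None) -> None:
    records = [SeqRecord(Seq(s), id=c, description="")
               for c, s in bundle.sequences.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in bundle.features:
            attr = (f"ID={f.gene_id}" if f.ftype == "gene"
                    else f"Parent={f.gene_id}")
            phase = str(f.phase) if f.ftype == "CDS" else "."
            fh.write(f"{f.contig}\tpopsel\t{f.ftype}\t{f.start + 1}\t{f.end}"
                     f"\t.\t{f.strand}\t{phase}\t{attr}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in bundle.cns_intervals:
                fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.category}\n")
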