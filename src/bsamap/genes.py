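"""Gene models: exon structure, genomic<->CDS coordinate mapping, GFF3/FASTA I/O.

Coordinates are 0-based half-open internally; GFF3 emission and parsing use
the format's 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
from Bio.Seq import Seq
from pyfaidx import Fasta

__all__ = ["GeneModel", "make_synthetic_suppressor_gene", "write_gff3", "read_gene_models"]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with a single transcript, CDS == exons.

    ``exons`` are genomic 0-based half-open intervals in ascending genomic
    order regardless of strand; ``cds_sequence`` is the spliced coding
    sequence on the coding strand, starting at the start codon.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.exons:
            if not start < end:
                raise ValueError(f"empty exon interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = end
        exon_len = sum(e - s for s, e in self.exons)
        if exon_len != len(self.cds_sequence):
            raise ValueError("spliced exon length does not match CDS sequence length")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not self.cds_sequence.upper().startswith("ATG"):
            raise ValueError("CDS must begin with a start codon")
        if self.cds_sequence.upper()[-3:] not in _STOPS:
            raise ValueError("CDS must end with a stop codon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def genomic_to_cds(self, pos: int) -> int | None:
        """CDS offset (0-based, from the start codon) of a genomic position.

        Returns None for intronic or out-of-gene positions.
        """
        offset = 0
        for start, end in self.exons:
            if start <= pos < end:
                plus_offset = offset + (pos - start)
                if self.strand == "+":
                    return plus_offset
                return len(self.cds_sequence) - 1 - plus_offset
            offset += end - start
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        n = len(self.cds_sequence)
        if not 0 <= cds_pos < n:
            raise IndexError(f"CDS position {cds_pos} outside [0, {n})")
        plus_offset = cds_pos if self.strand == "+" else n - 1 - cds_pos
        for start, end in self.exons:
            if plus_offset < end - start:
                return start + plus_offset
            plus_offset -= end - start
        raise AssertionError("unreachable: exon lengths match CDS length")

    def distance_to_splice_junction(self, pos: int) -> int | None:
        """bp distance from an intronic position to the nearest exon edge.

        Returns None for exonic positions and positions outside the gene.
        """
        if self.genomic_to_cds(pos) is not None:
            return None
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 <= pos < s2:
                return min(pos - e1 + 1, s2 - pos)
        return None


def _random_internal_codon(rng: np.random.Generator) -> str:
    bases = "ACGT"
    while True:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in _STOPS:
            return codon


def make_synthetic_suppressor_gene(
    gene_id: str,
    chromosome: str,
    start_bp: int,
    rng: np.random.Generator,
    strand: str = "+",
    n_codons: int = 501,
    lesion_codons: tuple[int, ...] = (335, 374),
    exon_cds_lengths: tuple[int, ...] = (300, 300, 903),
    intron_lengths: tuple[int, ...] = (180, 240),
) -> tuple[GeneModel, str, list[tuple[int, str, str]]]:
    """Construct a synthetic suppressor gene with plantable stop-gain sites.

    The CDS is random non-stop codons with a CAA (Gln) codon forced at each
    entry of ``lesion_codons`` (1-based codon indices), so that a C>T at the
    first codon position creates a TAA termination codon — the lesion type
    observed in UV mutagenesis screens.  With the defaults both lesion
    codons fall in the third exon.

    Returns the gene model, the genomic sequence of the gene span (genomic
    plus strand), and the planted lesions as
    ``(genomic_pos, ref_base, alt_base)`` on the genomic strand.
    """
    cds_len = 3 * n_codons
    if sum(exon_cds_lengths) != cds_len:
        raise ValueError("exon CDS lengths must sum to the CDS length")
    if len(intron_lengths) != len(exon_cds_lengths) - 1:
        raise ValueError("need one fewer intron than exons")
    codons = ["ATG"] + [_random_internal_codon(rng) for _ in range(n_codons - 2)] + ["TAA"]
    for idx in lesion_codons:
        if not 1 < idx < n_codons:
            raise ValueError(f"lesion codon {idx} outside the CDS interior")
        codons[idx - 1] = "CAA"
    cds = "".join(codons)

    # splice the CDS across exons, filling introns with GT...AG
    exon_seqs: list[str] = []
    off = 0
    for ln in exon_cds_lengths:
        exon_seqs.append(cds[off : off + ln])
        off += ln
    intron_seqs = [
        "GT" + "".join(rng.choice(list("ACGT"), size=ln - 4)) + "AG"
        for ln in intron_lengths
    ]
    coding_genomic = exon_seqs[0]
    for intron, exon in zip(intron_seqs, exon_seqs[1:]):
        coding_genomic += intron + exon

    # exon intervals on the coding strand, then flip to genomic if needed
    coding_exons: list[tuple[int, int]] = []
    pos = 0
    for exon, intron in zip(exon_seqs, intron_seqs + [""]):
        coding_exons.append((pos, pos + len(exon)))
        pos += len(exon) + len(intron)
    span = len(coding_genomic)

    if strand == "+":
        genomic_seq = coding_genomic
        exons = tuple((start_bp + s, start_bp + e) for s, e in coding_exons)
    else:
        genomic_seq = str(Seq(coding_genomic).reverse_complement())
        exons = tuple(
            sorted((start_bp + span - e, start_bp + span - s) for s, e in coding_exons)
        )

    gene = GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        cds_sequence=cds,
    )
    lesions = []
    for idx in lesion_codons:
        cds_pos = 3 * (idx - 1)  # first base of the codon
        gpos = gene.cds_to_genomic(cds_pos)
        ref, alt = ("C", "T") if strand == "+" else ("G", "A")
        lesions.append((gpos, ref, alt))
    return gene, genomic_seq, lesions


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            row = [g.chromosome, "bsamap", "gene", str(g.start + 1), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(row + [attrs]) + "\n")
            mrna_id = f"{g.gene_id}.1"
            row[2] = "mRNA"
            fh.write("\t".join(row + [f"ID={mrna_id};Parent={g.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                for feat in ("exon", "CDS"):
                    frow = [g.chromosome, "bsamap", feat, str(s + 1), str(e), ".", g.strand, "0" if feat == "CDS" else "."]
                    frow[7] = "." if feat == "exon" else frow[7]
                    fh.write(
                        "\t".join(frow + [f"ID={mrna_id}.{feat}{i};Parent={mrna_id}"]) + "\n"
                    )


def read_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 + genome FASTA (CDS == annotated CDS rows)."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = Fasta(str(fasta_path))
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds_parts = sorted(
            (
                (f.start - 1, f.end)
                for f in db.children(gene, featuretype="CDS")
            ),
        )
        spliced = "".join(str(fasta[gene.seqid][s:e]) for s, e in cds_parts).upper()
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=tuple(cds_parts),
                cds_sequence=spliced,
            )
        )
    return genes

# CDS phase is always 0 here: these models carry no UTRs and the CDS starts
# at the start codon, so phase handling reduces to the identity.
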