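"""Causative-variant candidate identification within a mapped region.

Starting from the four-sample variant table, this module keeps novel
variants (absent from both sequenced parents, present in the mutant pool),
restricts them to the region called by the genome scan, requires their
pooled frequencies to match the segregation expectation for the causative
lesion itself (mutant pool 2/3, control pool 0 at full viability — the
lesion rides the mutagenized parent's haplotype), annotates the coding
effect against a gene model, and ranks by effect severity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genes import GeneModel
from .scan import RegionCall

__all__ = [
    "CandidateVariant",
    "EFFECT_SEVERITY",
    "find_novel_variants",
    "frequency_match_filter",
    "annotate_effect",
    "rank_candidates",
]

#: most to least severe; ranking sorts by this order
EFFECT_SEVERITY = ("stop_gained", "splice_adjacent", "missense", "synonymous", "noncoding")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CandidateVariant:
    """A novel (non-parental) variant with pool evidence and annotation."""

    chromosome: str
    position_bp: int
    ref: str
    alt: str
    control_freq: float
    mutant_freq: float
    control_depth: int
    mutant_depth: int
    in_region: bool = False
    effect: str | None = None
    gene_id: str | None = None
    codon_index: int | None = None
    amino_acid_change: str | None = None
    rank_score: float | None = None

    def __post_init__(self) -> None:
        for f_ in (self.control_freq, self.mutant_freq):
            if not 0.0 <= f_ <= 1.0:
                raise ValueError("pool frequencies must lie in [0, 1]")

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


def find_novel_variants(
    variant_table: pd.DataFrame,
    min_parent_depth: int = 10,
    min_alt_reads: int = 3,
) -> list[CandidateVariant]:
    """Variants confidently absent from both parents, present in the mutant pool.

    "Confidently homozygous reference" means a genotype call of 0 with
    depth >= ``min_parent_depth`` and zero alternate reads in that parent;
    the mutant pool must carry at least ``min_alt_reads`` alternate reads
    (suppressing sequencing-error noise at ~44x depth).
    """
    required = {"p1_gt", "p2_gt", "p1_dp", "p2_dp", "p1_alt_ad", "p2_alt_ad"}
    missing = required - set(variant_table.columns)
    if missing:
        raise ValueError(f"variant table lacks parent sample fields: {sorted(missing)}")
    vt = variant_table
    keep = (
        (vt["p1_gt"] == 0)
        & (vt["p2_gt"] == 0)
        & (vt["p1_dp"] >= min_parent_depth)
        & (vt["p2_dp"] >= min_parent_depth)
        & (vt["p1_alt_ad"] == 0)
        & (vt["p2_alt_ad"] == 0)
        & (vt["mut_alt"] >= min_alt_reads)
    )
    out = []
    for row in vt.loc[keep].itertuples(index=False):
        c_dep, m_dep = int(row.ctrl_depth), int(row.mut_depth)
        out.append(
            CandidateVariant(
                chromosome=row.chrom,
                position_bp=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                control_freq=row.ctrl_alt / c_dep if c_dep else 0.0,
                mutant_freq=row.mut_alt / m_dep if m_dep else 0.0,
                control_depth=c_dep,
                mutant_depth=m_dep,
            )
        )
    return out


def _band(expected: float, depth: int, tolerance: float) -> float:
    se = np.sqrt(expected * (1 - expected) / depth) if depth > 0 else 0.0
    return max(tolerance, 3.0 * se)


def frequency_match_filter(
    variants: Iterable[CandidateVariant],
    region: RegionCall,
    expected_mut_freq: float = 2.0 / 3.0,
    expected_ctrl_freq: float = 0.0,
    tolerance: float = 0.1,
) -> list[CandidateVariant]:
    """Keep in-region variants whose pool frequencies match the lesion expectation.

    The acceptance band around each expectation is
    ``max(tolerance, 3 * binomial SE at the observed depth)``, so deeper
    sites are held to the fixed tolerance while shallow sites get the
    sampling slack they deserve.  An unlinked variant sitting near 0.5 in
    both pools falls outside the control-pool band and is rejected.
    """
    if region is None:
        raise ValueError("a called region is required")
    kept = []
    for v in variants:
        if not region.contains(v.chromosome, v.position_bp):
            continue
        ok_mut = abs(v.mutant_freq - expected_mut_freq) <= _band(
            expected_mut_freq, v.mutant_depth, tolerance
        )
        ok_ctrl = abs(v.control_freq - expected_ctrl_freq) <= _band(
            expected_ctrl_freq, v.control_depth, tolerance
        )
        if ok_mut and ok_ctrl:
            kept.append(replace(v, in_region=True))
    return kept


def annotate_effect(variant: CandidateVariant, gene: GeneModel) -> CandidateVariant:
    """Classify the coding effect of a substitution against one gene model.

    Exonic positions are mapped to CDS coordinates (honouring strand and
    introns), the base substituted, and the affected codon translated with
    the standard genetic code.  Intronic positions within 2 bp of a splice
    junction are ``splice_adjacent``; other intronic and out-of-gene
    positions are ``noncoding``.  Codon indices are reported 1-based from
    the start codon (Gln335Ter-style notation).
    """
    pos = variant.position_bp
    if variant.chromosome != gene.chromosome or not gene.start <= pos < gene.end:
        return replace(variant, effect="noncoding", gene_id=None)
    cds_pos = gene.genomic_to_cds(pos)
    if cds_pos is None:
        dist = gene.distance_to_splice_junction(pos)
        effect = "splice_adjacent" if dist is not None and dist <= 2 else "noncoding"
        return replace(variant, effect=effect, gene_id=gene.gene_id)

    ref, alt = variant.ref, variant.alt
    if gene.strand == "-":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    if gene.cds_sequence[cds_pos] != ref:
        raise ValueError(
            f"reference mismatch at {variant.chromosome}:{pos}: CDS has "
            f"{gene.cds_sequence[cds_pos]}, variant says {ref}"
        )
    codon_i = cds_pos // 3
    codon = gene.cds_sequence[3 * codon_i : 3 * codon_i + 3]
    offset = cds_pos % 3
    new_codon = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_alt == "*" and aa_ref != "*":
        effect = "stop_gained"
    elif aa_alt == aa_ref:
        effect = "synonymous"
    else:
        effect = "missense"
    change = f"{_aa3(aa_ref)}{codon_i + 1}{_aa3(aa_alt)}"
    return replace(
        variant,
        effect=effect,
        gene_id=gene.gene_id,
        codon_index=codon_i + 1,
        amino_acid_change=change,
    )


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


def _aa3(aa: str) -> str:
    return _AA3.get(aa, aa)


def rank_candidates(
    variants: Sequence[CandidateVariant],
    expected_mut_freq: float = 2.0 / 3.0,
    expected_ctrl_freq: float = 0.0,
) -> list[CandidateVariant]:
    """Order candidates: effect severity, then frequency fit, then position.

    The frequency-fit key is the summed absolute deviation of the pool
    frequencies from their expectations; ties beyond that break on genomic
    coordinate, so the ordering is stable and deterministic.
    """
    severity = {e: i for i, e in enumerate(EFFECT_SEVERITY)}

    def key(v: CandidateVariant):
        dev = abs(v.mutant_freq - expected_mut_freq) + abs(
            v.control_freq - expected_ctrl_freq
        )
        sev = severity.get(v.effect or "noncoding", len(EFFECT_SEVERITY))
        return (sev, dev, v.chromosome, v.position_bp)

    ranked = sorted(variants, key=key)
    return [
        replace(v, rank_score=float(len(ranked) - i)) for i, v in enumerate(ranked)
    ]
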