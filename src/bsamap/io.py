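"""Shared I/O: the four-sample VCF dialect, run configuration, outputs.

VCF files are 1-based; everything in memory is 0-based half-open.  The
variant table produced by :func:`read_vcf` is the common currency of the
scan and candidate modules: one row per site with parental genotypes and
depths plus per-pool depth and alternate-allele counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .candidates import CandidateVariant
from .scan import RegionCall

__all__ = ["RunConfig", "read_vcf", "write_outputs"]

REQUIRED_SAMPLES = ("PARENT1", "PARENT2", "POOL_CTRL", "POOL_MUT")


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for a pipeline run; defaults match each stage's own.

    Round-trips through YAML unchanged, so a run can be reproduced from its
    serialized config alone.
    """

    seed: int = 0
    window_markers: int = 51
    smooth_window: int = 51
    min_depth: int = 10
    min_parent_depth: int = 10
    n_permutations: int = 200
    threshold_quantile: float = 0.95
    clip: float = 0.01
    min_alt_reads: int = 3
    frequency_tolerance: float = 0.1
    selection_viability: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _gt_code(sample) -> int:
    """Haploid genotype as 0/1; -1 for missing."""
    alleles = sample.get("GT")
    if alleles is None:
        return -1
    alleles = [a for a in alleles if a is not None]
    if not alleles:
        return -1
    return int(alleles[0])


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Parse the four-sample dialect into the variant table.

    Requires samples PARENT1, PARENT2, POOL_CTRL, POOL_MUT, with DP on all
    samples and AD on the pools; extra INFO fields are tolerated.  Records
    must be coordinate-sorted within each chromosome.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in REQUIRED_SAMPLES if s not in samples]
        if missing:
            raise ValueError(f"VCF is missing required samples: {missing}")
        last: dict[str, int] = {}
        for rec in vcf:
            if rec.chrom in last and rec.start <= last[rec.chrom]:
                raise ValueError(
                    f"VCF not sorted: {rec.chrom}:{rec.pos} after position "
                    f"{last[rec.chrom] + 1}"
                )
            last[rec.chrom] = rec.start
            if rec.alts is None or len(rec.alts) != 1:
                continue  # only biallelic records carry a single pooled AD split
            p1, p2 = rec.samples["PARENT1"], rec.samples["PARENT2"]
            row = {
                "chrom": rec.chrom,
                "pos": rec.start,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "p1_gt": _gt_code(p1),
                "p2_gt": _gt_code(p2),
                "p1_dp": p1.get("DP") or 0,
                "p2_dp": p2.get("DP") or 0,
            }
            for parent, s in (("p1", p1), ("p2", p2)):
                ad = s.get("AD")
                row[f"{parent}_alt_ad"] = int(ad[1]) if ad is not None and len(ad) > 1 else 0
            for pool, s in (("ctrl", rec.samples["POOL_CTRL"]), ("mut", rec.samples["POOL_MUT"])):
                ad = s.get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    raise ValueError(
                        f"pool sample missing AD (allele depth) field at {rec.chrom}:{rec.pos}"
                    )
                dp = s.get("DP")
                row[f"{pool}_depth"] = int(dp) if dp is not None else int(ad[0] + ad[1])
                row[f"{pool}_alt"] = int(ad[1])
            rows.append(row)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return pd.DataFrame(rows)


def write_outputs(
    track: pd.DataFrame,
    regions: list[RegionCall],
    candidates: list[CandidateVariant],
    outdir: str | Path,
    config: RunConfig,
    extra_summary: dict | None = None,
) -> dict[str, Path]:
    """Write TSV tracks, BED regions, candidate TSV and a JSON run summary.

    Outputs are deterministic for a given input and config (no timestamps),
    so reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "track": outdir / "frequency_track.tsv",
        "regions": outdir / "regions.bed",
        "candidates": outdir / "candidates.tsv",
        "summary": outdir / "run_summary.json",
    }

    cols = [
        "chrom", "pos", "ref", "alt", "ctrl_depth", "mut_depth",
        "ctrl_freq", "mut_freq", "ctrl_smooth", "mut_smooth",
        "window_score", "included",
    ]
    track_out = track[[c for c in cols if c in track.columns]]
    track_out.to_csv(paths["track"], sep="\t", index=False, float_format="%.6g")

    with open(paths["regions"], "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for i, r in enumerate(regions, 1):
            fh.write(
                f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\tregion_{i}\t"
                f"{r.peak_score:.4g}\n"
            )

    cand_rows = [
        {
            "chrom": v.chromosome,
            "pos": v.position_bp,
            "ref": v.ref,
            "alt": v.alt,
            "substitution": v.substitution,
            "control_freq": round(v.control_freq, 6),
            "mutant_freq": round(v.mutant_freq, 6),
            "in_region": v.in_region,
            "effect": v.effect,
            "gene_id": v.gene_id,
            "codon_index": v.codon_index,
            "amino_acid_change": v.amino_acid_change,
            "rank_score": v.rank_score,
        }
        for v in candidates
    ]
    pd.DataFrame(
        cand_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "substitution", "control_freq",
            "mutant_freq", "in_region", "effect", "gene_id", "codon_index",
            "amino_acid_change", "rank_score",
        ],
    ).to_csv(paths["candidates"], sep="\t", index=False)

    summary = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "n_regions": len(regions),
        "n_candidates": len(candidates),
    }
    if extra_summary:
        summary.update(extra_summary)
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
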