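"""End-to-end pipeline: simulate -> scan -> candidates, plus YAML model I/O."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .candidates import (
    CandidateVariant,
    annotate_effect,
    find_novel_variants,
    frequency_match_filter,
    rank_candidates,
)
from .cross import (
    CrossConfig,
    ExperimentResult,
    default_cross_config,
    default_layout,
    simulate_experiment,
)
from .genes import GeneModel
from .io import RunConfig
from .scan import ScanResult, scan_genome
from .segregation import (
    FunctionalLocus,
    PhenotypeModel,
    expected_pool_allele_frequency,
    suppressor_screen_model,
)

__all__ = [
    "PipelineResult",
    "variant_table_from_result",
    "lesion_expected_frequencies",
    "run_candidate_stage",
    "run_pipeline",
    "model_from_yaml",
    "model_to_yaml",
    "cross_config_from_yaml",
]


def variant_table_from_result(result: ExperimentResult) -> pd.DataFrame:
    """The analysis-facing variant table for a simulated experiment.

    Identical in content to reading the emitted VCF back; the truth columns
    (``kind``, ``alt_origin``) are dropped so downstream stages see only
    what sequencing would reveal.
    """
    c = result.counts
    is_marker = (c["kind"] == "marker").to_numpy()
    return pd.DataFrame(
        {
            "chrom": c["chrom"],
            "pos": c["pos"],
            "ref": c["ref"],
            "alt": c["alt"],
            "p1_gt": 0,
            "p2_gt": is_marker.astype(int),
            "p1_dp": c["p1_dp"],
            "p2_dp": c["p2_dp"],
            "p1_alt_ad": 0,
            "p2_alt_ad": np.where(is_marker, c["p2_dp"], 0),
            "ctrl_depth": c["ctrl_depth"],
            "ctrl_alt": c["ctrl_alt"],
            "mut_depth": c["mut_depth"],
            "mut_alt": c["mut_alt"],
        }
    )


def lesion_expected_frequencies(model: PhenotypeModel) -> tuple[float, float]:
    """Expected (mutant, control) pool frequency of the causative lesion allele.

    The lesion is the parent-1 allele at the suppressor locus, so its
    expected pool frequency is one minus the parent-2 expectation: 2/3 in
    the mutant pool and 0 in the control pool at full viability.
    """
    sup = model.locus("suppressor")
    f2_mut = expected_pool_allele_frequency(model, "mutant", sup, 0.0).frequency
    f2_ctrl = expected_pool_allele_frequency(model, "control", sup, 0.0).frequency
    return 1.0 - f2_mut, 1.0 - f2_ctrl


@dataclass
class PipelineResult:
    scan: ScanResult
    candidates: list[CandidateVariant]
    novel: list[CandidateVariant]


def run_candidate_stage(
    variant_table: pd.DataFrame,
    scan_result: ScanResult,
    genes: list[GeneModel],
    model: PhenotypeModel,
    run: RunConfig,
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Novel-variant detection, region/frequency filtering, annotation, ranking."""
    novel = find_novel_variants(
        variant_table,
        min_parent_depth=run.min_parent_depth,
        min_alt_reads=run.min_alt_reads,
    )
    exp_mut, exp_ctrl = lesion_expected_frequencies(model)
    kept: list[CandidateVariant] = []
    seen: set[tuple[str, int]] = set()
    for region in scan_result.regions:
        for v in frequency_match_filter(
            novel, region, exp_mut, exp_ctrl, run.frequency_tolerance
        ):
            key = (v.chromosome, v.position_bp)
            if key not in seen:
                seen.add(key)
                kept.append(v)
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    annotated = []
    for v in kept:
        ann = None
        for g in by_chrom.get(v.chromosome, []):
            a = annotate_effect(v, g)
            if a.gene_id is not None:
                ann = a
                break
        annotated.append(ann if ann is not None else replace(v, effect="noncoding"))
    return rank_candidates(annotated, exp_mut, exp_ctrl), novel


def run_pipeline(
    config: CrossConfig, run: RunConfig | None = None, null: bool = False
) -> PipelineResult:
    """Simulate one experiment and analyse it end to end, fully seeded."""
    run = run or RunConfig(seed=config.seed)
    result = simulate_experiment(config, null=null)
    vt = variant_table_from_result(result)
    scan_result = scan_genome(
        vt,
        config.model,
        window_markers=run.window_markers,
        min_depth=run.min_depth,
        min_parent_depth=run.min_parent_depth,
        n_permutations=run.n_permutations,
        quantile=run.threshold_quantile,
        clip=run.clip,
        seed=run.seed,
        smooth_window=run.smooth_window,
    )
    ranked, novel = run_candidate_stage(
        vt, scan_result, [result.parents.gene], config.model, run
    )
    return PipelineResult(scan=scan_result, candidates=ranked, novel=novel)


# --- YAML descriptions -----------------------------------------------------


def model_to_yaml(model: PhenotypeModel, path: str | Path, viability: float = 1.0) -> None:
    data = {
        "loci": [
            {
                "name": l.name,
                "chromosome": l.chromosome,
                "position_bp": l.position_bp,
                "position_cm": l.position_cm,
                "mutant_parent": l.mutant_parent,
                "role": l.role,
            }
            for l in model.loci
        ],
        "selection_viability": viability,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def model_from_yaml(path: str | Path) -> PhenotypeModel:
    """Build the canonical screen model from a YAML locus description."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    loci = {l["role"]: FunctionalLocus(**l) for l in data["loci"]}
    if set(loci) != {"selection", "suppressor"}:
        raise ValueError("model YAML must define one selection and one suppressor locus")
    return suppressor_screen_model(
        loci["selection"], loci["suppressor"], float(data.get("selection_viability", 1.0))
    )


def cross_config_from_yaml(path: str | Path, seed: int | None = None) -> CrossConfig:
    """Cross configuration from YAML; flat keys override the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    layout = default_layout(
        n_chromosomes=data.pop("n_chromosomes", 27),
        length_bp=data.pop("chromosome_length_bp", 5_000_000),
        length_cm=data.pop("chromosome_length_cm", 100.0),
        marker_spacing_bp=data.pop("marker_spacing_bp", 25_000.0),
    )
    if seed is not None:
        data["seed"] = seed
    viability = data.pop("selection_viability", 1.0)
    return default_cross_config(layout=layout, selection_viability=viability, **data)
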