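"""Synthetic haploid cross: parental genomes, meiosis, pools, pooled counts.

This module generates the full synthetic experiment the analysis modules
consume: two divergent haploid parental genomes densely differing at SNP
markers, UV-induced variants private to the mutagenized parent (including
two planted C>T stop-gains in one suppressor gene), recombinant haploid
progeny produced under a Haldane (no-interference, Poisson-crossover)
meiosis model, phenotype-sorted sequencing pools, and per-marker pooled
read counts at a configurable mean depth and sequencing-error rate.

The default configuration mirrors the screen design the package models:
27 chromosomes, a selection locus and a suppressor locus on different
chromosomes, a control pool of 80 non-suppressed and a mutant pool of 98
suppressed progeny, mean sequencing depth 44x, per-base error 1e-3.  The
physical genome is scaled down (5 Mb / 100 cM per chromosome, ~25 kb
marker spacing) so a full experiment runs in seconds.

Internal coordinates are 0-based half-open; VCF emission is 1-based.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .genes import GeneModel, make_synthetic_suppressor_gene, write_gff3
from .segregation import (
    FunctionalLocus,
    PhenotypeModel,
    suppressor_screen_model,
)

__all__ = [
    "ChromosomeSpec",
    "GenomeLayout",
    "CrossConfig",
    "Individual",
    "ParentGenomes",
    "ExperimentResult",
    "default_layout",
    "default_cross_config",
    "build_parent_genomes",
    "simulate_gamete",
    "simulate_progeny_population",
    "construct_pools",
    "construct_null_pools",
    "pool_alt_frequencies",
    "simulate_pooled_counts",
    "simulate_experiment",
    "emit_vcf",
    "emit_fasta",
    "emit_gff3",
]

VCF_SAMPLES = ("PARENT1", "PARENT2", "POOL_CTRL", "POOL_MUT")


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: lengths must be positive")


@dataclass(frozen=True)
class GenomeLayout:
    """Physical + genetic layout of the synthetic genome."""

    chromosomes: tuple[ChromosomeSpec, ...]
    marker_spacing_bp: float = 25_000.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        if self.marker_spacing_bp <= 0:
            raise ValueError("marker spacing must be positive")

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def bp_to_cm(self, chrom: str, pos_bp: float) -> float:
        c = self.chromosome(chrom)
        return pos_bp / c.length_bp * c.length_cm

    def cm_to_bp(self, chrom: str, pos_cm: float) -> int:
        c = self.chromosome(chrom)
        return int(round(pos_cm / c.length_cm * c.length_bp))


def default_layout(
    n_chromosomes: int = 27,
    length_bp: int = 5_000_000,
    length_cm: float = 100.0,
    marker_spacing_bp: float = 25_000.0,
) -> GenomeLayout:
    """Scaled-down 27-chromosome layout used as the default design point."""
    chroms = tuple(
        ChromosomeSpec(f"Chr{i:02d}", length_bp, length_cm)
        for i in range(1, n_chromosomes + 1)
    )
    return GenomeLayout(chromosomes=chroms, marker_spacing_bp=marker_spacing_bp)


@dataclass(frozen=True)
class CrossConfig:
    """Everything needed to simulate one experiment, reproducibly."""

    layout: GenomeLayout
    model: PhenotypeModel
    n_uv_mutations: int = 150
    uv_ct_ga_fraction: float = 0.8
    lesion_codons: tuple[int, ...] = (335, 374)
    suppressor_gene_id: str = "SyntheticSuppressorGene"
    n_progeny: int = 1000
    n_control: int = 80
    n_mutant: int = 98
    mean_depth: float = 44.0
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be > 0")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ValueError("error rate must be in [0, 0.01]")
        if self.n_progeny <= 0 or self.n_control < 0 or self.n_mutant < 0:
            raise ValueError("population and pool sizes must be non-negative")


def default_cross_config(
    seed: int = 0, selection_viability: float = 1.0, **overrides
) -> CrossConfig:
    """The default experiment: two unlinked loci on Chr01 / Chr08, 80+98 pools, 44x."""
    layout = overrides.pop("layout", default_layout())
    selection = FunctionalLocus(
        "NOG1", "Chr01", 2_000_000, layout.bp_to_cm("Chr01", 2_000_000), 1, "selection"
    )
    suppressor = FunctionalLocus(
        "SNOG1A", "Chr08", 2_500_000, layout.bp_to_cm("Chr08", 2_500_000), 1, "suppressor"
    )
    model = overrides.pop(
        "model",
        suppressor_screen_model(selection, suppressor, selection_viability),
    )
    return CrossConfig(layout=layout, model=model, seed=seed, **overrides)


@dataclass
class Individual:
    """One haploid progeny: parental-origin mosaic plus derived state.

    ``breakpoints[chrom]`` holds the internal crossover positions (bp,
    ascending, excluding 0 and the chromosome end); the parental origin of
    the segment starting at 0 is ``first_origin[chrom]`` and alternates at
    each breakpoint, so segments tile the chromosome exactly.
    """

    breakpoints: dict[str, np.ndarray]
    first_origin: dict[str, int]
    genotype: tuple[int, ...] | None = None
    phenotype: str | None = None
    survived: bool = True

    def origins_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        n_breaks_before = np.searchsorted(self.breakpoints[chrom], positions, side="right")
        first = self.first_origin[chrom]
        return np.where(n_breaks_before % 2 == 0, first, 3 - first)

    def origin_at(self, chrom: str, pos: int) -> int:
        return int(self.origins_at(chrom, np.asarray([pos]))[0])

    def segments(self, chrom: str, length_bp: int) -> list[tuple[int, int, int]]:
        """(start, end, origin) tiles covering [0, length_bp)."""
        edges = [0, *self.breakpoints[chrom].tolist(), length_bp]
        origin = self.first_origin[chrom]
        out = []
        for s, e in zip(edges, edges[1:]):
            out.append((s, e, origin))
            origin = 3 - origin
        return out


def simulate_gamete(layout: GenomeLayout, rng: np.random.Generator) -> Individual:
    """Draw one recombinant haploid gamete under the Haldane model.

    Per chromosome: crossover count ~ Poisson(map length in Morgans),
    breakpoints uniform in map distance (mapped linearly to bp), starting
    parental origin Bernoulli(1/2), no crossover interference.
    """
    breakpoints: dict[str, np.ndarray] = {}
    first_origin: dict[str, int] = {}
    for c in layout.chromosomes:
        n_co = rng.poisson(c.length_cm / 100.0)
        if n_co:
            cm = np.sort(rng.uniform(0.0, c.length_cm, size=n_co))
            bp = np.unique((cm / c.length_cm * c.length_bp).astype(np.int64))
            bp = bp[(bp > 0) & (bp < c.length_bp)]
        else:
            bp = np.empty(0, dtype=np.int64)
        breakpoints[c.name] = bp
        first_origin[c.name] = int(rng.integers(1, 3))
    return Individual(breakpoints=breakpoints, first_origin=first_origin)


@dataclass
class ParentGenomes:
    """Output of :func:`build_parent_genomes`.

    ``variants`` has one row per site, sorted by chromosome then position:
    ``chrom, pos, ref, alt, kind, alt_origin`` where ``kind`` is ``marker``
    (parental SNP difference; ALT is the parent-2 allele), ``uv``
    (UV-induced variant private to the mutagenized parent-1 lineage and
    absent from both sequenced parents) or ``lesion`` (the planted
    stop-gain sites).  ``alt_origin`` is the parental origin whose carriers
    contribute ALT reads: 2 for markers, 1 for novel variants.
    """

    variants: pd.DataFrame
    gene: GeneModel
    chrom_sequences: dict[str, str]
    lesions: list[tuple[str, int, str, str]]  # chrom, pos, ref, alt

    @property
    def markers(self) -> pd.DataFrame:
        return self.variants[self.variants["kind"] == "marker"].reset_index(drop=True)


_BASES = np.array(list("ACGT"))


def _poisson_positions(length_bp: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    n_expected = length_bp / spacing
    gaps = rng.exponential(spacing, size=int(n_expected * 1.5) + 20)
    pos = np.cumsum(gaps).astype(np.int64)
    pos = pos[pos < length_bp]
    while len(pos) and pos[-1] < length_bp - 3 * spacing:  # pragma: no cover
        extra = pos[-1] + np.cumsum(rng.exponential(spacing, size=20)).astype(np.int64)
        pos = np.concatenate([pos, extra[extra < length_bp]])
    return np.unique(pos)


def _shift_gene(gene: GeneModel, delta: int) -> GeneModel:
    return replace(gene, exons=tuple((s + delta, e + delta) for s, e in gene.exons))


def build_parent_genomes(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> ParentGenomes:
    """Place markers, UV variants, the suppressor gene, and planted lesions.

    Markers are Poisson-spaced at the configured density with distinct
    parental alleles.  UV variants are uniform across the genome with a
    C>T/G>A-dominated substitution spectrum; they sit on the mutagenized
    parent-1 haplotype but are absent from both *sequenced* parental
    genomes (the sequenced parent predates mutagenesis).  The suppressor
    gene is positioned so its first planted lesion coincides exactly with
    the model's suppressor locus; markers and UV variants are kept out of
    the gene span so the planted lesions are the only variants inside it.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    layout = config.layout
    suppressor = config.model.locus("suppressor")

    gene, gene_seq, gene_lesions = make_synthetic_suppressor_gene(
        config.suppressor_gene_id,
        suppressor.chromosome,
        0,
        rng,
        lesion_codons=config.lesion_codons,
    )
    delta = suppressor.position_bp - gene_lesions[0][0]
    if delta < 0 or gene.end + delta > layout.chromosome(suppressor.chromosome).length_bp:
        raise ValueError("suppressor locus too close to a chromosome edge for the gene")
    gene = _shift_gene(gene, delta)
    lesion_sites = [(p + delta, ref, alt) for p, ref, alt in gene_lesions]
    gene_span = (gene.start, gene.end)

    rows: list[dict] = []

    # dense markers distinguishing the two parents
    for c in layout.chromosomes:
        pos = _poisson_positions(c.length_bp, layout.marker_spacing_bp, rng)
        if c.name == suppressor.chromosome:
            pos = pos[(pos < gene_span[0]) | (pos >= gene_span[1])]
        if len(pos) < 2:
            import warnings

            warnings.warn(
                f"marker density too low to cover chromosome {c.name}", stacklevel=2
            )
        refs = rng.integers(0, 4, size=len(pos))
        alts = (refs + rng.integers(1, 4, size=len(pos))) % 4
        for p, r_i, a_i in zip(pos, refs, alts):
            rows.append(
                dict(chrom=c.name, pos=int(p), ref=_BASES[r_i], alt=_BASES[a_i],
                     kind="marker", alt_origin=2)
            )

    taken = {(r["chrom"], r["pos"]) for r in rows}
    taken.update((suppressor.chromosome, p) for p, _, _ in lesion_sites)

    # UV-induced variants, uniform over the genome, transition-dominated
    lengths = np.array([c.length_bp for c in layout.chromosomes], dtype=float)
    chrom_probs = lengths / lengths.sum()
    names = layout.names()
    n_placed = 0
    while n_placed < config.n_uv_mutations:
        ci = int(rng.choice(len(names), p=chrom_probs))
        chrom = names[ci]
        p = int(rng.integers(0, int(lengths[ci])))
        if (chrom, p) in taken:
            continue
        if chrom == suppressor.chromosome and gene_span[0] <= p < gene_span[1]:
            continue
        if rng.random() < config.uv_ct_ga_fraction:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        else:
            ref = str(rng.choice(list("ACGT")))
            others = [b for b in "ACGT" if b != ref]
            if ref == "C":
                others.remove("T")
            if ref == "G":
                others.remove("A")
            alt = str(rng.choice(others))
        rows.append(dict(chrom=chrom, pos=p, ref=ref, alt=alt, kind="uv", alt_origin=1))
        taken.add((chrom, p))
        n_placed += 1

    for p, ref, alt in lesion_sites:
        rows.append(
            dict(chrom=suppressor.chromosome, pos=int(p), ref=ref, alt=alt,
                 kind="lesion", alt_origin=1)
        )

    variants = pd.DataFrame(rows)
    order = {n: i for i, n in enumerate(names)}
    variants["_c"] = variants["chrom"].map(order)
    variants = variants.sort_values(["_c", "pos"]).drop(columns="_c").reset_index(drop=True)

    # reference sequence only for chromosomes carrying gene models; variant
    # REF bases are written into it so FASTA, GFF3 and VCF stay consistent
    chrom_len = layout.chromosome(suppressor.chromosome).length_bp
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_arr = base_codes[rng.integers(0, 4, size=chrom_len)]
    seq_arr[gene.start : gene.end] = np.frombuffer(gene_seq.encode(), dtype=np.uint8)
    on_gene_chrom = variants["chrom"] == suppressor.chromosome
    ref_codes = np.frombuffer(
        "".join(variants.loc[on_gene_chrom, "ref"]).encode(), dtype=np.uint8
    )
    seq_arr[variants.loc[on_gene_chrom, "pos"].to_numpy()] = ref_codes
    sequences = {suppressor.chromosome: seq_arr.tobytes().decode("ascii")}

    lesions = [(suppressor.chromosome, p, ref, alt) for p, ref, alt in lesion_sites]
    return ParentGenomes(
        variants=variants, gene=gene, chrom_sequences=sequences, lesions=lesions
    )


def simulate_progeny_population(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> list[Individual]:
    """Simulate the screened progeny population; returns survivors only.

    Each progeny is an independent gamete of the cross; its genotype is
    read off the segment mosaic at the functional loci, survival is drawn
    from the class viability, and the phenotype follows the epistasis rule.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model = config.model
    loci = model.loci
    survivors: list[Individual] = []
    for _ in range(config.n_progeny):
        ind = simulate_gamete(config.layout, rng)
        genotype = tuple(ind.origin_at(loc.chromosome, loc.position_bp) for loc in loci)
        v = model.class_viability(genotype)
        survived = bool(v >= 1.0 or rng.random() < v)
        if not survived:
            continue
        ind.genotype = genotype
        ind.phenotype = model.rule[genotype]
        survivors.append(ind)
    return survivors


def _sample(pop: Sequence[Individual], n: int, rng: np.random.Generator) -> list[Individual]:
    idx = rng.choice(len(pop), size=n, replace=False)
    return [pop[i] for i in sorted(idx)]


def construct_pools(
    individuals: Sequence[Individual],
    n_control: int,
    n_mutant: int,
    rng: np.random.Generator,
    model: PhenotypeModel,
) -> tuple[list[Individual], list[Individual]]:
    """Phenotype-sort the progeny and sample the two sequencing pools."""
    from .segregation import POOL_PHENOTYPE

    by_pool = {}
    for pool, want in (("control", n_control), ("mutant", n_mutant)):
        members = [i for i in individuals if i.phenotype == POOL_PHENOTYPE[pool]]
        if len(members) < want:
            raise ValueError(
                f"only {len(members)} {POOL_PHENOTYPE[pool]} progeny available for a "
                f"{pool} pool of {want}; increase n_progeny"
            )
        by_pool[pool] = _sample(members, want, rng)
    return by_pool["control"], by_pool["mutant"]


def construct_null_pools(
    individuals: Sequence[Individual],
    n_control: int,
    n_mutant: int,
    rng: np.random.Generator,
) -> tuple[list[Individual], list[Individual]]:
    """Pools drawn ignoring phenotype — a label-shuffled negative control."""
    if len(individuals) < n_control + n_mutant:
        raise ValueError("not enough individuals for null pools")
    idx = rng.choice(len(individuals), size=n_control + n_mutant, replace=False)
    return [individuals[i] for i in idx[:n_control]], [individuals[i] for i in idx[n_control:]]


def pool_alt_frequencies(pool: Sequence[Individual], variants: pd.DataFrame) -> np.ndarray:
    """True ALT-allele frequency of every variant within a pool.

    A pool member contributes the ALT allele at a site when its parental
    origin there equals the site's ``alt_origin``.
    """
    if not len(pool):
        raise ValueError("pool is empty")
    acc = np.zeros(len(variants), dtype=float)
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        alt_origin = grp["alt_origin"].to_numpy()
        idx = grp.index.to_numpy()
        for ind in pool:
            acc[idx] += ind.origins_at(chrom, pos) == alt_origin
    return acc / len(pool)


def simulate_pooled_counts(
    pool: Sequence[Individual],
    variants: pd.DataFrame,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled short-read counts: depth ~ Poisson, ALT reads ~ Binomial.

    Per site the read-level ALT probability is ``f (1-e) + (1-f) e`` where
    ``f`` is the true pool allele frequency and ``e`` the per-base error.
    Returns a copy of ``variants`` with ``depth`` and ``alt_count`` columns.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    f = pool_alt_frequencies(pool, variants)
    depth = rng.poisson(mean_depth, size=len(variants))
    p = f * (1 - error_rate) + (1 - f) * error_rate
    alt = rng.binomial(depth, p)
    out = variants.copy()
    out["depth"] = depth
    out["alt_count"] = alt
    return out


@dataclass
class ExperimentResult:
    """A complete simulated experiment plus its sequencing summary table.

    ``counts`` extends the variant table with per-pool ``ctrl_depth``,
    ``ctrl_alt``, ``mut_depth``, ``mut_alt`` and parental ``p1_dp``,
    ``p2_dp`` read depths.
    """

    config: CrossConfig
    parents: ParentGenomes
    progeny: list[Individual]
    control_pool: list[Individual]
    mutant_pool: list[Individual]
    counts: pd.DataFrame


def simulate_experiment(config: CrossConfig, null: bool = False) -> ExperimentResult:
    """Run the whole generator with one seeded RNG stream.

    With ``null=True`` the pools are drawn ignoring phenotype, removing any
    linkage signal — the negative control used to calibrate the scan.
    """
    rng = np.random.default_rng(config.seed)
    parents = build_parent_genomes(config, rng)
    progeny = simulate_progeny_population(config, rng)
    if null:
        ctrl, mut = construct_null_pools(progeny, config.n_control, config.n_mutant, rng)
    else:
        ctrl, mut = construct_pools(
            progeny, config.n_control, config.n_mutant, rng, config.model
        )
    ctrl_counts = simulate_pooled_counts(
        ctrl, parents.variants, config.mean_depth, config.error_rate, rng
    )
    mut_counts = simulate_pooled_counts(
        mut, parents.variants, config.mean_depth, config.error_rate, rng
    )
    counts = parents.variants.copy()
    counts["ctrl_depth"] = ctrl_counts["depth"]
    counts["ctrl_alt"] = ctrl_counts["alt_count"]
    counts["mut_depth"] = mut_counts["depth"]
    counts["mut_alt"] = mut_counts["alt_count"]
    counts["p1_dp"] = rng.poisson(config.mean_depth, size=len(counts))
    counts["p2_dp"] = rng.poisson(config.mean_depth, size=len(counts))
    return ExperimentResult(
        config=config,
        parents=parents,
        progeny=progeny,
        control_pool=ctrl,
        mutant_pool=mut,
        counts=counts,
    )


def _vcf_header(config: CrossConfig) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in config.layout.chromosomes:
        header.contigs.add(c.name, length=c.length_bp)
    header.add_meta("source", value="bsamap-simulate")
    header.add_meta("bsamap_seed", value=str(config.seed))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in VCF_SAMPLES:
        header.add_sample(s)
    return header


def emit_vcf(result: ExperimentResult, path: str | Path) -> None:
    """Write the four-sample VCF (parents with haploid calls, pools with AD).

    Marker sites carry PARENT1=ref / PARENT2=alt haploid genotypes; novel
    sites (UV variants and the planted lesions) are homozygous reference in
    both sequenced parents by construction.  Pool samples carry no genotype
    call, only DP and AD.  Records are emitted sorted; the seed is recorded
    in the header.
    """
    counts = result.counts
    chrom_order = {n: i for i, n in enumerate(result.config.layout.names())}
    key = counts["chrom"].map(chrom_order).to_numpy()
    pos = counts["pos"].to_numpy()
    dk, dp = np.diff(key), np.diff(pos)
    if not np.all((dk > 0) | ((dk == 0) & (dp > 0))):
        raise ValueError("variant records are not sorted")
    header = _vcf_header(result.config)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in counts.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos),
                alleles=(row.ref, row.alt),
                qual=None,
            )
            is_marker = row.kind == "marker"
            rec.samples["PARENT1"]["GT"] = (0,)
            rec.samples["PARENT2"]["GT"] = (1,) if is_marker else (0,)
            rec.samples["PARENT1"]["DP"] = int(row.p1_dp)
            rec.samples["PARENT2"]["DP"] = int(row.p2_dp)
            rec.samples["PARENT1"]["AD"] = (int(row.p1_dp), 0)
            rec.samples["PARENT2"]["AD"] = (
                (0, int(row.p2_dp)) if is_marker else (int(row.p2_dp), 0)
            )
            for sample, d, a in (
                ("POOL_CTRL", row.ctrl_depth, row.ctrl_alt),
                ("POOL_MUT", row.mut_depth, row.mut_alt),
            ):
                rec.samples[sample]["GT"] = (None,)
                rec.samples[sample]["DP"] = int(d)
                rec.samples[sample]["AD"] = (int(d) - int(a), int(a))
            vcf.write(rec)


def emit_fasta(parents: ParentGenomes, path: str | Path) -> None:
    """Write the reference sequence of gene-bearing chromosomes."""
    with open(path, "w") as fh:
        for chrom, seq in parents.chrom_sequences.items():
            fh.write(f">{chrom}\n")
            for line in textwrap.wrap(seq, 60):
                fh.write(line + "\n")


def emit_gff3(parents: ParentGenomes, path: str | Path) -> None:
    write_gff3([parents.gene], path)
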