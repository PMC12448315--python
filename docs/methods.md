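# Methods

## The genetic model

`bsamap` models the mapping arm of a haploid suppressor screen. A
mutagenized line (parent 1) carries a selection-locus disruption (*NOG1*)
plus an unknown second-site suppressor lesion (*SNOG1A*); it is crossed to
a wild-type donor (parent 2, the Reute background). Because the progeny
are haploid, the genotype at any locus is simply the parent of origin of
that chromosomal segment, and with `k` functional loci on distinct
chromosomes the progeny fall into `2^k` equiprobable classes.

The epistasis rule: a progeny individual shows the original non-suppressed
(2D-restricted) phenotype only when it inherits the selection mutation
*without* the suppressor lesion. With two loci that is one class of four,
so a quarter of viable progeny are non-suppressed. An optional relative
viability `v ∈ (0, 1]` on every class carrying the selection mutation
(modelling impaired spore germination of the disruptant) distorts the
ratio to

    f_non-suppressed = v / (2 + 2v),

which `infer_viability` inverts as `v = 2f / (1 − 2f)`. The inversion is
undefined at `f ≥ 0.5` (no positive viability reaches it) and is allowed
to return `v > 1` for `f ∈ (0.25, 0.5)`, leaving the interpretation to the
caller.

Conditioning the class probabilities on pool membership (control =
non-suppressed, mutant = suppressed progeny) gives the expected parent-2
allele frequency at a marker at recombination fraction `r` from a locus:

    f(r) = f0 · (1 − r) + (1 − f0) · r,

where `f0` is the conditional parent-2 frequency at the locus itself. For
the canonical rule at full viability: control pool 1 and mutant pool 1/3
at the suppressor locus, 0 and 2/3 at the selection locus, and 1/2 at any
unlinked marker (`r = 0.5`). These closed forms are checked against a
brute-force enumeration over (class × recombinant/non-recombinant marker
state) to 1e-12 in the test suite.

## The synthetic experiment

The generator reproduces the statistical structure the analysis assumes,
at a deliberately scaled-down genome so a full experiment runs in about a
second:

| parameter | default | why |
|---|---|---|
| chromosomes | 27 × 5 Mb, 100 cM each | 27 chromosomes match the assembly the screen was plotted on; physical size scaled down from ~470 Mb for desk-scale runtime |
| marker spacing | mean 25 kb (Poisson) | ~5,400 informative SNPs genome-wide, dense enough for 51-marker windows at ~1.3 Mb |
| UV mutations | 150, 80 % C>T/G>A | UV signature; transition-dominated spectrum |
| planted lesions | two C>T stop-gains, codons 335 and 374, third exon of one gene | the causative-lesion configuration the filter must recover |
| progeny screened | 1,000 | comfortably supports 80 + 98 pools at the ¼ : ¾ split |
| pools | control 80, mutant 98 | the screen's stated pool sizes |
| depth | Poisson, mean 44× per pool | the stated coverage; read "44×" as per-pool |
| error rate | 1e-3 per base | typical short-read substitution error |

Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson(map length in Morgans), breakpoints are uniform in map distance
(mapped linearly to bp), the starting parental origin is Bernoulli(1/2),
and there is no crossover interference. Recombinant fractions between
marker pairs therefore follow the Haldane transform `r = (1 − e^(−2d))/2`,
which the tests verify at 10,000 gametes.

UV variants sit on the mutagenized parent-1 haplotype but are absent from
both *sequenced* parental genomes — the sequenced parent predates
mutagenesis — so they surface as "novel" variants whose pool frequencies
track parent-1 ancestry at their position: ≈0.5/0.5 when unlinked, 2/3
mutant / 0 control for the suppressor lesion itself. The suppressor gene
is placed so its first lesion coincides exactly with the model's
suppressor locus, and markers/UV variants are kept out of the gene span so
the emitted FASTA, GFF3 and VCF stay mutually consistent.

Pooled counts are generated per site as depth ~ Poisson(λ) and ALT reads
~ Binomial(depth, f(1−ε) + (1−f)ε) with `f` the true pool frequency. Pool
members are sampled within phenotype independently of the screen-wide
phenotype fraction (the screen sorted individuals after phenotyping; pool
sizes are not a ratio estimate).

What the generator does **not** emulate: read-level artefacts (mapping
bias, indel realignment, duplicate reads), variant-caller genotype error
in the parents, segregation distortion other than the single viability
multiplier, crossover interference, and structural variation. Passing
tests therefore demonstrate correctness of the inference given
binomial-sampling pooled data, not robustness to alignment artefacts.

## The genome scan

Markers are sites where the two parental haploid calls differ confidently
(call present, depth ≥ 10). Raw tracks are the per-marker parent-2 read
fraction per pool; markers below a per-pool depth floor of 10 are flagged
excluded, never silently dropped. Visual smoothing uses a centred rolling
median over 51 included markers (robust to single-marker noise);
truncated at chromosome edges.

The scan statistic is a binomial log-likelihood ratio summed over a
sliding 51-marker window and both pools:

    S(w) = Σ_i [ log B(c_i; d_i, f_linked) − log B(c_i; d_i, 0.5) ],

with expected linked frequencies taken from the segregation model at
`r = 0` (control 1 → clipped to 0.99, mutant 1/3; the clip bound ε_f =
0.01 keeps the likelihood finite when a stray read contradicts a frequency
of exactly 1). The LLR weighs markers by depth automatically.

Region calling threshold: 200 within-run permutations that swap the two
pools' counts independently per marker, genome-wide maximum window score,
95th percentile (conservative `higher` interpolation). Because the
per-marker swap destroys the linkage-induced autocorrelation between
neighbouring markers, its null maxima can sit below the observed null
maxima; calling therefore additionally requires positive evidence — the
effective threshold is `max(permutation quantile, 0)`, i.e. a called
window must favour the linked model over the unlinked null outright.
Runs of contiguous above-threshold windows are merged into half-open
regions, reported best-first (peak score, then span, then coordinate).

A separate diagnostic checks the selection locus: local mean pool
frequencies within ±50 kb must sit within 0.15 of the model's expectations
(control ≈ 0, mutant ≈ 2/3). The 0.15 tolerance absorbs the
pool-composition noise of an 80–98-member pool (SD ≈ 0.05) on top of read
sampling.

## Candidate filtering

Novel variants are sites where both parents are confidently homozygous
reference (call 0, depth ≥ 10, zero ALT reads) and the mutant pool has at
least 3 ALT reads (suppressing ε-rate error at 44×). Within the called
region, pooled frequencies must match the lesion expectation — mutant 2/3,
control 0 at full viability — within `max(0.1, 3 × binomial SE at the
observed depth)`; the fixed 0.1 floor is this package's choice where no
published threshold exists. Effects are annotated against GFF3 gene
models (genomic↔CDS mapping honours strand and introns; codon indices are
1-based from the start codon, Gln335Ter-style), and candidates are ranked
by effect severity (stop_gained > splice_adjacent > missense > synonymous
> noncoding), then frequency fit, then coordinate. An optional UV-spectrum
prior (keep only C>T/G>A) is deliberately off by default: it is a prior,
not an observed filtering step.

## Numerical and design choices

- Coordinates are 0-based half-open internally; VCF and GFF3 emission use
  their native 1-based conventions; BED output is 0-based half-open.
- One seeded `numpy` Generator per simulated experiment; the seed is
  recorded in the VCF header and the JSON run summary, and identical seed
  + config reruns are byte-identical (no timestamps in any output).
- The scan is invariant to input row order: markers are canonically
  sorted before scoring and the permutation stream is tied to that order.
- Degenerate inputs fail loudly: identical parents (no markers), pools
  larger than the available phenotype class, unsorted VCFs, incomplete
  phenotype rules (the missing combination is named), non-suppressed
  fractions ≥ 0.5.
- The acceptance script averages the design-point mutant-pool frequency
  over 25 replicate crosses: a single 98-member pool has composition SD
  ≈ 0.048 around 1/3, and the replicate mean estimates the same quantity
  with SD ≈ 0.01.

## Known limitations

- The viability model is a single multiplier shared by all
  selection-mutant classes; locus-specific or environment-dependent
  viability is out of scope.
- The simulator starts at variant counts; FASTQ-level simulation, read
  mapping and variant calling are out of scope, as are diploid genetics,
  dominance, selfing designs and multi-generation pedigrees.
- The per-marker permutation null is anticonservative under linkage (see
  above); the positive-evidence floor compensates, but the permutation
  quantile alone should not be interpreted as a calibrated genome-wide
  p-value for arbitrary statistics.
- Nonsense-associated altered splicing and transcript-level validation of
  candidates are not modelled.
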