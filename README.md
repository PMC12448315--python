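# bsamap

Bulk segregant analysis (BSA-seq) for **haploid suppressor screens**: an
exact segregation model for a two-locus epistatic cross, a synthetic
cross + pooled-sequencing generator, a genome-wide pooled
allele-frequency scan, and a causative-variant candidate filter.

## The problem

A suppressor screen mutagenizes a mutant (here a moss line whose *NOG1*
disruption blocks the 2D→3D growth transition) and recovers individuals
whose second-site mutation restores the wild-type-like phenotype. Mapping
that suppressor by BSA-seq means crossing the suppressed mutant to a
divergent wild-type donor, sorting the haploid progeny by phenotype into a
**control pool** (non-suppressed, original-mutant-like) and a **mutant
pool** (suppressed, 3D-capable), sequencing both pools alongside the
parents, and scanning for genomic regions where the pools' parental
allele frequencies depart from the unlinked expectation of 0.5.

Because the progeny are haploid, the genetics is exact. With the
selection locus and the suppressor locus on different chromosomes, the
four progeny classes are equiprobable and only the class carrying the
selection mutation with the wild-type suppressor allele is
non-suppressed, so:

- ¼ of viable progeny show the original mutant phenotype (with reduced
  viability *v* of selection-mutant classes: *v*/(2+2*v*));
- at a marker at recombination fraction *r* from a pool-defining locus
  the expected donor-allele frequency is *f*(*r*) = *f*₀(1−*r*) + (1−*f*₀)*r*,
  giving **1** (control) and **⅓** (mutant) at the suppressor locus,
  **0** and **⅔** at the selection locus, and **½** anywhere unlinked.

The scan statistic is a depth-weighted binomial log-likelihood ratio per
sliding marker window, Σᵢ [log B(cᵢ; dᵢ, f_linked) − log B(cᵢ; dᵢ, ½)],
thresholded by within-run permutation; candidates inside the called
region must be novel (absent from both parents), match the lesion's
expected pool frequencies (⅔ / 0), and are ranked by coding-effect
severity after annotation against gene models. See `docs/methods.md`.

## Worked example

```bash
python examples/04_candidate_variants.py
```

simulates the default experiment (27 chromosomes, pools of 80 and 98
individuals, 44× mean depth, seed 11), scans it and ranks candidates:

```
novel (non-parental) variants genome-wide: 152
candidates inside the called region passing the frequency filter: 4

rank  position          change      effect       ctrl  mut   gene
   1  Chr08:2500118    C>T Gln374Ter  stop_gained  0.00  0.66  SyntheticSuppressorGene
   2  Chr08:2500001    C>T Gln335Ter  stop_gained  0.00  0.69  SyntheticSuppressorGene
   3  Chr08:2988797    T>C -          noncoding    0.09  0.61  -
   4  Chr08:2048426    G>C -          noncoding    0.03  0.53  -
```

The two planted C>T stop-gains top the ranking: both sit in one gene in
the called region, are absent from the control pool and near the expected
⅔ frequency in the mutant pool, and truncate the protein at glutamine
codons (Gln→Ter). The other examples show the analytic class table
(`01`), the raw simulated experiment (`02`) and the genome scan with its
selection-locus diagnostic (`03`).

The same stages are available as a thin CLI:

```bash
bsamap expected                      # class table + expected pool frequencies
bsamap simulate --out sim/ --seed 11 # VCF + GFF3 + FASTA
bsamap scan --vcf sim/simulated.vcf --out scan/ --seed 11
bsamap candidates --vcf sim/simulated.vcf --regions scan/regions.bed \
    --gff sim/genes.gff3 --fasta sim/genome.fa --out cand/
bsamap run-all --out run/ --seed 11  # all of the above, deterministic
```

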