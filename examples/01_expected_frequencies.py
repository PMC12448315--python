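"""Exact segregation expectations for the haploid suppressor-screen cross.

Enumerates the four progeny classes of the two-locus cross, then prints
the expected phenotype fractions and the pooled allele frequencies a
bulk-segregant experiment should observe. The 0.25 non-suppressed
fraction and the 1 / 0.33 suppressor-locus pool frequencies are computed
from the rule, never hard-coded.
"""

from bsamap import (
    enumerate_progeny_classes,
    expected_phenotype_fraction,
    expected_pool_allele_frequency,
    infer_viability,
    suppressor_screen_model,
)

model = suppressor_screen_model()

print("Progeny classes (haploid two-locus cross):")
print(enumerate_progeny_classes(model).to_string(index=False))

frac = expected_phenotype_fraction(model, "non_suppressed")
print(f"\nExpected non-suppressed progeny fraction: {frac}")

print("\nExpected parent-2 (wild-type donor) allele frequency by pool:")
for locus in model.loci:
    for pool in ("control", "mutant"):
        f0 = expected_pool_allele_frequency(model, pool, locus, 0.0).frequency
        f5 = expected_pool_allele_frequency(model, pool, locus, 0.5).frequency
        print(f"  {locus.name:7s} {pool:7s}  r=0: {f0:.2f}   unlinked: {f5:.2f}")

# an observed deficit of non-suppressed progeny implies reduced viability
# of the selection-mutant classes
for observed in (0.25, 1 / 6):
    print(f"\nObserved non-suppressed fraction {observed:.3f} "
          f"-> inferred selection-class viability {infer_viability(observed):.2f}")
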