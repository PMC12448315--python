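"""Simulate the full synthetic experiment and look at its raw material.

Generates parental genomes (markers + UV variants + two planted stop-gain
lesions), 1,000 recombinant haploid progeny, phenotype-sorted pools of 80
and 98, and pooled read counts at mean depth 44x, then summarizes what a
sequencing experiment would see at the causative locus.
"""

from bsamap import default_cross_config, simulate_experiment

config = default_cross_config(seed=11)
result = simulate_experiment(config)

counts = result.counts
print(f"progeny surviving: {len(result.progeny)}")
print(f"pool sizes: control {len(result.control_pool)}, mutant {len(result.mutant_pool)}")
print("variant sites by kind:", counts["kind"].value_counts().to_dict())

non_sup = sum(i.phenotype == "non_suppressed" for i in result.progeny)
print(f"non-suppressed fraction in the screen: {non_sup / len(result.progeny):.3f} "
      "(expected 0.25)")

print("\nPlanted lesions as the pools see them:")
lesions = counts[counts["kind"] == "lesion"]
for row in lesions.itertuples():
    print(f"  {row.chrom}:{row.pos + 1} {row.ref}>{row.alt}  "
          f"control {row.ctrl_alt}/{row.ctrl_depth} reads, "
          f"mutant {row.mut_alt}/{row.mut_depth} reads "
          f"(freq {row.mut_alt / row.mut_depth:.2f}, expected 0.67)")
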