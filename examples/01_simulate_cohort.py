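"""Simulate a closed-breed cohort with a recent causal variant on an old risk haplotype.

The generator plants four old "decoy" variants on every copy of a ~7 Mb
risk haplotype and the causal allele on only 60% of those copies, so some
unaffected dogs are homozygous for the haplotype (and its decoys) without
being homozygous for the causal variant — the confound the discovery
pipeline has to survive.
"""

from homrec import SimulationConfig, simulate_breed_population

gm, variants, samples, pedigree, truth = simulate_breed_population(SimulationConfig(seed=1))

print(f"cohort: {samples['status'].value_counts().to_dict()}")
print(f"genotype matrix: {gm.n_samples} samples x {gm.n_markers} markers")
print(f"candidate variants: {variants.n_variants} "
      f"({len(truth.decoy_positions_bp)} decoys + 1 causal + background)")
print(f"causal variant: chr{truth.causal_chrom}:{truth.causal_position_bp}")
print(f"risk interval: {truth.risk_interval_bp[0]:,}-{truth.risk_interval_bp[1]:,} bp")

carrier = samples.loc[samples["obligate_carrier"], "sample_id"].iloc[0]
print(f"obligate carrier {carrier}: "
      f"{truth.risk_copies[carrier]} risk-haplotype copies, "
      f"{truth.causal_copies[carrier]} causal copies (heterozygous, as a case's parent must be)")

discordant = [
    s for s in samples.loc[samples["status"] == "control", "sample_id"]
    if truth.risk_copies[s] == 2 and truth.causal_copies[s] == 0
]
print(f"{len(discordant)} control(s) homozygous for the risk haplotype but free of the causal allele")
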