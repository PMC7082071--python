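"""Case/control association scan with QC, permutation and genomic control.

Markers pass call-rate, minor-allele-frequency and Hardy-Weinberg filters,
then each is tested with the 2x2 allelic chi-square (1 df).  Max-T
permutation gives genome-wide empirical p-values, and lambda summarises
inflation (1.0 means no stratification).
"""

from homrec import SimulationConfig, simulate_breed_population
from homrec.gwas import association_scan, permutation_empirical, qc_filter

gm, _, samples, _, truth = simulate_breed_population(SimulationConfig(seed=1))

gm_qc, qc = qc_filter(gm, samples)
print(f"QC: {qc.n_input} markers in, {qc.n_retained} retained "
      f"(call-rate {qc.removed_call_rate}, MAF {qc.removed_maf}, HWE {qc.removed_hwe} removed)")

assoc = association_scan(gm_qc, samples, case_statuses={"case_type1"})
perm = permutation_empirical(gm_qc, samples, case_statuses={"case_type1"}, n_perm=2000, seed=1)
table = assoc.table.merge(perm, on="marker_id")

top = table.loc[table["chi2"].idxmax()]
lo, hi = truth.risk_interval_bp
print(f"lambda_gc = {assoc.lambda_gc:.3f}")
print(f"top marker {top['marker_id']} at chr{top['chromosome']}:{top['position_bp']:,} "
      f"chi2={top['chi2']:.1f} p_raw={top['p_raw']:.2e} p_genome={top['p_genome']:.4f}")
print(f"inside the planted risk interval: {lo <= top['position_bp'] <= hi}")
# p_genome is the fraction of label permutations whose best genome-wide
# statistic beats this marker -- the multiple-testing-robust significance.
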