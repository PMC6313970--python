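"""Simulate a small matched tumor/xenograft cohort and inspect its truth.

Builds two cases with the default clonal architecture (one truncal clone,
two subclones, planted germline variants and a mouse-homology artifact
region), then prints what the simulator guarantees: read-compartment
composition per sample and expected allele fractions per stage.
"""

from xenovar import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_cases=2, depth=120.0), seed=7)

print(f"panel: {cohort.panel.gene_count} genes, {cohort.panel.assayed_mb*1000:.1f} kb assayed")
print(f"drivers: {sorted(cohort.driver_genes)}")
print(f"mouse-homology artifact alleles planted: {len(cohort.artifact_keys)}\n")

for sample_id in cohort.sample_ids:
    truth = cohort.truths[sample_id]
    counts = truth.origin_counts()
    total = sum(counts.values())
    mix = ", ".join(f"{k} {100*v/total:.1f}%" for k, v in counts.items() if v)
    print(f"{sample_id:12s} {total:6d} reads: {mix}")

case = cohort.cases[0]
print(f"\nexpected allele fractions, {case.case_id} (primary -> P2):")
for v in case.model.variants:
    af_p = case.model.expected_af(v.variant_id, "primary")
    af_x = case.model.expected_af(v.variant_id, "P2")
    tag = "germline" if v.germline else ("truncal" if len(case.model.carriers(v.variant_id)) == 3 else "subclonal")
    print(f"  {v.variant_id:18s} {v.vtype:5s} {tag:9s} {af_p:.3f} -> {af_x:.3f}")

print("\nExpected AF = purity x carrying-clone fraction x 0.5 (heterozygous);")
print("the xenograft values reflect the engraftment bottleneck and higher purity.")
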