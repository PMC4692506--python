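"""Single-locus screening: Hardy-Weinberg and case-control chi-square.

Runs on the margin-exact synthetic reconstruction of the motivating
ischemic-stroke study (712 cases / 774 controls), so the single-locus
numbers equal what the published genotype counts give.
"""

import epimdr as em

cohort = em.reconstructed_cohort(seed=0)
controls = cohort.subset(cohort.phenotype == 0)
threshold = em.bonferroni_threshold(0.05, len(cohort.loci))

print(f"Bonferroni-corrected significance level: {threshold:.4f}\n")
print(f"{'locus':<12} {'HWE p (controls)':>17} {'case-control p':>15}  significant")
for locus in cohort.loci:
    hwe = em.hwe_chisq(em.genotype_table(controls, locus.name).counts[:, 0], locus)
    assoc = em.chisq_independence(em.genotype_table(cohort, locus.name))
    print(f"{locus.name:<12} {hwe.p_value:>17.3f} {assoc.p_value:>15.3f}  "
          f"{assoc.p_value < threshold}")

print("\nAll loci are consistent with Hardy-Weinberg in controls; no single")
print("locus survives the Bonferroni correction: the nominal signals at")
print("ACE (p~0.024) and FGB T148C (p~0.026) are too weak on their own.")
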