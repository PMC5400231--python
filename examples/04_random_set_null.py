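"""The random-gene-set empirical null in isolation.

How specific is an observed gene-set burden p-value? Draw many random sets
of the same size from an eligibility pool (genes with a sufficiently
specific GO annotation, outside the hypothesis sets) and ask what fraction
of their p-values beats the observed one.
"""

from rvburden.filters import apply_filters
from rvburden.genesets import NullSamplerConfig, eligible_pool, sample_random_sets
from rvburden.simulate import SimulationConfig, simulate_cohort
from rvburden.stats import (
    burden_counts,
    empirical_specificity,
    gene_count_table,
    null_p_distribution,
    welch_one_sided,
)

bundle = simulate_cohort(
    SimulationConfig(seed=1, n_genes=1200, n_ranked=500, target_set_size=200)
)
kept, _ = apply_filters(bundle.records, bundle.subjects)

counts = burden_counts(kept, bundle.target_set, "damaging_missense", subjects=bundle.subjects)
observed = welch_one_sided(
    [counts[s] for s in bundle.case_ids],
    [counts[s] for s in bundle.control_ids],
    direction="observed",
)

cfg = NullSamplerConfig(n_sets=400, set_size=len(bundle.target_set), seed=1)
pool = eligible_pool(bundle.gene_go, excluded=[bundle.target_set], cfg=cfg)
random_sets = sample_random_sets(pool, cfg)

table = gene_count_table(kept, bundle.subjects, "damaging_missense")
null_ps = null_p_distribution(table, random_sets, bundle.case_ids, bundle.control_ids)
specificity, null_ps = empirical_specificity(observed.p_one_sided, null_ps)

print(f"observed target-set p: {observed.p_one_sided:.4f}")
print(f"eligible pool: {len(pool)} genes; random sets drawn: {len(null_ps)}")
print(f"fraction of random-set p-values below observed: {specificity:.3f}")
print()
print(
    "Reading: a small fraction (< 0.05) says the signal is specific to the\n"
    "target set rather than an artifact of set size or cohort structure."
)
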