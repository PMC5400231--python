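"""Generate a synthetic cohort and run the full pipeline on its files.

The generator emits every input format the pipeline reads (VCF + annotation
sidecar, sample sheet, GMT, ranked list, GO table, GWAS table, genotypes);
the pipeline filters, classifies, burden-tests, draws a random-gene-set
empirical null, and scores the polygenic model.
"""

import tempfile

from rvburden.pipeline import run_pipeline
from rvburden.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(
    seed=7, n_genes=1000, n_ranked=400, target_set_size=150, n_gwas_snps=150
)
bundle = simulate_cohort(cfg)

with tempfile.TemporaryDirectory() as tmp:
    paths = bundle.write(f"{tmp}/bundle")
    result = run_pipeline(
        {
            "inputs": paths,
            "analysis": {"top_k": [150], "direction": "observed"},
            "null_sampler": {"enabled": True, "n_sets": 300, "set_size": 150, "seed": 7},
            "prs": {"enabled": True},
            "seed": 7,
            "output_dir": f"{tmp}/out",
        }
    )

print(result.results.round(4).to_string(index=False))
print(f"\nempirical specificity of the target set: {result.specificity:.3f}")
print(f"filter ledger: {result.manifest['filter_ledger']}")
print()
print(
    "Reading: the simulated enrichment (case mean ~10 vs control ~4.8 in the\n"
    "target set) is recovered by the top-150 damaging-missense test, and few\n"
    "random gene-sets of the same size beat its p-value (the specificity)."
)
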