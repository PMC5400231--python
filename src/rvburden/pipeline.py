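"""End-to-end orchestration: filter -> classify -> burden -> null -> PRS.

`run_pipeline` drives the full analysis from a config mapping (YAML-able)
referencing input files on disk, and writes result tables plus a run
manifest that fully determines a rerun (config snapshot, seeds, input
checksums, per-stage filter ledger, package version).

`reference_analysis` recomputes, from the bundled cohort tables alone, the
desk-scale statistics of the reference study: the five gene-set burden
tests with BH-FDR and a Wilcoxon check, the negative-control phenotype
tests, and the higher-stringency (top-500) case burden.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__, fixtures
from . import io as rvio
from .classify import ClassifierThresholds
from .filters import RarityPolicy, RegionPolicy, apply_filters
from .genesets import NullSamplerConfig, eligible_pool, sample_random_sets, top_k
from .prs import PrsConfig, compare_prs, score_cohort
from .stats import (
    DegenerateStatisticsError,
    BurdenTestResult,
    attach_bh,
    burden_counts,
    empirical_specificity,
    gene_count_table,
    null_p_distribution,
    welch_one_sided,
    wilcoxon_one_sided,
)
from .types import GeneSet, Group

VARIANT_CLASSES = ("LOF", "damaging_missense")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    results: pd.DataFrame
    manifest: dict
    null_ps: Optional[np.ndarray] = None
    specificity: Optional[float] = None
    prs: Optional[pd.DataFrame] = None


def _test_row(
    counts: dict[str, int],
    case_ids: list[str],
    control_ids: list[str],
    set_name: str,
    variant_class: str,
    direction: str,
) -> dict[str, Any]:
    x = [counts[s] for s in case_ids]
    y = [counts[s] for s in control_ids]
    row: dict[str, Any] = {
        "set_name": set_name,
        "variant_class": variant_class,
        "direction": direction,
        "n_case": len(x),
        "n_control": len(y),
        "mean_case": float(np.mean(x)),
        "sd_case": float(np.std(x, ddof=1)),
        "mean_control": float(np.mean(y)),
        "sd_control": float(np.std(y, ddof=1)),
    }
    try:
        res = welch_one_sided(x, y, direction=direction)
        row.update(t=res.t, df=res.df, p_one_sided=res.p_one_sided, method="welch")
        row["wilcoxon_p"] = wilcoxon_one_sided(x, y, direction=direction)
    except DegenerateStatisticsError:
        row.update(t=np.nan, df=np.nan, p_one_sided=np.nan, wilcoxon_p=np.nan,
                   method="degenerate")
    return row


def run_pipeline(config: dict) -> RunResult:
    """Run the full analysis described by ``config`` and write outputs.

    Deterministic given the config's seeds and inputs; rerunning with the
    same manifest reproduces the result tables byte for byte.
    """
    inputs = config["inputs"]
    outdir = Path(config.get("output_dir", "rvburden_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    direction = config.get("analysis", {}).get("direction", "observed")

    rarity_cfg = config.get("rarity", {})
    rarity = RarityPolicy(
        threshold=float(rarity_cfg.get("threshold", 0.01)),
        missing_is_rare=bool(rarity_cfg.get("missing_is_rare", True)),
    )
    region_cfg = config.get("region", {})
    region = RegionPolicy(
        autosomes_only=bool(region_cfg.get("autosomes_only", True)),
        breakpoint_window=int(region_cfg.get("breakpoint_window_bp", 4_000_000)),
    )
    cls_cfg = config.get("classifier", {})
    thresholds = ClassifierThresholds(
        criteria_required=int(cls_cfg.get("criteria_required", 4))
    )
    missing_policy = cls_cfg.get("missing_policy", "unmet")

    subjects = rvio.read_sample_sheet(inputs["sample_sheet"])
    case_ids = [s.subject_id for s in subjects if s.group is Group.CASE]
    control_ids = [s.subject_id for s in subjects if s.group is Group.CONTROL]
    records = rvio.read_variant_calls(inputs["vcf"], inputs["annotations"])
    kept, ledger = apply_filters(records, subjects, rarity, region)

    gene_sets: list[GeneSet] = []
    if inputs.get("gene_sets"):
        gene_sets.extend(rvio.read_gene_sets(inputs["gene_sets"]))
    ranked = rvio.read_ranked_list(inputs["ranked_list"]) if inputs.get("ranked_list") else None
    top_sets: list[GeneSet] = []
    if ranked is not None:
        for k in config.get("analysis", {}).get("top_k", [1000]):
            top_sets.append(top_k(ranked, int(k), exclusions=gene_sets))

    # genome-wide pseudo-set: every annotated gene
    all_genes = GeneSet(name="genome_wide", genes=frozenset(a.gene for _, a in kept))

    rows = []
    tested_sets = [all_genes, *gene_sets, *top_sets]
    for gs in tested_sets:
        for vc in VARIANT_CLASSES:
            counts = burden_counts(
                kept, gs, vc, subjects=subjects,
                thresholds=thresholds, missing_policy=missing_policy,
            )
            rows.append(_test_row(counts, case_ids, control_ids, gs.name, vc, direction))
    results = pd.DataFrame(rows)
    valid = results["p_one_sided"].notna()
    if valid.any():
        from .stats import bh_fdr

        q = pd.Series(np.nan, index=results.index)
        q[valid] = bh_fdr(results.loc[valid, "p_one_sided"].tolist())
        results["q_bh"] = q
    else:
        results["q_bh"] = np.nan

    # random gene-set empirical null for the first ranked target set
    null_ps = None
    specificity = None
    null_cfg = config.get("null_sampler", {})
    if null_cfg.get("enabled", False) and top_sets and inputs.get("gene_go"):
        gene_go = rvio.read_gene_go_table(inputs["gene_go"])
        ns = NullSamplerConfig(
            n_sets=int(null_cfg.get("n_sets", 10_000)),
            set_size=int(null_cfg.get("set_size", len(top_sets[0]))),
            go_term_max_size=int(null_cfg.get("go_term_max_size", 500)),
            seed=int(null_cfg.get("seed", seed)),
        )
        pool = eligible_pool(gene_go, excluded=[*gene_sets, *top_sets], cfg=ns)
        random_sets = sample_random_sets(pool, ns)
        table = gene_count_table(
            kept, subjects, "damaging_missense",
            thresholds=thresholds, missing_policy=missing_policy,
        )
        null_ps = null_p_distribution(table, random_sets, case_ids, control_ids, direction)
        mask = (results["set_name"] == top_sets[0].name) & (
            results["variant_class"] == "damaging_missense"
        )
        observed = results.loc[mask, "p_one_sided"].iloc[0]
        specificity, null_ps = empirical_specificity(float(observed), null_ps)
        pd.DataFrame({"null_p": null_ps}).to_csv(
            outdir / "null_p_distribution.tsv", sep="\t", index=False
        )

    # polygenic risk score
    prs_df = None
    prs_cfg = config.get("prs", {})
    if prs_cfg.get("enabled", False) and inputs.get("gwas") and inputs.get("genotypes"):
        gwas = rvio.read_gwas_table(inputs["gwas"])
        genotypes = rvio.read_genotype_table(inputs["genotypes"])
        pconf = PrsConfig(
            p_thresholds=tuple(float(t) for t in prs_cfg.get("thresholds", (1e-3, 1e-5, 1e-7)))
        )
        prs_results, match_summary = score_cohort(genotypes, gwas, pconf)
        prs_df = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "threshold": r.threshold,
                    "n_snps_used": r.n_snps_used,
                    "score": r.score,
                }
                for r in prs_results
            ]
        )
        prs_df.to_csv(outdir / "prs_scores.tsv", sep="\t", index=False)
    else:
        match_summary = None

    results.to_csv(outdir / "burden_results.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_checksums": {
            name: _sha256(path) for name, path in inputs.items() if path
        },
        "filter_ledger": ledger.as_dict(),
        "n_subjects": len(subjects),
        "n_tests": int(valid.sum()),
        "specificity": specificity,
        "prs_match": None
        if match_summary is None
        else {
            "n_input": match_summary.n_input,
            "n_matched": match_summary.n_matched,
            "n_missing_genotype": match_summary.n_missing_genotype,
            "n_incompatible_alleles": match_summary.n_incompatible_alleles,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return RunResult(
        results=results,
        manifest=manifest,
        null_ps=null_ps,
        specificity=specificity,
        prs=prs_df,
    )


# ---------------------------------------------------------------------------
# Desk-scale recomputation from the bundled cohort tables
# ---------------------------------------------------------------------------

def reference_analysis() -> dict[str, Any]:
    """Recompute the reference cohort's headline statistics from fixtures.

    Returns a dict with:

    ``burden`` — DataFrame of the five defined gene-set x class tests
    (one-sided Welch on the observed tail, BH q across the family, exact
    Wilcoxon check);
    ``negative_controls`` — phenotype-swap p-values (schizophrenia with the
    fixed case-greater tail, seizure with the observed tail);
    ``top500`` — case counts and group mean at the higher-stringency
    (rank <= 500) truncation, derived from the case variant list;
    ``total_adjusted_p`` — the top-1000 missense test adjusted for each
    subject's genome-wide damaging-missense total.
    """
    rows = []
    tests = [
        ("genome_wide", "LOF"),
        ("genome_wide", "damaging_missense"),
        ("deletion_region_22q11", "damaging_missense"),
        ("top_1000", "LOF"),
        ("top_1000", "damaging_missense"),
    ]
    results: list[BurdenTestResult] = []
    for set_name, vc in tests:
        x = fixtures.case_counts(set_name, vc)
        y = fixtures.control_counts(set_name, vc)
        res = welch_one_sided(x, y, direction="observed", set_name=set_name, variant_class=vc)
        results.append(res)
        rows.append(
            {
                "set_name": set_name,
                "variant_class": vc,
                "mean_case": res.mean_case,
                "sd_case": res.sd_case,
                "mean_control": res.mean_control,
                "sd_control": res.sd_control,
                "t": res.t,
                "df": res.df,
                "p_one_sided": res.p_one_sided,
                "wilcoxon_p": wilcoxon_one_sided(x, y, direction="observed"),
            }
        )
    attach_bh(results)
    burden = pd.DataFrame(rows)
    burden["q_bh"] = [r.q_bh for r in results]

    scz_pos, scz_neg = fixtures.counts_by_flag("top_1000", "damaging_missense", "schizophrenia")
    sz_pos, sz_neg = fixtures.counts_by_flag("top_1000", "damaging_missense", "seizure")
    negative_controls = {
        "schizophrenia_top1000_p": welch_one_sided(
            scz_pos, scz_neg, direction="cases_greater"
        ).p_one_sided,
        "seizure_top1000_p": welch_one_sided(sz_pos, sz_neg, direction="observed").p_one_sided,
    }

    variants = fixtures.case_variant_table()
    missense = variants[variants["variant_class"] == "missense"]
    top500_counts = [
        int((missense[missense["case"] == c]["rank"] <= 500).sum())
        for c in fixtures.CASE_IDS
    ]
    top500 = {
        "case_counts": top500_counts,
        "mean_case": float(np.mean(top500_counts)),
        "sd_case": float(np.std(top500_counts, ddof=1)),
    }

    adj = None
    from .stats import total_adjusted_test

    adj_res = total_adjusted_test(
        fixtures.case_counts("top_1000", "damaging_missense"),
        fixtures.control_counts("top_1000", "damaging_missense"),
        fixtures.case_counts("genome_wide", "damaging_missense"),
        fixtures.control_counts("genome_wide", "damaging_missense"),
        direction="observed",
    )
    adj = adj_res.p_one_sided

    return {
        "burden": burden,
        "negative_controls": negative_controls,
        "top500": top500,
        "total_adjusted_p": adj,
    }
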