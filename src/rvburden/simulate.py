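"""Synthetic cohort generator.

Emulates the data structure of a small CNV-carrier case/control WGS study:
a handful of subjects, per-gene rare-variant counts with a controlled
case enrichment in one target gene-set, predictor scores engineered to a
known damaging fraction, reference-panel allele frequencies with a
controlled common fraction, a hemizygous deletion region, gene resources
(ranked list, GO table) and a GWAS summary table with cohort genotypes.

The statistical model is deliberately simple: per subject x gene variant
counts are independent Poisson draws, with the target-set rate multiplied
by ``enrichment_ratio`` in cases. Benign missense variants are emitted as
an independent Poisson stream, so the *damaging* count distribution is
exactly Poisson at the configured means both before and after
classification. No linkage, haplotype or mutation-spectrum realism is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as rvio
from .genesets import NullSamplerConfig, sample_random_index_matrix
from .stats import welch_one_sided_matrix
from .types import (
    EffectRaw,
    GeneSet,
    GenomicInterval,
    Group,
    GwasSnp,
    RankedGeneList,
    Subject,
    VariantAnnotation,
    VariantCall,
    Zygosity,
)

_BASES = np.array(list("ACGT"))

DEFAULT_DELETION = GenomicInterval("22", 18_900_000, 21_500_000)

_LOF_EFFECTS = (EffectRaw.STOP_GAIN, EffectRaw.FRAMESHIFT, EffectRaw.CORE_SPLICE)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the reference study design: 3 cases vs 6 controls,
    a 1000-gene target set with a control mean of 4.8 rare damaging
    missense variants per subject and a case mean of 10.0
    (enrichment_ratio 10/4.8), a genome-wide damaging-missense load around
    90-105 per subject and ~14 LOF variants per subject, and a hemizygous
    ~2.6 Mb deletion on chromosome 22.
    """

    n_cases: int = 3
    n_controls: int = 6
    n_genes: int = 5_000
    n_ranked: int = 1_561
    target_set_size: int = 1_000
    baseline_mean_count: float = 4.8
    enrichment_ratio: float = 10.0 / 4.8
    background_missense_mean: float = 85.0
    lof_mean: float = 14.0
    damaging_fraction: float = 0.5
    common_mean: float = 20.0
    lowqual_mean: float = 3.0
    x_chrom_mean: float = 2.0
    synonymous_mean: float = 3.0
    deletion_region_mean: float = 0.4
    n_deletion_genes: int = 46
    deletion_interval: GenomicInterval = DEFAULT_DELETION
    n_gwas_snps: int = 500
    gwas_or_sigma: float = 0.15
    gwas_missing_fraction: float = 0.05
    rarity_threshold: float = 0.01
    freq_datasets: tuple[str, ...] = (
        "freq_1kg",
        "freq_esp",
        "freq_exac",
        "freq_inhouse1",
        "freq_inhouse2",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_set_size > self.n_ranked or self.n_ranked > self.n_genes:
            raise ValueError(
                "need target_set_size <= n_ranked <= n_genes "
                f"(got {self.target_set_size}, {self.n_ranked}, {self.n_genes})"
            )
        if not 0 <= self.damaging_fraction <= 1:
            raise ValueError("damaging_fraction must be in [0, 1]")
        for name in (
            "baseline_mean_count",
            "enrichment_ratio",
            "background_missense_mean",
            "lof_mean",
            "common_mean",
            "lowqual_mean",
            "x_chrom_mean",
            "synonymous_mean",
            "deletion_region_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CohortBundle:
    """All inputs the pipeline consumes, in memory, plus a file writer."""

    config: SimulationConfig
    subjects: list[Subject]
    records: list[tuple[VariantCall, VariantAnnotation]]
    ranked: RankedGeneList
    target_set: GeneSet
    deletion_set: GeneSet
    gene_go: dict[str, set[tuple[str, int]]]
    gwas: list[GwasSnp]
    genotypes: rvio.GenotypeTable

    @property
    def case_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects if s.group is Group.CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects if s.group is Group.CONTROL]

    def write(self, outdir) -> dict[str, str]:
        """Emit the bundle in the exact formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sample_sheet": outdir / "sample_sheet.tsv",
            "vcf": outdir / "calls.vcf",
            "annotations": outdir / "annotations.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "ranked_list": outdir / "ranked_list.tsv",
            "gene_go": outdir / "gene_go.tsv",
            "gwas": outdir / "gwas.tsv",
            "genotypes": outdir / "genotypes.tsv",
            "deletion_bed": outdir / "deletions.bed",
        }
        rvio.write_sample_sheet(paths["sample_sheet"], self.subjects)
        rvio.write_variant_calls(
            paths["vcf"],
            paths["annotations"],
            self.records,
            subject_ids=[s.subject_id for s in self.subjects],
            freq_datasets=self.config.freq_datasets,
        )
        # candidate sets only; the target set is re-derived from the ranked list
        rvio.write_gene_sets(paths["gene_sets"], [self.deletion_set])
        rvio.write_ranked_list(paths["ranked_list"], self.ranked)
        rvio.write_gene_go_table(paths["gene_go"], self.gene_go)
        rvio.write_gwas_table(paths["gwas"], self.gwas)
        rvio.write_genotype_table(paths["genotypes"], self.genotypes)
        rvio.write_bed(paths["deletion_bed"], [s.deletion for s in self.subjects])
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# score / frequency synthesis
# ---------------------------------------------------------------------------

_SCORE_PASS = {
    "phylop_placental": lambda rng: 2.3 + rng.uniform(0.1, 3.0),
    "phylop_100vert": lambda rng: 4.0 + rng.uniform(0.1, 3.0),
    "sift": lambda rng: rng.uniform(0.0, 0.049),
    "polyphen2": lambda rng: rng.uniform(0.90, 1.0),
    "mutation_assessor": lambda rng: 1.9 + rng.uniform(0.1, 2.0),
    "cadd_phred": lambda rng: rng.uniform(15.0, 40.0),
    "mutation_taster": lambda rng: rng.uniform(0.51, 1.0),
}
_SCORE_FAIL = {
    "phylop_placental": lambda rng: 2.3 - rng.uniform(0.2, 3.0),
    "phylop_100vert": lambda rng: 4.0 - rng.uniform(0.2, 3.0),
    "sift": lambda rng: rng.uniform(0.06, 1.0),
    "polyphen2": lambda rng: rng.uniform(0.0, 0.85),
    "mutation_assessor": lambda rng: 1.9 - rng.uniform(0.2, 2.0),
    "cadd_phred": lambda rng: rng.uniform(0.0, 14.0),
    "mutation_taster": lambda rng: rng.uniform(0.0, 0.49),
}
_SCORE_KEYS = tuple(_SCORE_PASS)


def _draw_scores(rng: np.random.Generator, damaging: bool) -> dict[str, float]:
    """Scores meeting >=4 of the 7 criteria iff ``damaging``.

    Failing predictors go missing with probability 0.2 (missing counts as
    unmet, so the intended classification is unchanged).
    """
    n_pass = int(rng.integers(4, 8)) if damaging else int(rng.integers(0, 4))
    passing = set(rng.choice(len(_SCORE_KEYS), size=n_pass, replace=False).tolist())
    scores = {}
    for i, key in enumerate(_SCORE_KEYS):
        if i in passing:
            scores[key] = float(_SCORE_PASS[key](rng))
        elif rng.random() >= 0.2:
            scores[key] = float(_SCORE_FAIL[key](rng))
    return scores


def _draw_freqs(
    rng: np.random.Generator, datasets: tuple[str, ...], threshold: float, rare: bool
) -> dict[str, float]:
    freqs = {}
    for ds in datasets:
        if rng.random() < 0.3:
            continue  # unobserved in this panel
        freqs[ds] = float(rng.uniform(0.0, threshold * 0.9))
    if not rare:
        ds = datasets[int(rng.integers(len(datasets)))]
        freqs[ds] = float(rng.uniform(threshold * 2, 0.5))
    return freqs


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _gene_layout(cfg: SimulationConfig) -> dict[str, GenomicInterval]:
    """Deterministic gene coordinates: autosomal genes on chromosomes 1-21,
    deletion-region genes inside the deletion interval on chromosome 22."""
    layout: dict[str, GenomicInterval] = {}
    span = 10_000
    for i in range(cfg.n_genes):
        chrom = str(i % 21 + 1)
        slot = i // 21
        start = 1_000_000 + slot * 100_000
        layout[f"G{i + 1:05d}"] = GenomicInterval(chrom, start, start + span)
    d = cfg.deletion_interval
    step = max((d.length - span) // max(cfg.n_deletion_genes, 1), 1)
    for j in range(cfg.n_deletion_genes):
        start = d.start + 1000 + j * step
        layout[f"DELG{j + 1:02d}"] = GenomicInterval(d.chrom, start, start + min(span, step))
    return layout


class _VariantFactory:
    """Emits subject variants with unique per-gene positions."""

    def __init__(self, layout, cfg: SimulationConfig):
        self.layout = layout
        self.cfg = cfg
        self.offsets: dict[str, int] = {}

    def emit(
        self,
        rng: np.random.Generator,
        subject_id: str,
        gene: str,
        effect: EffectRaw,
        damaging_scores: bool,
        rare: bool = True,
        quality_pass: bool = True,
        zygosity: Zygosity = Zygosity.HETEROZYGOUS,
        interval_override: Optional[GenomicInterval] = None,
    ) -> tuple[VariantCall, VariantAnnotation]:
        iv = interval_override or self.layout[gene]
        offset = self.offsets.get(gene, 0)
        self.offsets[gene] = offset + 1
        pos = iv.start + offset % iv.length
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        call = VariantCall(
            interval=GenomicInterval(iv.chrom, pos, pos + 1),
            ref=str(ref),
            alt=str(alt),
            subject_id=subject_id,
            zygosity=zygosity,
            quality_pass=quality_pass,
        )
        annotation = VariantAnnotation(
            gene=gene,
            effect_raw=effect,
            scores=_draw_scores(rng, damaging_scores),
            allele_freqs=_draw_freqs(
                rng, self.cfg.freq_datasets, self.cfg.rarity_threshold, rare
            ),
        )
        return call, annotation


def simulate_cohort(cfg: SimulationConfig = SimulationConfig()) -> CohortBundle:
    """Generate a complete, reproducible synthetic input bundle.

    Per-subject damaging-missense counts in the target set are Poisson with
    mean ``baseline_mean_count`` (controls) and ``baseline_mean_count x
    enrichment_ratio`` (cases); seeds are split deterministically per
    component so each resource is stable under config changes elsewhere.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_layout, rng_subjects, rng_variants, rng_gwas, rng_go = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    layout = _gene_layout(cfg)
    autosomal_genes = [g for g in layout if g.startswith("G")]
    deletion_genes = [g for g in layout if g.startswith("DELG")]

    ranked_genes = rng_layout.permutation(autosomal_genes)[: cfg.n_ranked]
    ranked = RankedGeneList(
        entries=tuple((str(g), r) for r, g in enumerate(ranked_genes, start=1))
    )
    target_genes = [g for g, r in ranked.entries if r <= cfg.target_set_size]
    target_set = GeneSet(name=f"top_{cfg.target_set_size}", genes=frozenset(target_genes))
    deletion_set = GeneSet(name="deletion_region", genes=frozenset(deletion_genes))

    subjects = []
    for i in range(cfg.n_cases + cfg.n_controls):
        is_case = i < cfg.n_cases
        sid = f"CASE{i + 1}" if is_case else f"CTRL{i - cfg.n_cases + 1}"
        subjects.append(
            Subject(
                subject_id=sid,
                group=Group.CASE if is_case else Group.CONTROL,
                phenotype_flags={
                    "schizophrenia": bool(rng_subjects.random() < 0.5),
                    "seizure": bool(rng_subjects.random() < 0.4),
                },
                deletion=cfg.deletion_interval,
            )
        )

    # per-gene damaging missense rates
    target_idx = {g: True for g in target_genes}
    n_background = cfg.n_genes - len(target_genes)
    bg_rate = cfg.background_missense_mean / max(n_background, 1)
    base_rate = cfg.baseline_mean_count / len(target_genes)
    lof_rate = cfg.lof_mean / cfg.n_genes

    df = cfg.damaging_fraction
    benign_factor = (1 - df) / df if df > 0 else 1.0

    factory = _VariantFactory(layout, cfg)
    records: list[tuple[VariantCall, VariantAnnotation]] = []
    for subject in subjects:
        sid = subject.subject_id
        case_mult = cfg.enrichment_ratio if subject.group is Group.CASE else 1.0
        rates = np.array(
            [
                (base_rate * case_mult if g in target_idx else bg_rate)
                for g in autosomal_genes
            ]
        )
        damaging_counts = rng_variants.poisson(rates) if df > 0 else np.zeros(len(rates), int)
        benign_counts = rng_variants.poisson(rates * benign_factor)
        lof_counts = rng_variants.poisson(np.full(len(autosomal_genes), lof_rate))
        for gi, gene in enumerate(autosomal_genes):
            for _ in range(int(damaging_counts[gi])):
                records.append(
                    factory.emit(rng_variants, sid, gene, EffectRaw.MISSENSE, True)
                )
            for _ in range(int(benign_counts[gi])):
                records.append(
                    factory.emit(rng_variants, sid, gene, EffectRaw.MISSENSE, False)
                )
            for _ in range(int(lof_counts[gi])):
                effect = _LOF_EFFECTS[int(rng_variants.integers(3))]
                records.append(factory.emit(rng_variants, sid, gene, effect, False))
        # streams exercising each filter: common, low-quality, non-autosomal
        for _ in range(int(rng_variants.poisson(cfg.common_mean))):
            gene = autosomal_genes[int(rng_variants.integers(len(autosomal_genes)))]
            records.append(
                factory.emit(rng_variants, sid, gene, EffectRaw.MISSENSE, True, rare=False)
            )
        for _ in range(int(rng_variants.poisson(cfg.lowqual_mean))):
            gene = autosomal_genes[int(rng_variants.integers(len(autosomal_genes)))]
            records.append(
                factory.emit(
                    rng_variants, sid, gene, EffectRaw.MISSENSE, True, quality_pass=False
                )
            )
        for _ in range(int(rng_variants.poisson(cfg.x_chrom_mean))):
            pos = int(rng_variants.integers(1_000_000, 100_000_000))
            records.append(
                factory.emit(
                    rng_variants,
                    sid,
                    f"GX{int(rng_variants.integers(100)) + 1:03d}",
                    EffectRaw.MISSENSE,
                    True,
                    interval_override=GenomicInterval("X", pos, pos + 10_000),
                )
            )
        for _ in range(int(rng_variants.poisson(cfg.synonymous_mean))):
            gene = autosomal_genes[int(rng_variants.integers(len(autosomal_genes)))]
            records.append(
                factory.emit(rng_variants, sid, gene, EffectRaw.OTHER, False)
            )
        # hemizygous calls inside the subject's deletion
        if deletion_genes:
            for _ in range(int(rng_variants.poisson(cfg.deletion_region_mean))):
                gene = deletion_genes[int(rng_variants.integers(len(deletion_genes)))]
                records.append(
                    factory.emit(
                        rng_variants,
                        sid,
                        gene,
                        EffectRaw.MISSENSE,
                        True,
                        zygosity=Zygosity.HEMIZYGOUS,
                    )
                )

    # gene -> GO table: ~90% of genes carry a specific (<=500) term
    gene_go: dict[str, set[tuple[str, int]]] = {}
    for i, gene in enumerate([*autosomal_genes, *deletion_genes]):
        if rng_go.random() < 0.9:
            gene_go[gene] = {(f"GO:{i:07d}", int(rng_go.integers(10, 501)))}
        else:
            gene_go[gene] = {(f"GO:{i:07d}", int(rng_go.integers(501, 2001)))}

    gwas, genotypes = _simulate_gwas(cfg, subjects, rng_gwas)

    return CohortBundle(
        config=cfg,
        subjects=subjects,
        records=records,
        ranked=ranked,
        target_set=target_set,
        deletion_set=deletion_set,
        gene_go=gene_go,
        gwas=gwas,
        genotypes=genotypes,
    )


def _simulate_gwas(cfg, subjects, rng):
    """GWAS summary table plus cohort genotypes; a small fraction of SNPs
    is left uncallable in one subject to exercise the matching rule."""
    gwas = []
    genotypes: dict[str, dict[tuple[str, int], tuple[str, str]]] = {
        s.subject_id: {} for s in subjects
    }
    ids = [s.subject_id for s in subjects]
    for i in range(cfg.n_gwas_snps):
        chrom = str(int(rng.integers(1, 22)))
        pos0 = 200_000_000 + i * 17  # clear of the simulated gene loci
        effect, other = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        snp = GwasSnp(
            snp_id=f"rs{900000 + i}",
            interval=GenomicInterval(chrom, pos0, pos0 + 1),
            effect_allele=effect,
            odds_ratio=float(np.exp(rng.normal(0.0, cfg.gwas_or_sigma))),
            p_value=float(10.0 ** rng.uniform(-8, 0)),
            other_allele=other,
        )
        gwas.append(snp)
        freq = rng.uniform(0.1, 0.9)
        drop = ids[int(rng.integers(len(ids)))] if rng.random() < cfg.gwas_missing_fraction else None
        for sid in ids:
            if sid == drop:
                continue
            n_eff = int(rng.binomial(2, freq))
            alleles = tuple([effect] * n_eff + [other] * (2 - n_eff))
            genotypes[sid][(chrom, pos0)] = alleles
    return gwas, genotypes


# ---------------------------------------------------------------------------
# Count-level replicate helpers (fast paths for power / calibration studies)
# ---------------------------------------------------------------------------

def replicate_target_counts(
    n_replicates: int,
    case_mean: float,
    control_mean: float,
    n_cases: int = 3,
    n_controls: int = 6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson per-subject target-set counts for many replicate cohorts.

    This is the count-level marginal of :func:`simulate_cohort` (the
    per-gene Poisson rates sum over the target set), used for replicate
    studies where emitting full variant records would be waste.
    """
    rng = np.random.default_rng(seed)
    X = rng.poisson(case_mean, size=(n_replicates, n_cases))
    Y = rng.poisson(control_mean, size=(n_replicates, n_controls))
    return X, Y


def simulate_null_specificities(
    n_replicates: int = 1000,
    n_genes: int = 400,
    set_size: int = 50,
    n_random_sets: int = 150,
    baseline_mean: float = 4.8,
    n_cases: int = 3,
    n_controls: int = 6,
    seed: int = 0,
    direction: str = "observed",
) -> np.ndarray:
    """Empirical specificity of a target set under *no* enrichment.

    For each replicate: draw a gene-level Poisson count matrix with a flat
    rate (total target-set mean = ``baseline_mean`` in every subject),
    burden-test an arbitrary target set, burden-test ``n_random_sets``
    random sets of the same size, and record the fraction of random-set
    p-values strictly below the target's. Under the null this fraction is
    approximately Uniform(0, 1) across replicates.
    """
    root = np.random.SeedSequence(seed)
    rate = baseline_mean / set_size
    n_subjects = n_cases + n_controls
    out = np.empty(n_replicates)
    for r, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        counts = rng.poisson(rate, size=(n_subjects, n_genes)).astype(float)
        target = counts[:, :set_size].sum(axis=1)
        obs_p = welch_one_sided_matrix(
            target[None, :n_cases], target[None, n_cases:], direction=direction
        )[0]
        idx = sample_random_index_matrix(
            n_genes,
            NullSamplerConfig(n_sets=n_random_sets, set_size=set_size, seed=int(ss.generate_state(1)[0] % 2**31)),
        )
        membership = np.zeros((n_random_sets, n_genes))
        rows = np.repeat(np.arange(n_random_sets), set_size)
        membership[rows, idx.ravel()] = 1.0
        set_counts = membership @ counts.T  # (n_random_sets, n_subjects)
        null_p = welch_one_sided_matrix(
            set_counts[:, :n_cases], set_counts[:, n_cases:], direction=direction
        )
        null_p = null_p[~np.isnan(null_p)]
        out[r] = np.mean(null_p < obs_p) if null_p.size else np.nan
    return out
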