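"""Common-variant polygenic risk scoring from GWAS summary statistics.

Each subject's score at a given association p-value threshold is

    PRS(s) = sum over matched SNPs with p <= threshold of
             (# alleles matching the effect allele) * ln(odds ratio)

A GWAS SNP is *matched* only when every subject in the cohort has a
callable genotype at its position whose alleles are compatible with the
SNP's allele pair; no strand flipping or ambiguous-site resolution is
attempted — incompatible sites are skipped and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .stats import BurdenTestResult, welch_one_sided
from .types import GwasSnp, normalize_chrom

logger = logging.getLogger(__name__)

#: subject -> {(chrom, 0-based pos): (allele1, allele2)}
GenotypeTable = Mapping[str, Mapping[tuple[str, int], tuple[str, str]]]


@dataclass(frozen=True)
class PrsConfig:
    p_thresholds: tuple[float, ...] = (1e-3, 1e-5, 1e-7)
    log_base: str = "natural"
    unmatched_snp_policy: str = "skip"

    def __post_init__(self) -> None:
        if any(not 0 < t < 1 for t in self.p_thresholds):
            raise ValueError("thresholds must be in (0, 1)")
        if self.log_base != "natural":
            raise ValueError("only natural log is supported")
        if self.unmatched_snp_policy != "skip":
            raise ValueError("only the skip policy is supported")


@dataclass(frozen=True)
class PrsResult:
    subject_id: str
    threshold: float
    n_snps_used: int
    score: float


@dataclass
class MatchSummary:
    n_input: int = 0
    n_matched: int = 0
    n_missing_genotype: int = 0
    n_incompatible_alleles: int = 0


def match_snps(
    genotypes: GenotypeTable,
    gwas: Sequence[GwasSnp],
) -> tuple[list[GwasSnp], MatchSummary]:
    """SNPs with a compatible, callable genotype in *every* subject.

    A genotype is compatible when each of its alleles is in the SNP's
    allele pair ({effect, other}; effect alone if the other allele is not
    given). Unmatched SNPs are skipped and counted, never imputed.
    """
    summary = MatchSummary(n_input=len(gwas))
    matched = []
    for snp in gwas:
        key = (normalize_chrom(snp.interval.chrom), snp.interval.start)
        allowed = {snp.effect_allele}
        if snp.other_allele is not None:
            allowed.add(snp.other_allele)
        missing = False
        incompatible = False
        for sid, sites in genotypes.items():
            gt = sites.get(key)
            if gt is None:
                missing = True
                break
            if snp.other_allele is not None and not set(gt) <= allowed:
                incompatible = True
                break
        if missing:
            summary.n_missing_genotype += 1
            continue
        if incompatible:
            summary.n_incompatible_alleles += 1
            logger.warning("SNP %s skipped: alleles incompatible with GWAS pair", snp.snp_id)
            continue
        summary.n_matched += 1
        matched.append(snp)
    return matched, summary


def allele_count(genotype: tuple[str, str], effect_allele: str) -> int:
    """Number of alleles in a diploid genotype matching the effect allele."""
    return sum(1 for a in genotype if a == effect_allele)


def polygenic_score(
    subject_genotypes: Mapping[tuple[str, int], tuple[str, str]],
    gwas: Sequence[GwasSnp],
    threshold: float,
    subject_id: str = "",
    cfg: PrsConfig = PrsConfig(),
) -> PrsResult:
    """Sum of allele_count x ln(OR) over matched SNPs with p <= threshold.

    ``gwas`` should already be restricted to matched SNPs
    (see :func:`match_snps`); SNPs without a genotype here are an error,
    since matching guarantees every subject is callable.
    """
    score = 0.0
    n_used = 0
    for snp in gwas:
        if snp.p_value > threshold:
            continue
        key = (normalize_chrom(snp.interval.chrom), snp.interval.start)
        gt = subject_genotypes.get(key)
        if gt is None:
            raise KeyError(f"subject {subject_id!r} has no genotype for matched SNP {snp.snp_id}")
        score += allele_count(gt, snp.effect_allele) * math.log(snp.odds_ratio)
        n_used += 1
    return PrsResult(subject_id=subject_id, threshold=threshold, n_snps_used=n_used, score=score)


def score_cohort(
    genotypes: GenotypeTable,
    gwas: Sequence[GwasSnp],
    cfg: PrsConfig = PrsConfig(),
) -> tuple[list[PrsResult], MatchSummary]:
    """Match SNPs across the cohort, then score every subject at every threshold."""
    matched, summary = match_snps(genotypes, gwas)
    results = []
    for threshold in cfg.p_thresholds:
        for sid in sorted(genotypes):
            results.append(
                polygenic_score(genotypes[sid], matched, threshold, subject_id=sid, cfg=cfg)
            )
    return results, summary


def compare_prs(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    threshold: float,
    direction: str = "cases_greater",
) -> BurdenTestResult:
    """One-sided Welch comparison of per-subject scores between groups."""
    return welch_one_sided(
        case_scores,
        control_scores,
        direction=direction,
        set_name=f"prs_p<={threshold:g}",
        variant_class="prs",
        method="prs_welch",
    )
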