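"""Variant-level inclusion rules.

A variant enters the burden analysis only if it is (a) a high-quality call,
(b) rare — alternate allele frequency below a bound in *every* reference
panel, including ethnic subgroups, and (c) in a diploid region of the
genome: autosomal and not hemizygous, with one deliberate exception — calls
inside a subject's hemizygous deletion interval are kept, because for a
deletion carrier those single-copy calls are the entire genotype there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import (
    GenomicInterval,
    StructuralVariant,
    Subject,
    VariantAnnotation,
    VariantCall,
    Zygosity,
    is_autosome,
    normalize_chrom,
)


@dataclass(frozen=True)
class RarityPolicy:
    """Rarity = allele frequency below ``threshold`` in all reference panels.

    ``missing_is_rare`` controls whether a variant absent from a panel is
    treated as satisfying the bound (the usual reading: unobserved in the
    reference panel implies rare).
    """

    threshold: float = 0.01
    require_all_datasets: bool = True
    missing_is_rare: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"rarity threshold must be in (0, 1), got {self.threshold}")


@dataclass(frozen=True)
class RegionPolicy:
    """Diploid-region restriction with a per-subject deletion exception."""

    autosomes_only: bool = True
    breakpoint_window: int = 4_000_000

    def __post_init__(self) -> None:
        if self.breakpoint_window < 0:
            raise ValueError("breakpoint_window must be >= 0")


def is_rare(annotation: VariantAnnotation, policy: RarityPolicy = RarityPolicy()) -> bool:
    """True iff every present panel frequency is below the threshold.

    With ``missing_is_rare`` (default) absent panels count as satisfying the
    bound; an empty frequency map is then rare. Flipping it requires an
    observed sub-threshold frequency in at least one panel and no panel at
    or above threshold.
    """
    present = list(annotation.allele_freqs.values())
    for f in present:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency {f} outside [0, 1]")
        if f >= policy.threshold:
            return False
    if not present and not policy.missing_is_rare:
        return False
    return True


def passes_region_policy(
    call: VariantCall,
    subject: Subject,
    policy: RegionPolicy = RegionPolicy(),
) -> bool:
    """Diploid-region filter with the deletion-interval exception.

    Keeps autosomal calls that are diploid (not hemizygous); a call inside
    the subject's declared deletion interval is kept regardless of reported
    zygosity. An empty/absent deletion reduces this to a plain
    autosomal-diploid filter.
    """
    if policy.autosomes_only and not is_autosome(call.interval.chrom):
        return False
    deletion = subject.deletion
    if deletion is not None and deletion.overlaps(call.interval):
        return True
    return call.zygosity is not Zygosity.HEMIZYGOUS


def near_breakpoint(
    call: VariantCall,
    deletion: GenomicInterval,
    window: int = 4_000_000,
) -> bool:
    """True iff the call lies outside the deletion but within ``window`` bases
    of either deletion boundary (same chromosome only)."""
    iv = call.interval
    if normalize_chrom(iv.chrom) != normalize_chrom(deletion.chrom):
        return False
    if deletion.overlaps(iv):
        return False
    gap = deletion.distance_to(iv)
    return gap is not None and gap <= window


def sv_overlaps_coding_exon(
    sv: StructuralVariant,
    exons: Iterable[GenomicInterval],
) -> bool:
    """True iff the SV overlaps >=1 base of any coding exon (half-open)."""
    return any(sv.interval.overlaps(exon) for exon in exons)


@dataclass
class FilterLedger:
    """Counts of variants removed at each stage; emitted in run manifests."""

    total: int = 0
    fail_quality: int = 0
    fail_rarity: int = 0
    fail_region: int = 0
    passed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "fail_quality": self.fail_quality,
            "fail_rarity": self.fail_rarity,
            "fail_region": self.fail_region,
            "passed": self.passed,
        }


def apply_filters(
    records: Sequence[tuple[VariantCall, VariantAnnotation]],
    subjects: Sequence[Subject],
    rarity: RarityPolicy = RarityPolicy(),
    region: RegionPolicy = RegionPolicy(),
) -> tuple[list[tuple[VariantCall, VariantAnnotation]], FilterLedger]:
    """Apply quality, rarity and region filters in order.

    Stages are applied sequentially, so each record is charged to the first
    filter it fails and ledger counts sum to the total.
    """
    by_id = {s.subject_id: s for s in subjects}
    ledger = FilterLedger()
    kept = []
    for call, annotation in records:
        ledger.total += 1
        if not call.quality_pass:
            ledger.fail_quality += 1
            continue
        if not is_rare(annotation, rarity):
            ledger.fail_rarity += 1
            continue
        subject = by_id.get(call.subject_id)
        if subject is None:
            raise KeyError(f"call for unknown subject {call.subject_id!r}")
        if not passes_region_policy(call, subject, region):
            ledger.fail_region += 1
            continue
        ledger.passed += 1
        kept.append((call, annotation))
    return kept, ledger
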