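"""Core domain types for small-cohort rare-variant burden analysis.

All genomic coordinates are 0-based, half-open internally. External formats
(VCF, GWAS summary tables) are 1-based and converted at the I/O boundary;
BED is already 0-based half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

#: The seven predictor / conservation score keys an annotation may carry.
PREDICTOR_KEYS = (
    "phylop_placental",
    "phylop_100vert",
    "sift",
    "polyphen2",
    "mutation_assessor",
    "cadd_phred",
    "mutation_taster",
)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so 'chr22' and '22' compare equal."""
    chrom = chrom.strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"


class EffectRaw(str, enum.Enum):
    """Raw annotated effect class of a coding variant."""

    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CORE_SPLICE = "core_splice"
    MISSENSE = "missense"
    OTHER = "other"


class ImpactClass(str, enum.Enum):
    """Collapsed impact class used for burden counting."""

    LOF = "LOF"
    MISSENSE = "missense"
    OTHER = "other"


class Group(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class SvType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"
    OTHER = "other"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 base of overlap; half-open touching intervals do not overlap."""
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return False
        return self.start <= other.start and other.end <= self.end

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bases between two intervals on the same chromosome.

        0 if they overlap or touch; None if on different chromosomes.
        """
        if normalize_chrom(self.chrom) != normalize_chrom(other.chrom):
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class VariantCall:
    """One called small variant in one subject.

    The interval spans the reference allele (length == len(ref)).
    """

    interval: GenomicInterval
    ref: str
    alt: str
    subject_id: str
    zygosity: Zygosity
    quality_pass: bool = True

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref})")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """(chrom, 0-based pos, ref, alt) — joins a call to its annotation."""
        return (
            normalize_chrom(self.interval.chrom),
            self.interval.start,
            self.ref,
            self.alt,
        )


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation of one variant site.

    ``scores`` holds the seven predictor / conservation scores; absent
    entries mean the predictor produced no value and are never imputed.
    ``allele_freqs`` maps a reference-panel name to an alternate allele
    frequency in [0, 1] (absent = unobserved in that panel).
    """

    gene: str
    effect_raw: EffectRaw
    scores: Mapping[str, float] = field(default_factory=dict)
    allele_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.scores) - set(PREDICTOR_KEYS)
        if bad:
            raise ValueError(f"unknown predictor keys: {sorted(bad)}")
        for name, f in self.allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency {name}={f} outside [0, 1]")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: Group
    phenotype_flags: Mapping[str, bool] = field(default_factory=dict)
    deletion: Optional[GenomicInterval] = None


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class RankedGeneList:
    """Genome-wide candidate ranking with contiguous ranks 1..N."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        entries = tuple((g.strip(), int(r)) for g, r in self.entries)
        object.__setattr__(self, "entries", entries)
        symbols = [g for g, _ in entries]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({g for g in symbols if symbols.count(g) > 1})
            raise ValueError(f"duplicate gene symbols in ranked list: {dupes}")
        ranks = [r for _, r in entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be contiguous 1..N in order")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    def rank_of(self, gene: str) -> Optional[int]:
        for g, r in self.entries:
            if g == gene:
                return r
        return None


@dataclass(frozen=True)
class GwasSnp:
    """One GWAS summary-statistics record (effect allele oriented upstream)."""

    snp_id: str
    interval: GenomicInterval
    effect_allele: str
    odds_ratio: float
    p_value: float
    other_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError(f"odds ratio must be positive, got {self.odds_ratio}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class StructuralVariant:
    interval: GenomicInterval
    subject_id: str
    sv_type: SvType
    quality_pass: bool = True
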