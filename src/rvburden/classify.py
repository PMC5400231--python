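"""Deleteriousness classification of qualifying coding variants.

Loss-of-function (stop-gain, frameshift, core splice-site) variants are
counted as deleterious outright. A missense variant is called damaging when
it meets at least ``criteria_required`` (default 4) of seven predictor /
conservation criteria:

==================  =========  =========
predictor           direction  threshold
==================  =========  =========
PhyloP placental    >=         2.3
PhyloP 100-vert     >=         4.0
SIFT                <=         0.05
PolyPhen2           >=         0.90
Mutation Assessor   >=         1.9
CADD (Phred)        >=         15.0
MutationTaster      >  (strict) 0.5
==================  =========  =========

The two PhyloP conservation thresholds count as two independent criteria of
the seven. A missing score does not satisfy its criterion under the default
(conservative) missing policy; the ``"exclude"`` sensitivity mode instead
drops missing predictors from the denominator and requires the same 4/7
proportion among those present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .types import EffectRaw, ImpactClass, VariantAnnotation


@dataclass(frozen=True)
class ClassifierThresholds:
    phylop_placental_min: float = 2.3
    phylop_100vert_min: float = 4.0
    sift_max: float = 0.05
    polyphen2_min: float = 0.90
    mutation_assessor_min: float = 1.9
    cadd_phred_min: float = 15.0
    mutation_taster_gt: float = 0.5
    criteria_required: int = 4

    def __post_init__(self) -> None:
        if not 1 <= self.criteria_required <= 7:
            raise ValueError("criteria_required must be in 1..7")


DEFAULT_THRESHOLDS = ClassifierThresholds()

_LOF_EFFECTS = frozenset(
    {EffectRaw.STOP_GAIN, EffectRaw.FRAMESHIFT, EffectRaw.CORE_SPLICE}
)

# impact severity used to collapse multi-transcript annotations
_SEVERITY = {ImpactClass.LOF: 2, ImpactClass.MISSENSE: 1, ImpactClass.OTHER: 0}


def classify_effect(annotation: VariantAnnotation) -> ImpactClass:
    """Collapse the raw effect class to LOF / missense / other."""
    if annotation.effect_raw in _LOF_EFFECTS:
        return ImpactClass.LOF
    if annotation.effect_raw is EffectRaw.MISSENSE:
        return ImpactClass.MISSENSE
    return ImpactClass.OTHER


def _criteria(thresholds: ClassifierThresholds):
    """The seven (key, predicate) pairs, boundary semantics as documented."""
    return (
        ("phylop_placental", lambda v: v >= thresholds.phylop_placental_min),
        ("phylop_100vert", lambda v: v >= thresholds.phylop_100vert_min),
        ("sift", lambda v: v <= thresholds.sift_max),
        ("polyphen2", lambda v: v >= thresholds.polyphen2_min),
        ("mutation_assessor", lambda v: v >= thresholds.mutation_assessor_min),
        ("cadd_phred", lambda v: v >= thresholds.cadd_phred_min),
        ("mutation_taster", lambda v: v > thresholds.mutation_taster_gt),
    )


def count_criteria_met(
    scores: Mapping[str, float],
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Number of the seven criteria satisfied; missing scores contribute 0."""
    met = 0
    for key, predicate in _criteria(thresholds):
        value = scores.get(key)
        if value is not None and predicate(value):
            met += 1
    return met


def count_criteria_present(scores: Mapping[str, float]) -> int:
    return sum(1 for key in scores if scores[key] is not None)


def is_damaging_missense(
    annotation: VariantAnnotation,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    missing_policy: str = "unmet",
) -> bool:
    """Whether a missense variant meets the >=4-of-7 deleteriousness rule.

    missing_policy
        ``"unmet"`` (default): a missing score simply fails its criterion.
        ``"exclude"``: missing predictors are dropped from the denominator
        and the same required proportion (criteria_required / 7) must hold
        among the predictors present; no scores present => not damaging.
    """
    if classify_effect(annotation) is not ImpactClass.MISSENSE:
        raise ValueError(
            f"is_damaging_missense called on {annotation.effect_raw.value} variant"
        )
    met = count_criteria_met(annotation.scores, thresholds)
    if missing_policy == "unmet":
        return met >= thresholds.criteria_required
    if missing_policy == "exclude":
        present = count_criteria_present(annotation.scores)
        if present == 0:
            return False
        return met / present >= thresholds.criteria_required / 7
    raise ValueError(f"unknown missing_policy {missing_policy!r}")


def is_deleterious(
    annotation: VariantAnnotation,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    missing_policy: str = "unmet",
) -> bool:
    """LOF (always) or damaging missense (per the voting rule)."""
    impact = classify_effect(annotation)
    if impact is ImpactClass.LOF:
        return True
    if impact is ImpactClass.MISSENSE:
        return is_damaging_missense(annotation, thresholds, missing_policy)
    return False


def most_severe_effect(annotations: Iterable[VariantAnnotation]) -> VariantAnnotation:
    """Pick one annotation per variant when several transcripts disagree.

    Severity order LOF > missense > other; ties broken by gene symbol for
    determinism.
    """
    best: Optional[VariantAnnotation] = None
    for a in annotations:
        if best is None:
            best = a
            continue
        sa, sb = _SEVERITY[classify_effect(a)], _SEVERITY[classify_effect(best)]
        if sa > sb or (sa == sb and a.gene < best.gene):
            best = a
    if best is None:
        raise ValueError("no annotations given")
    return best
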