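"""The >=4-of-7 deleteriousness voting rule and effect collapsing."""

import numpy as np
import pytest

from rvburden.classify import (
    ClassifierThresholds,
    classify_effect,
    count_criteria_met,
    is_damaging_missense,
    is_deleterious,
    most_severe_effect,
)
from rvburden.types import EffectRaw, ImpactClass, VariantAnnotation, PREDICTOR_KEYS

THR = ClassifierThresholds()


def missense(scores):
    return VariantAnnotation(gene="G", effect_raw=EffectRaw.MISSENSE, scores=scores)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "effect,impact",
        [
            (EffectRaw.STOP_GAIN, ImpactClass.LOF),
            (EffectRaw.FRAMESHIFT, ImpactClass.LOF),
            (EffectRaw.CORE_SPLICE, ImpactClass.LOF),
            (EffectRaw.MISSENSE, ImpactClass.MISSENSE),
            (EffectRaw.OTHER, ImpactClass.OTHER),
        ],
    )
    def test_raw_effect_collapse(self, effect, impact):
        a = VariantAnnotation(gene="G", effect_raw=effect)
        assert classify_effect(a) is impact


class TestCountCriteria:
    def test_exact_threshold_boundaries(self):
        """At the printed thresholds six criteria pass: MutationTaster alone
        is a strict inequality."""
        scores = {
            "phylop_placental": 2.3,
            "phylop_100vert": 4.0,
            "sift": 0.05,
            "polyphen2": 0.90,
            "mutation_assessor": 1.9,
            "cadd_phred": 15.0,
            "mutation_taster": 0.5,
        }
        assert count_criteria_met(scores, THR) == 6

    def test_all_missing_is_zero(self):
        assert count_criteria_met({}, THR) == 0

    def test_four_present_passing_scores(self):
        scores = {"sift": 0.01, "polyphen2": 0.95, "cadd_phred": 20, "mutation_taster": 0.9}
        assert count_criteria_met(scores, THR) == 4


class TestDamagingMissense:
    @pytest.mark.parametrize("n_met,expected", [(3, False), (4, True), (7, True)])
    def test_vote_threshold(self, n_met, expected):
        passing = {
            "phylop_placental": 5.0,
            "phylop_100vert": 6.0,
            "sift": 0.0,
            "polyphen2": 1.0,
            "mutation_assessor": 3.0,
            "cadd_phred": 30.0,
            "mutation_taster": 0.9,
        }
        scores = dict(list(passing.items())[:n_met])
        assert is_damaging_missense(missense(scores), THR) is expected

    def test_non_missense_input_is_an_error(self):
        lof = VariantAnnotation(gene="G", effect_raw=EffectRaw.STOP_GAIN)
        with pytest.raises(ValueError):
            is_damaging_missense(lof, THR)

    def test_lof_is_deleterious_regardless_of_scores(self):
        lof = VariantAnnotation(gene="G", effect_raw=EffectRaw.FRAMESHIFT, scores={})
        assert is_deleterious(lof)

    def test_exclude_missing_sensitivity_mode(self):
        """In 'exclude' mode the 4/7 proportion applies to present scores."""
        three_of_four = {
            "sift": 0.01, "polyphen2": 0.95, "cadd_phred": 20.0, "mutation_taster": 0.1,
        }
        a = missense(three_of_four)
        assert not is_damaging_missense(a, THR, missing_policy="unmet")
        assert is_damaging_missense(a, THR, missing_policy="exclude")  # 3/4 >= 4/7
        assert not is_damaging_missense(missense({}), THR, missing_policy="exclude")


def _brute_force_count(scores):
    """Independent re-evaluation of the seven printed predicates."""
    n = 0
    g = scores.get
    if g("phylop_placental") is not None and g("phylop_placental") >= 2.3:
        n += 1
    if g("phylop_100vert") is not None and g("phylop_100vert") >= 4.0:
        n += 1
    if g("sift") is not None and g("sift") <= 0.05:
        n += 1
    if g("polyphen2") is not None and g("polyphen2") >= 0.90:
        n += 1
    if g("mutation_assessor") is not None and g("mutation_assessor") >= 1.9:
        n += 1
    if g("cadd_phred") is not None and g("cadd_phred") >= 15.0:
        n += 1
    if g("mutation_taster") is not None and g("mutation_taster") > 0.5:
        n += 1
    return n


RANGES = {
    "phylop_placental": (-5, 10),
    "phylop_100vert": (-5, 12),
    "sift": (0, 1),
    "polyphen2": (0, 1),
    "mutation_assessor": (-3, 5),
    "cadd_phred": (0, 50),
    "mutation_taster": (0, 1),
}


class TestClassifierProperties:
    def test_matches_brute_force_on_random_score_grid(self):
        """Classifier output equals independent predicate enumeration over a
        randomized grid of score vectors, including boundary values and
        missing entries."""
        rng = np.random.default_rng(20240917)
        boundaries = {
            "phylop_placental": 2.3, "phylop_100vert": 4.0, "sift": 0.05,
            "polyphen2": 0.90, "mutation_assessor": 1.9, "cadd_phred": 15.0,
            "mutation_taster": 0.5,
        }
        for _ in range(500):
            scores = {}
            for key in PREDICTOR_KEYS:
                u = rng.random()
                if u < 0.2:
                    continue  # missing
                if u < 0.35:
                    scores[key] = boundaries[key]  # exact boundary
                else:
                    lo, hi = RANGES[key]
                    scores[key] = float(rng.uniform(lo, hi))
            expected = _brute_force_count(scores)
            assert count_criteria_met(scores, THR) == expected
            assert is_damaging_missense(missense(scores), THR) == (expected >= 4)

    def test_monotone_in_single_score_improvement(self):
        """Moving any one score toward deleteriousness never lowers the count."""
        rng = np.random.default_rng(7)
        better = {
            "sift": -1, "phylop_placental": +1, "phylop_100vert": +1, "polyphen2": +1,
            "mutation_assessor": +1, "cadd_phred": +1, "mutation_taster": +1,
        }
        for _ in range(200):
            scores = {
                k: float(rng.uniform(*RANGES[k])) for k in PREDICTOR_KEYS if rng.random() > 0.3
            }
            base = count_criteria_met(scores, THR)
            for key in scores:
                improved = dict(scores)
                improved[key] = scores[key] + better[key] * abs(rng.uniform(0, 5))
                assert count_criteria_met(improved, THR) >= base

    def test_monotone_in_required_criteria(self):
        scores = {"sift": 0.01, "polyphen2": 0.95, "cadd_phred": 20.0, "mutation_taster": 0.9}
        a = missense(scores)
        damaging = [
            is_damaging_missense(a, ClassifierThresholds(criteria_required=k))
            for k in range(1, 8)
        ]
        # once the rule fails at some stringency it fails at all higher ones
        assert damaging == sorted(damaging, reverse=True)


class TestMostSevere:
    def test_lof_beats_missense_beats_other(self):
        lof = VariantAnnotation(gene="A", effect_raw=EffectRaw.STOP_GAIN)
        mis = VariantAnnotation(gene="B", effect_raw=EffectRaw.MISSENSE)
        oth = VariantAnnotation(gene="C", effect_raw=EffectRaw.OTHER)
        assert most_severe_effect([oth, mis, lof]) is lof
        assert most_severe_effect([oth, mis]) is mis
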