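"""Classify variants with the >=4-of-7 deleteriousness voting rule.

LOF variants (stop-gain, frameshift, core splice) count outright; missense
variants must satisfy at least four of seven predictor / conservation
criteria.
"""

from rvburden.classify import count_criteria_met, is_deleterious
from rvburden.types import EffectRaw, VariantAnnotation

examples = {
    "stop-gain, no scores": VariantAnnotation(gene="G1", effect_raw=EffectRaw.STOP_GAIN),
    "missense, 4 criteria": VariantAnnotation(
        gene="G2",
        effect_raw=EffectRaw.MISSENSE,
        scores={"sift": 0.01, "polyphen2": 0.95, "cadd_phred": 20.0, "mutation_taster": 0.9},
    ),
    "missense, 3 criteria": VariantAnnotation(
        gene="G3",
        effect_raw=EffectRaw.MISSENSE,
        scores={"sift": 0.01, "polyphen2": 0.95, "cadd_phred": 20.0},
    ),
    "missense, all at boundary": VariantAnnotation(
        gene="G4",
        effect_raw=EffectRaw.MISSENSE,
        scores={
            "phylop_placental": 2.3, "phylop_100vert": 4.0, "sift": 0.05,
            "polyphen2": 0.90, "mutation_assessor": 1.9, "cadd_phred": 15.0,
            "mutation_taster": 0.5,
        },
    ),
}

for label, ann in examples.items():
    met = count_criteria_met(ann.scores)
    print(f"{label:28s} criteria met: {met}/7  deleterious: {is_deleterious(ann)}")

print()
print(
    "Reading: the boundary case meets 6/7 because the MutationTaster\n"
    "criterion is a strict inequality (>0.5); missing scores never count\n"
    "toward the vote."
)
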