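"""Curate the dual-supervised fine-tuning pair table for a cohort.

Lesion-positive pairs get area-dependent slice-range expansion; normal
anatomy pairs are template pseudo-findings over per-slice organ labels.
"""

from keyslice.curation import build_training_set, expansion_padding
from keyslice.synthetic import make_fixture_cohort

cohort = make_fixture_cohort(n_studies=6, seed=1)
pairs, manifest = build_training_set(cohort.annotations, list(cohort.labels.values()))

print("manifest:", manifest)
print("first lesion pair:", next(p for p in pairs if p.source == "lesion"))
print("first organ pair: ", next(p for p in pairs if p.source == "organ_template"))

# the padding rule in isolation: slices added above/below by lesion box area
for area in (1500, 2000, 2500, 4500, 6500):
    print(f"bbox area {area:5d} px -> +-{expansion_padding(area)} slices")
# Organ-pair count equals the total number of (slice, present organ)
# entries; lesion slice links follow the area thresholds exactly.
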