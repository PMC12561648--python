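# Methods

## Selection model

A finding sentence and every axial slice of a CT volume are embedded into
one shared space by a dual encoder; both embeddings are L2-normalized, so
the dot product is the cosine similarity. The per-slice similarity
profile drives two prediction modes:

- **hard** — the key slice is the argmax of the raw profile;
- **soft** — the profile is first smoothed with a moving average over the
  ±r neighbouring slices (default r = 2) and the argmax is taken on the
  smoothed profile. Smoothing exploits the fact that anatomy and lesions
  extend across neighbouring slices, so an isolated high score is more
  likely noise than a finding.

Boundary windows are truncated: `smoothed[i]` is the mean over
`[max(0, i−r), min(N−1, i+r)]`. This choice is simple and linear, but it
divides by fewer terms near the volume ends, so a score bump at the first
or last couple of slices can be inflated relative to an interior bump.
Clinical profiles are smooth and findings at the extreme ends of a scan
are rare; the synthetic recovery suites therefore plant lesions at least
3 slices from either end, and the caveat is documented rather than
special-cased. All ties (argmax and Top-k ranking) break toward the
lowest slice index, making every selection deterministic. Top-k ranking
uses the same mode as Top-1 (soft by default); similarity is plain
cosine with no temperature at inference.

## Preprocessing

CT intensities are in Hounsfield units. Each slice is (1) cropped by
`floor(crop_frac · dim)` pixels per edge — the default fraction 32/512
generalizes the usual 512 → 448 crop to any input size; (2) bilinearly
resampled to the encoder input size (default 224×224, align-corners-off
convention via `skimage.transform.resize`); (3) windowed into [0, 1] by
`clip((HU − (level − width/2)) / width, 0, 1)`. The default window
(level 40 HU, width 400 HU) is the radiological soft-tissue convention;
both values are configurable because different anatomy (lung, bone) needs
different windows. Train-time augmentation (flips, affine
translate/scale/rotate, elastic distortion, cutout) is seeded and purely
functional — the same `(slice, config, seed)` triple always yields the
same output — and is never applied in selection or evaluation paths.

DICOM series are ordered by the z component of ImagePositionPatient (not
by instance number or filename); NIfTI volumes store the slice axis last.

## Encoders

`EmbeddingModel` is a duck-typed contract: `dim`, `max_tokens = 77`,
`encode_text`, `encode_image`, with unit-norm outputs. Sentences are
tokenized to lowercase word tokens and truncated to 77 tokens before
encoding. An all-zero input (e.g. an empty slice) embeds as the uniform
vector `1/√d` to avoid dividing by a zero norm.

Two reference implementations ship with the package:

- **OracleEncoder** ties each concept (organ or lesion type) to a known
  HU intensity code. Text embeds as the normalized sum of one-hots of the
  concepts named in the sentence; an image embeds as the normalized sum of
  one-hots of the codes detected in it (a code counts as present when at
  least 4 pixels lie within 1.5 HU of its windowed value). On noiseless
  phantoms this gives the closed form
  cos(concept c, slice with concept set S) = 1/√|S| if c ∈ S else 0,
  which makes every downstream quantity exactly predictable; it is the
  package's independent oracle for end-to-end tests.
- **TinyTrainableEncoder** is a linear dual encoder: text features are
  CRC32-hashed bag-of-token counts (256 bins + bias), image features are
  the slice mean-pooled to 16×16 (+ bias); each side has one trainable
  linear map into the shared space, plus a learnable log-inverse
  temperature. It is a desk-scale stand-in for transformer backbones —
  trainable in seconds on one CPU — not a clinical model. Pretrained
  backbones can be registered by name behind the same contract.

## Curation

Fine-tuning data is dual-supervised. Lesion-positive pairs come from
radiologist-style annotations (sentence, key slice, bounding box); the
slice range grows with the bounding-box **area** in pixels — strictly
greater than 2000 px adds ±1 slice, >4000 px ±2, >6000 px ±3, with an
area exactly at a threshold taking the smaller padding — clamped to the
volume. Each expanded slice becomes its own (sentence, slice) link so the
contrastive loss sees 2D pairs. Normal-anatomy pairs insert organ names
into a fixed template (default "This CT image includes the {organ}";
word mode emits the bare name) for every (slice, present organ) entry of
the per-slice organ labels, which are consumed as input (produced
externally by a segmenter). The organ list defaults to 15
thoracoabdominal organs and is editable. A pluggable text-rewriter hook
(default: identity) is the seam where LLM paraphrasing of templates would
attach; the core makes no network calls. Output ordering is deterministic
(study, slice, organ), so identical inputs give byte-identical tables.

## Training

The objective is the standard symmetric InfoNCE: for a batch of n
matched pairs with unit text rows T and image rows I,
L = (T Iᵀ)/τ and loss = ½[CE(rows, diag) + CE(columns, diag)] averaged
over n. It equals ln n when all logits are equal and → 0 for identity
similarities as τ → 0. The temperature is learnable, parameterized as
log(1/τ) and initialized at τ = 0.07. Optimization is AdamW (β = 0.9 /
0.999, weight decay 0.01, no decay on the temperature) with a per-step
cosine-annealed learning rate `lr(t) = lr_min + ½(lr_max − lr_min)(1 +
cos(πt/T))`; defaults are lr 5e-5 → 1e-6 over 20 epochs at batch 64,
the recipe appropriate for fine-tuning pretrained backbones. The
checkpoint returned is the one with minimum validation loss (the
untrained initialization counts as a candidate, so a zero-learning-rate
run returns its initialization). Gradients for the tiny encoder are
closed-form (backprop through the normalization and linear maps) and are
verified against finite differences in the test suite.

Two batch-composition choices address dataset pathologies the loss is
otherwise blind to: per-batch stratified sampling with a configurable
lesion:organ weight (default 1:1) prevents the far more numerous organ
pairs from swamping the lesion signal, and at most one pair per
(study, concept) is kept per batch so a batch does not contain duplicated
positives of the same study masquerading as negatives. Both are
configurable off. Collisions that remain (the same organ sentence from
different studies, or one slice containing several prompted organs) are
inherent to template-generated data and leave an irreducible floor in the
loss.

The packaged fine-tuning experiment (`pipeline.finetune_experiment`)
trains the tiny encoder from random initialization on a 6-study phantom
cohort (4 train / 1 val / 1 test) and evaluates Top-1-in-range accuracy
on a separate 8-study cohort (120 organ findings + 16 lesion findings).
Because it trains from scratch rather than fine-tuning pretrained
weights, it uses a larger learning rate (1e-3 → 2e-5) and 60 epochs while
keeping the schedule's shape; with the defaults it gains 26–44 Top-1
points across seeds. Lesion retrieval stays near chance at this scale —
a handful of lesion pairs cannot teach a linear map to spot a few bright
pixels — so the measured gain is carried by the organ findings; this is
the expected desk-scale behaviour, not a target of the experiment.

## Organ calibration

For each organ, prompt-vs-slice cosine scores on the validation split are
split into positives (organ present) and negatives. Candidate thresholds
are the midpoints between consecutive distinct pooled scores; a slice is
called positive when score ≥ t; the threshold maximizing J = TPR − FPR is
selected, ties breaking to the smallest t (preferring sensitivity).
Midpoints avoid ties on observed values, and the degenerate all-equal
case raises a calibration error rather than returning an arbitrary
cutoff. Thresholds are frozen before touching the test split. Presence
classification uses the raw (unsmoothed) profile, since it is a per-slice
decision, not retrieval. Metrics are accuracy and F1 per organ plus the
unweighted macro mean ± population standard deviation; an organ with zero
true and zero predicted positives scores F1 = 1.0 by convention (the
classifier was vacuously right on every slice).

## Evaluation

Validation-style records (single ground-truth index) are scored by the
mean ± population std of |k̂ − k| in slice units. Test-style records
carry an inclusive 0-based range [lo, hi]: Acc@1 is the percentage of
records whose top prediction lies in the range, Acc@k the percentage
whose top-k list intersects it (so Acc@5 ≥ Acc@1 always). On-disk truth
tables carry an `index_base` column and 1-based imports are rejected.
Baseline-vs-fine-tuned deltas are reported in percentage points to two
decimals.

## Synthetic phantoms

`synthetic.make_fixture_cohort` generates multi-study cohorts with exact
ground truth: each of the 15 organs is a constant-intensity rectangle in
its own grid cell, occupying a random contiguous slice interval of 4–9
slices (roughly 15–35% of a 24–32 slice scan); an unlabeled "body"
background spans every slice so that, as in real scans, no slice is
concept-free; lesions (2 per study, distinct types) are small boxes of
distinct intensity planted across key slice ±1 inside a host organ, with
key slices kept at least 3 slices from the scan ends (see the smoothing
caveat above). Each concept's intensity code is unique and lies strictly
inside the default window, spaced wider than the oracle's detection
tolerance. Presence labels derive exactly from the intervals; annotations
record the planted key slice and box; optional Gaussian HU noise degrades
the oracle's detection monotonically within the signal-to-chance regime.
Studies split 4:1:1 into train/val/test deterministically.

The phantoms validate computation, not radiology: real CT has continuous
anatomy, overlapping intensity distributions, partial-volume effects and
inter-patient variability, none of which the rectangles emulate. Passing
tests therefore demonstrate that the pipeline's arithmetic, contracts and
learning dynamics are correct — not that any particular encoder reaches
clinical accuracy. `ProfileSpec`/`generate_profiles` additionally
simulate unimodal similarity profiles (Gaussian bump + iid noise, clipped
to [−1, 1]) for studying hard-vs-soft prediction in isolation; at noise
0.5 of peak height, soft prediction reduces MAE roughly 3–4× over 500
repetitions.

## Problem sizes and numerical choices

Default phantom images are 64×64 (a 512×512 path exists to exercise the
exact crop arithmetic); cohorts are 6–8 studies; the fine-tuning
experiment and the reproduction script complete in a few seconds on one
CPU. Unit-norm checks use 1e-6 tolerance; NIfTI round-trips are exact to
1e-5 (float32 storage). Candidate thresholds, argmax ties and sort ties
are all resolved deterministically, and every stochastic component
(phantom drawing, noise, batch sampling, initialization) is driven by an
explicit integer seed.

## Known limitations

- Organ labels are inputs; no segmentation is performed.
- The tiny encoder is linear: it cannot represent non-linear visual
  concepts and its lesion sensitivity at desk scale is near chance.
- Calibration offers the Youden index only (no isotonic/Platt scaling),
  and thresholds are fixed after validation.
- Series choice (e.g. contrast phase) is an input; the package selects
  slices within a given series only.
- Report translation/paraphrasing is out of scope; sentences arrive in
  the working language, and the rewriter hook is a no-op by default.
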