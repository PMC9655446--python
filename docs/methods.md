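# Methods

## Scope and model

`herdface` implements the deterministic and statistical machinery of an
open-set animal face-identification system. The trained networks such a
system needs in production — a face detector, a landmark regressor, and an
embedding encoder — are represented by contracts (`Detection` inputs, the
`EncoderBackend` protocol), not by weights. The package's own content is
everything that surrounds them: alignment geometry, enrollment policy,
similarity search, temporal smoothing, and evaluation.

A probe face is reduced to a unit-direction comparison problem: encoder
output vectors of the same individual should point nearly the same way,
and identification is a cosine-similarity argmax over all enrolled records
with a reject option. All acceptance rules are strict inequalities
(`score > T`, detector `confidence > 0.7`, diversity `similarity <
threshold`): a single convention applied everywhere, including at the
buffer threshold, so that a score exactly at a threshold is always
rejected.

## Geometry

Coordinates are 0-based, origin top-left, y downward, half-open boxes.
Detector post-processing keeps the single highest-confidence box above the
confidence threshold (the deployment scenario is one animal per frame),
expands it to a square of side `max(w, h)` centered on the box center, and
translates — never shrinks — the square to fit the frame, clamping the
side only if it exceeds the smaller frame dimension. This squarify rule is
idempotent.

Alignment rotates the image by the negative eye angle about the eye
midpoint so the eye line becomes horizontal. The eye angle is reported in
(−90°, 90°]; the remaining half-turn ambiguity is resolved by the muzzle:
if it lands above the eye line after rotation, a further 180° turn
restores portrait orientation. The square region is then re-cropped around
the rotated box center and resampled bilinearly (black fill outside the
canvas) to the chip side, 224 px by default. Resampling uses
pixel-center-at-`i + 0.5` conventions, which keeps transformed landmarks
and pixels consistent to well under a pixel; alignment tests require the
output eye angle to be within 0.5°.

## Encoding and the toy backend

Embeddings default to 512 dimensions to match typical CNN backbones;
desk-scale work and the synthetic world use d = 64, which preserves the
relevant geometry (near-orthogonal identity directions) at a fraction of
the cost. Embeddings are stored raw; normalization happens inside the
cosine.

The `ToyEncoder` is a deliberately simple deterministic stand-in:
grayscale, block-average onto a coarse grid, flatten to d values, subtract
the mean. As a linear map of pixel intensities it is exactly sign-flipped
by a photometric negative and identical for identical chips, and on the
procedural faces it separates identities because the speckle texture is
rendered in face coordinates (so alignment cancels pose). It makes no
claim of realism; it exists so the full pipeline runs and can be tested
offline.

## Enrollment

Enrollment replays the diversity rule used during data collection:
candidates stream in acquisition order; the first is always kept, and each
later one is kept only while its maximum cosine similarity to that
identity's previously kept samples is strictly below the diversity
threshold (default 0.9), stopping at `nim_target` (default 25) records.
Diversity is enforced within an identity only — the phrase "previously
saved identity features" is read as that identity's features, consistent
with per-clip, per-identity sampling; cross-identity diversity is not a
well-defined enrollment constraint (two similar-looking animals must both
still be enrolled). The feature source used for the diversity comparison
is configurable separately from the production encoder, since collection
pipelines often use a generic pretrained feature there.

Removing an identity deletes its records and nothing else; no retraining
is implied, which is the operational advantage of lookup-based
identification over a closed classifier head.

## Lookup and voting

Ranking is chip-level — several candidates may share an identity — so that
top-R voting over the candidate list is meaningful. Ties in the ranking
are broken by (identity, enrollment order) ascending; voting ties prefer
the identity with the higher best score, then the lexicographically
smaller id. The top-1 identity is therefore exactly the identity of the
single most similar chip. `pipScore` always reports the top similarity,
accepted or not, so score distributions can be studied pre-threshold.

## Streams and the buffer

Video is sampled every n-th frame starting at frame 0 (n = 6 at 30 fps is
one sample per 200 ms; a 600-frame clip yields exactly 100 samples).
Per-sample `pipID` values enter a fixed-capacity FIFO. No output is
emitted until the buffer first fills; afterwards the vote is recomputed on
every push (a sliding window). `UNIDENTIFIED` entries occupy slots — they
count in the `bufScore` denominator — but cannot win the vote unless the
buffer holds nothing else: the buffer's job is to report the best
supported identity, not to amplify non-answers, while a run of rejects
still drags the winner's score down and lets `bufThreshold` reject the
window. Vote ties go to the most recently pushed of the tied identities,
favoring the current appearance.

## Evaluation

Rates follow the FRVT identification-track definitions (see README for
the formulas). Rates with an empty denominator are NaN, never 0 — a
battery with no non-mate searches has no false-alarm rate. CMC is FNIR's
complement at T = 0 and is computed with the same rank rule, so
`TPIR + FNIR = 1` holds exactly and CMC is non-decreasing in R by
construction. A mate probe whose accepted top-1 is a *wrong* enrolled
identity counts only as a miss; FPIR is defined over non-mate searches
alone. The EER is located by linear interpolation of FNIR − FPIR between
adjacent grid points of the threshold sweep; when the curves never cross
on the grid the closest-gap point is reported with an explicit flag.

The experiment sweep (`run_sweep`) tabulates two different R semantics
deliberately: `identification_rates` uses the rank-based definition
(true id within top R), while the sweep's CMC cells use top-R *voting*
accuracy — the final prediction is the most frequent identity among the
top R chips — which is the mechanism an unattended deployment would use
and which can dip slightly as R grows. Sweep cells where R exceeds the
per-identity record count are left undefined. Buffered rows rerun the same
probe streams through the FIFO and score the emitted `bufID`s.

`landmark_error_rate` converts a landmark-regression MSE in square pixels
to a percent-of-chip-width radius (MSE 9.2 on a 224 px chip → 1.35%),
purely as a reporting convenience for landmark backends.

## Synthetic world

Identity mean directions are independent standard normal vectors,
normalized — near-orthogonal for d ≫ 1, which is the geometry a
well-trained encoder is meant to produce. Samples are
`mean + σ·N(0, I)`, renormalized: a Gaussian perturb-and-renormalize
rather than an exact von Mises–Fisher draw, chosen because the properties
under test (monotone degradation with σ, separability at small σ) need no
specific density. At d = 64, σ = 0.05 gives within-identity similarities
≈ 0.99 and cross ≈ 0; σ = 0.8 erases the identity signal.

Procedural faces carry an identity-seeded speckle field in face
coordinates, two dark eye disks and one bright muzzle disk at analytic
positions, rotated about the face center; the returned box and landmarks
are exact, enabling sub-degree alignment checks. Clip rendering adds a
smooth per-frame illumination field (canvas coordinates, so alignment does
not cancel it), which is what gives consecutive chips of one animal
realistic non-identity variation: with the default amplitude the toy
encoder sees within-identity similarities around 0.75–0.9, so the
diversity filter keeps several varied chips per clip instead of collapsing
to one. What the synthetic world does **not** emulate: occlusion,
background clutter, multiple animals per frame, detector/landmark noise,
and real photometric structure — passing tests demonstrate the
correctness of the pipeline machinery, not field accuracy on real animals.

## Problem sizes and calibration

The desk-scale study conditions are 50 mates + 10 non-mates at d = 64 with
25 enrolled records (selected from 40 candidates) and 20 probes per
identity; enrollment-capacity checks use 89 identities × 25 records. The
buffering and enrollment-size sweeps use 10 mates + 3 non-mates with σ =
0.23, calibrated once so that per-frame rank-1 accuracy sits in the ~0.85
regime where temporal smoothing is the operative mechanism; the sweep then
shows CMC rising with enrollment size and buffered accuracy at or above
the per-frame pipeline on a closed set.

## Known limitations

- Exhaustive search only; fine for thousands of records, no ANN index.
- The toy encoder is linear and illumination-sensitive by construction;
  any real deployment must register a trained backend.
- The buffer assumes one subject per stream, matching the single-animal
  crush/chute deployment; multi-subject tracking is out of scope.
- `eye_angle` folds to (−90°, 90°], so a face rotated beyond ±90° relies
  on the muzzle flip rule; a face rotated exactly ±90° with a centered
  muzzle is resolved by the flip rule's strict "above" test.
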