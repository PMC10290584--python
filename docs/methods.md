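# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions and the design choices behind `mmecho`, in the
order the pipeline runs them.

## Acquisition model and preprocessing

A record is a DICOM Ultrasound Multi-frame Image Storage object: 49
equal-width frames covering 4.869 s of a parasternal short-axis M-mode
line at 0.833 ms per column, with a per-record depth resolution (the
y-spacing varies between acquisitions). Consecutive frames overlap in
time. Stitching (`mmecho.io.stitch_frames`) removes the duplicated
columns using either

- the recorded overlap metadata (written by our generator into a private
  DICOM block), or
- content matching: the overlap of each adjacent pair is the offset
  (searched over 1..50 % of the frame width) minimising the mean absolute
  difference between the trailing and leading column blocks, accepted
  only when the match is essentially exact (< 5e-3 mean absolute
  intensity difference on the 8-bit grid). Overlapping columns are
  duplicated samples, so a true overlap matches exactly even on speckled
  data; anything worse is treated as "no overlap".

Both paths exist because real archives may or may not carry usable
overlap metadata; on generator output they produce identical images.

Windowing: the quality classifier sees square 256×256 crops, vertically
centred on the 256-row strip with maximal temporal intensity variance
(that is where wall motion lives; fallback: image centre; deterministic
first-argmax). The segmenter sees full-height, fixed-width crops. Both
sweeps use a default stride of 128 columns and right-align the last
window so the record is fully covered. Axes: columns are half-open
`[i·x_res, (i+1)·x_res)` ms intervals; row 0 is shallowest.

## Quality classification

Architecture: five blocks of Convolution (3×3) → ReLU → BatchNorm →
MaxPool (2×2), then one fully connected layer and a sigmoid. Channel
widths default to (4, 8, 16, 32, 32); this compact setting trains in a
few minutes on one CPU and is configurable. Training: 15 epochs of Adam
at 1e-4 with (binary) cross-entropy, batch size 8, an 80/20
train/validation split **by record** (never by window, since overlapping
windows of one record would leak across a window-level split), and the
best epoch by held-out loss retained.

Window scores become time intervals as follows: every column's score is
the arithmetic mean of the scores of all windows covering it; columns
with score ≥ 0.5 are high (ties count as high, matching a "cutoff"
reading); same-label runs merge; any high run shorter than 0.3 s — the
minimum length a human annotator would mark as a region — is relabelled
low. The result is a list of half-open intervals tiling the record.
Raising the cutoff can only shrink total high time (tested as a
property).

## Segmentation

A QuickNAT-style binary encoder–decoder: four dense blocks down, a
bottleneck, four dense blocks up. Each dense block is two 3×3
convolutions whose inputs are the concatenation of all previous feature
maps in the block (internal skips), fused by a 1×1 convolution; every
convolution is followed by ReLU and BatchNorm, mirroring the
classifier's block order. Downsampling is 2×2 max pooling whose winner
indices drive the decoder's unpooling; long skip connections concatenate
each encoder block's output into the matching decoder block. Default
width: 8 channels per block with growth 8 (unstated in the QuickNAT
family at this scale; chosen for CPU training and recorded in the spec
object). The head is a 1×1 convolution with one logit channel, so any
input size is accepted (inputs are zero-padded internally to a multiple
of 16 and cropped back).

Training: 20 epochs under the same conditions as the classifier;
"cross-entropy" is per-pixel binary cross-entropy with logits. Only
windows lying fully inside high-quality regions are used, because
low-quality stretches do not represent the true ventricle.

Full-record inference tiles the record, averages the per-pixel
probabilities of overlapping windows (order-invariant), thresholds at
0.5, and then keeps only the longest contiguous foreground run in each
column. That cleanup can only shrink the per-column extent: superimposed
structures tend to split the cavity, and bridging across them would
fabricate diameter, while dropping detached specks cannot.

An oracle backend (`seg.oracle_segmenter`) rasterises the ground-truth
wall traces instead of running the network; it makes the downstream
feature and statistics stages testable deterministically.

## Feature extraction and filtering

LVID(t) per column = (longest contiguous foreground run) × y-resolution;
columns with no foreground are undefined and excluded. Local maxima
(end-diastole) and minima (end-systole) are detected per contiguous
defined segment with a minimum same-type separation of 31 ms (half a
period at a 16 Hz heart-rate cap) and a minimum prominence of 0.1 mm
(suppresses speckle-induced micro-extrema without touching true beats;
both configurable). Each maximum is paired with the immediately
following minimum; a leading unmatched minimum is discarded. A pair is
retained only if **both** event times lie in high-quality intervals (the
stricter of the defensible endpoint conventions) and LVIDd > LVIDs.

Per beat: Teichholz volumes V(D) = 7/(2.4+D)·D³ (mm³), EF =
(V_d−V_s)/V_d·100, FS = (LVIDd−LVIDs)/LVIDs·100. The FS denominator is
LVIDs by default (`fs_variant="paper"`), which exceeds 100 % for strong
contractions and deviates from the conventional definition
(denominator LVIDd, `fs_variant="conventional"`); the package
implements both rather than silently "correcting" either, and logs the
variant in every report. Per mouse: arithmetic means over all retained
beats; a mouse with zero retained beats is flagged excluded and listed,
never silently dropped.

## Statistical screening

Per sex and per parameter (LVIDd, LVIDs, EF, FS), per-mouse means of
mutants and controls are compared with a two-sided Wilcoxon rank-sum
test: exact enumeration when the pooled sample is ≤ 12 and tie-free,
otherwise the mid-rank normal approximation with tie and continuity
corrections (scipy's implementation; an independent brute-force
enumerator lives in the test suite). Significance is p < α with α = 0.05
and **no multiple-testing correction** — eight raw tests per study is
the screening convention this mirrors; a Holm option exists but is off
by default. A stratum emptied by exclusions is marked untestable.

Against a manual baseline the outcome per stratum is a pure function of
the two significance flags: both significant → validated_significant;
neither → validated_nonsignificant; manual-only → lost; automatic-only →
gained. Agreement statistics (Pearson r, paired differences,
Bland–Altman bias ± 1.96 SD) use only mice present in both tables
(intersection; ≥ 3 required).

## Synthetic data generator

The generator emulates the acquisition conditions above, not ultrasound
physics. Its defaults are the study conditions used throughout the
tests:

| parameter | default | meaning |
|---|---|---|
| n_frames / duration / x_res | 49 / 4869 ms / 0.833 ms | acquisition protocol |
| y_res_mm_range | 0.015–0.02 mm/px | per-record depth resolution (depth 6 mm → 300–400 rows) |
| heart_rate_hz | 11 | conscious mouse, ~660 bpm (not stated by protocol; physiologically plausible, configurable) |
| dd_mm / ds_mm | 3.8 / 2.4 | mean end-diastolic / end-systolic LVID |
| beat_cv | 0.04 | relative beat-to-beat jitter of period and amplitudes |
| drift_amp / period | 0.15 mm / 1500 ms | slow physiological fluctuation |
| noise_level | 0.15 | multiplicative speckle strength |
| corruption_rate | 0.25 | expected low-quality time fraction |

The LVID trace places systole and diastole **nodes** alternately in time
(half-period gaps, jittered), adds the drift at the nodes, and joins
them with half-cosine segments. Consequence: the sampled curve's strict
local extrema are exactly the recorded beat events, which is what makes
exact one-to-one extrema-recovery tests possible. Beat events are the
(diastole, following systole) node pairs.

Rendering paints bright wall bands (0.3 mm), a dark cavity and mid-grey
tissue, injects corruption intervals — a wobbling echogenic band across
the cavity (papillary-muscle-like) or a contrast-collapsing dropout —
applies Gaussian multiplicative speckle, quantises to the 8-bit grid,
and slices the image into overlapping frames. Corruption intervals have
lengths uniform on [300, 900] ms; their count uses fractional rounding
so the expected corrupted fraction equals `corruption_rate`; placement
is uniform, rejecting layouts that would leave a high-quality gap
shorter than 0.3 s (so ground-truth regions always satisfy the region
convention).

Frame tiling: with 49 equal-width frames covering exactly 5845 columns,
an overlap of exactly 20 % of the frame width is not an integer
solution; the generator picks the feasible integer (width, overlap) pair
closest to the requested fraction — (133, 14) ≈ 10.5 % by default — and
records it in the metadata. The stitched duration is 4868.885 ms, within
one column of the protocol's 4.869 s.

The "manual" surrogate annotation averages two consecutive clean beats —
deterministically the 3rd and 4th of the longest high-quality region
(fallback: its first two) — emulating an operator picking a
comfortable stretch; an optional `broad_bias` flag instead picks the two
consecutive beats with the largest LVIDd, emulating the human preference
for broad regions.

**What the generator does not model:** ultrasound wave propagation,
anisotropic speckle statistics, probe-angle-dependent wall thickness,
ECG/respiration channels, anaesthetised physiology, B-mode or long-axis
views. Passing tests therefore demonstrate the pipeline's correctness
and its statistical behaviour under controlled conditions, not
segmentation accuracy on real tissue texture.

## Numerical choices and degenerate inputs

- Ties at the quality cutoff are high; per-column score aggregation is
  the arithmetic mean.
- Extremum times are reported at the centre of the extremal column. On
  quantised (mask-derived) curves a peak becomes a plateau;
  `scipy.signal.find_peaks` reports the plateau midpoint, which stays
  within one column of the true event for the generator's symmetric
  waveforms.
- Mask cleanup ties (two equal-length runs) keep the topmost run
  (first argmax), deterministically.
- `evaluate_seg` defines DSC of two empty masks as 1.0.
- Empty score lists yield a single low interval; all-undefined LVID
  curves yield an empty event list; a study stratum emptied by
  exclusions is untestable, and `compare_study` refuses empty samples.
- All training is float32; weight init is He-normal; seeds fully
  determine initialisation, splits, shuffling, and therefore byte-identical
  outputs on rerun.

## Problem sizes in the shipped tests

Chosen so the whole suite runs on one CPU in well under half an hour:
classifier surrogate — 8 training records (~400 windows, balanced
high/low) and a 4-record held-out study; segmenter surrogate — 4 records
giving ~70 full-height 64-column windows with a record-level validation
split; recovery — one 28-mouse oracle-backend study; screening power and
null classification — 50 seeded replicate studies each in the test suite
(25 in the acceptance script); type-I error — 500 replicate null studies
at the trace level. With these sizes the classifier reaches held-out
accuracy ≈ 1.0 and the segmenter held-out DSC ≈ 0.97–0.98, comfortably
above the 0.90 thresholds the tests assert.

## Known limitations

- The synthetic corruption types (band, dropout) are far easier to
  classify than real low-quality echo; classifier metrics on synthetic
  data overstate real-world performance by construction.
- The segmenter is trained on synthetic texture; applying it to real
  records requires retraining on annotated data (the training code path
  is identical).
- The rank-sum asymptotic path at n = 7 per group is mildly conservative;
  exact enumeration engages only for pooled samples ≤ 12 without ties.
- FS per the default variant is not comparable to conventionally
  reported FS values; use `fs_variant="conventional"` for that.
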