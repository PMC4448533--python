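# Methods

## Model

The screen treats a binarized H&E tile as a full cubical complex: every
foreground pixel contributes a closed unit square (face, 4 edges, 4
vertices), shared cells counted once. Two foreground pixels that share an
edge *or a corner* are therefore in the same component (8-connectivity),
and planar duality forces the complement to be read with 4-connectivity. A
hole (`b1`) is a 4-connected component of background pixels that does not
reach the image border. With these conventions the Euler characteristic
identity `b0 − b1 = V − E + F` holds exactly for every mask, and the
implementation asserts it against an independent cell-enumeration routine
and a pure flood-fill oracle in the tests.

The diagnostic signal is the conversion of `b0` into `b1` as nuclear
contact increases: isolated nuclei (high `b0`, `b1 ≈ 0`) fuse into
fenestrated sheets (low `b0`, high `b1`). The screen only thresholds `b1`;
`b0` is reported for inspection.

## Binarization

The published description of the system states only that the binarization
parameter is derived automatically from each image's RGB data, so the rule
here is a design choice: darkness is the complement of Rec.601 luminance
(`d = 255 − round(0.299R + 0.587G + 0.114B)`), and the threshold maximizes
between-class variance of `d` restricted to non-blank pixels (Otsu's
criterion, computed by `skimage.filters.threshold_otsu`). Foreground is
*strictly* darker than the threshold, and blank pixels are never
foreground. Restricting the histogram to tissue keeps large glass areas
from dragging the threshold toward white. Degenerate single-valued
histograms fall back to the median, which leaves the foreground empty
under the strict inequality — the correct answer for featureless tissue.
Bit-identity with the original system is not claimable; the tests pin the
contract instead (classification equal to an exhaustive
integer-threshold sweep on two-population histograms).

Blankness is `min(R,G,B) ≥ 220`. The level is a parameter (`--blank-level`)
because scanner white points vary; 220 cleanly separates glass from eosin
pink in the synthetic palette and in typical H&E scans.

## Grid, normalization, flagging

Segment boundaries are `round(j·width/cols)` (half-up), giving a gapless,
overlap-free 14 × 14 partition whose cells differ by at most one pixel in
size. Each segment is scored independently; holes are evaluated within the
segment's own border, so structures cut by a segment edge do not count.

The raw `b1` of a segment scales with how much of it is tissue, so scores
are divided by the segment's non-blank ratio before thresholding
(threshold 30, strict `>`). The choice to threshold the *normalized* value
is deliberate: normalization exists precisely to make segments with
different tissue coverage comparable. `--no-normalize` switches to raw
`b1` for comparison.

Normalization has a failure mode: a segment that is 2% tissue with a
single incidental hole scores `1/0.02 = 50` and flags. The guard
`min_tissue = 0.05` reports such segments as `insufficient_tissue`
(raw values retained, normalized score 0) instead of flagging them;
`min_tissue = 0` disables the guard and reproduces the artifact, which the
tests exercise both ways.

## Evaluation

Verdicts (positive iff ≥ 1 flagged segment) are cross-tabulated against
reference labels; the four rates are percentages rounded half-up to one
decimal for display, with raw ratios kept in machine output. The module
carries the published 1825-image benchmark tables as reference data — the
cancer-detector cells (1284, 422, 1, 118), the ROI-detector cells
(1615, 91, 1, 118) and the 11-category itemization of the 422 benign
positives — used by the tests and the acceptance script to verify metric
arithmetic and the sums tying the tables together. The category vocabulary
is closed; assigning a category to an image is manual annotation input,
never computed.

## Synthetic tissue

The generator exists because the benchmark images are not public. It
emulates the *topological* phenotypes the method discriminates, not
histologic appearance:

* **normal_mucosa** — gland (crypt) cross-sections: rings of tangentially
  elongated nuclei around white lumina on pink stroma, spaced so nuclei
  stay disconnected. Expected per-segment `b1 ≈ 0`.
* **adenocarcinoma** — one compact sheet of nuclei on a jittered 5-px
  lattice with radius ~3 px: adjacent nuclei overlap while lattice
  interstices stay uncovered, yielding a connected fenestrated sheet with
  ≈ 40–55 windows per 37-px segment, comfortably above the threshold. The
  sheet is sized so the tile's nuclear count matches the normal preset
  (default 600): the phenotypes differ in arrangement, not cellularity.
* **inflammation** — small round cells (r ≈ 2.4 px) in a few aggregates
  whose packing spacing is drawn per tile from 4.4–6.0 px; dense draws
  cross the threshold, sparse ones do not, so tiles flag at an
  intermediate rate — the lymphocyte-aggregation false-positive mode.
* **blank_margin** — bare glass with a narrow tissue strip and four tiny
  ring-shaped debris specks (~30 px² each, one hole) centered in otherwise
  empty segments: with the guard off, each scores `1/0.02 ≈ 40` and flags;
  with the default guard they are `insufficient_tissue`.
* **folded_artifact** — normal tissue plus a doubled-over band rendered as
  a hematoxylin-dark sheet with fine pink clefts; the band binarizes as a
  fenestrated solid and flags, emulating the folded-sample false-positive
  mode.

Stain palette: nuclei (64, 32, 128), stroma (230, 170, 190), glass
(250, 250, 250), fold (120, 60, 140), plus Gaussian noise (σ 2–4). Chosen
so the default blank level and the automatic threshold separate the three
classes with wide margins.

Default tile size is 512 × 512, making each of the 196 segments ≈ 37 px —
large enough to hold tens of windows at nuclear scale. All randomness
derives from the single integer seed in `SyntheticTissueSpec`; there is no
global random state.

What the generator does **not** emulate: stain variation between scanners,
out-of-focus blur, chromatin texture, nuclear polarity, stromal texture,
mucin, tissue-boundary irregularity, or any of the specific benign lesion
subtypes in the false-positive taxonomy beyond generic inflammation.
Passing the synthetic discrimination tests shows the pipeline orders the
intended topological phenotypes correctly; it says nothing about accuracy
on real slides.

`generate_pattern` builds homology fixtures (disks, rings, fused ring
lattices, checkerboards, random disk/ring mixtures) whose Betti pairs are
certain by construction: shape placement enforces a minimum clearance at
draw time, so no post-hoc verification is involved.

## Numerical choices

* Tie-break at the flag threshold: strict `>` (a score of exactly 30 does
  not flag).
* Rounding of reported rates: half-up via `decimal`, matching the printed
  benchmark values; banker's rounding would report 21.8 for 21.85.
* Grid boundaries: half-up rounding of `j·extent/n`; half-open ranges,
  0-based indices everywhere.
* Empty-complement and all-blank edge cases return zeros rather than
  erroring; zero-area masks and empty record lists are errors.
* Test problem sizes: the oracle suite uses all 512 3×3 masks plus 1000
  random 64×64 masks; cohort checks use 20 tiles per phenotype at the
  512-px default, which keeps the whole suite under a minute on one core
  while leaving the flagged-count comparison far from marginal
  (tumor ≈ 5.5 flags/tile vs normal 0).

## Known limitations

* The original system's exact binarization rule and its homology engine's
  connectivity convention are unpublished; this implementation fixes both
  by the contracts above, so per-image agreement with the original on real
  data is not guaranteed.
* "14 × 14 segments" is read as a 14 × 14 *grid*; if the original meant
  fixed 14-px segments, pass `--grid-rows/--grid-cols` accordingly.
* Whether the original thresholded raw or normalized `b1` is ambiguous;
  both are available (`--no-normalize`).
* Whole-slide formats and tiling are out of scope; inputs are
  already-extracted PNG/TIFF/BMP tiles.
* The screen is a detector of nuclear-contact anomalies, not a cancer
  classifier: the published benchmark's own specificity as a cancer
  detector is 21.9%, and most of its false positives are genuine ROIs of
  benign origin.
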