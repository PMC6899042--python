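# Methods

## Block-matching motion estimation

The estimator is classic motion-vector-prediction (MVP) block matching.
For each consecutive frame pair and each grid point, the N×N block centred
on the grid point in the current frame is compared with the block at every
integer offset (i, j), |i|,|j| ≤ w, in the previous frame; the matching
criterion is the mean absolute error

    MAE(i, j) = (1/N²) Σₘ Σₙ | fₜ(m,n) − fₜ₋₁(m+i, n+j) |.

Defaults N = 16 px, w = 4 px, grid stride 4 px match the operating point
used for embryonic-heart video at 150 fps. Normalising by N² is the
package default with a flag for the raw sum; the argmin, and therefore
every vector and velocity, is identical either way.

Numerical and policy choices:

- **Tie-break.** Equal-MAE offsets resolve to the smallest Euclidean norm,
  then row-major order. Deterministic, and biased toward "no motion", which
  is the right prior for featureless blocks.
- **Boundary policy.** Grid points whose block or search window would leave
  the frame are dropped (and counted), never padded — padding fabricates
  intensities and biases the MAE.
- **Sign convention.** The stored vector is the negated matching offset,
  i.e. the displacement of scene content from the previous to the current
  frame. Only magnitudes are used downstream.
- **Sub-pixel refinement** (default on; `subpixel=False` gives the pure
  integer search used by the oracle tests). The integer minimum is refined
  per axis by the vertex of a parabola fitted through the *squared* MAE at
  offsets −1/0/+1. For a smoothly textured scene near alignment, the MAE
  grows essentially linearly with |misalignment| (an L1 cost), so the
  squared MAE is locally quadratic: the parabola on squared values is
  asymptotically unbiased, whereas a parabola on the raw V-shaped cost
  pulls estimates toward the integer grid by up to a factor of two at small
  fractional shifts. This matters directly here: the slowest preset moves
  ≈ 0.6 px/frame at peak, entirely inside one pixel. Refinement applies
  only when the minimum is interior to the search range, the fitted
  parabola is convex, and the match is not exact (MAE > 0, so pure integer
  translations stay exact); components are clamped to ±(w + 0.5).
- **Vectorisation.** The field computation evaluates, per offset, the
  absolute-difference image and an integral image, then reads all block
  sums at once; it is verified in the tests to be bit-identical to the
  per-block reference search at every grid point, in both integer and
  sub-pixel modes.

The velocity trace is the ROI-mean vector magnitude per transition,
converted to μm/s by pixel size × frame rate, time-stamped at the later
frame of each pair. Both calibration constants are required inputs
everywhere; the package never assumes a magnification.

## Beat segmentation and summaries

Speeds are magnitudes, so systole and diastole are both positive lobes;
each beat is a large peak followed by a smaller one. A global threshold
cannot implement that rule when diastolic peaks of strong beats exceed
systolic peaks of weak ones, so segmentation is period-anchored:

1. Optional centred moving-average smoothing (default 5 frames = 33 ms at
   150 fps, well under a systolic lobe; window 1 disables).
2. The beat period is the strongest autocorrelation peak of the
   mean-subtracted trace with lag in a physiological band (default
   0.2–2.0 s, i.e. 30–300 beats/min) and height ≥ 20% of the zero-lag
   value — the height floor rejects aperiodic traces.
3. Candidate peaks need prominence ≥ 20% of the trace's 95th percentile.
   Period-length windows are anchored on the tallest candidate; each
   window's tallest candidate is its systolic peak, and the tallest
   candidate before the next systolic peak (or the trace end, for the last
   beat) is the diastolic peak. Beats without a diastolic candidate, or
   where the pairing would invert the systolic ≥ diastolic invariant, are
   dropped and counted.

Chamber summaries report the per-specimen **maximum** over beats of each
peak speed (the means of per-beat peaks are emitted alongside, since either
convention can feed a cross-specimen average) and the heart rate as
60 / median inter-systolic interval. Group comparison uses the two-sided
pooled-variance Student's t-test with s.e.m. = SD/√n; degenerate
zero-variance groups define t = 0, p = 1 when means agree.

## Synthetic beating-wall videos

The generator emulates exactly what the estimator measures: a textured
wall whose speed follows a prescribed waveform. Per beat period, the
velocity is a negative half-sine contraction lobe (amplitude = peak
systolic speed, duration 0.12 s by default) followed by a positive
half-sine relaxation lobe whose amplitude is the peak diastolic speed and
whose duration is solved from the area balance

    V_sys · T_sys = V_dia · T_dia,

so the wall returns exactly to baseline each beat while both peak speeds
remain independently prescribable; the remainder of the period is rest.
Displacement is integrated in closed form. Rendering attaches a
Gaussian-blurred white-noise texture (σ = 2 px — block matching needs
local contrast, not anatomical realism) to either a rigidly translating
horizontal band or a radially displacing annulus, samples it with linear
sub-pixel interpolation, and adds clipped Gaussian sensor noise
(σ = 2 intensity units of 8 bits). Everything derives from one seeded
generator, so videos are bit-reproducible.

Preset conditions carry reference chamber/genotype peak speeds
(atrium 183/140 wild type, 64/35 mutant; ventricle 189/136 and 29/22
μm/s) at 150 fps. The beat period (0.5 s = 120 beats/min) and systolic
lobe duration (0.12 s) are generator-side choices in the physiological
range for embryonic fish hearts — the period is never used as ground truth
for any reported comparison. The preset pixel size, 0.325 μm/px, keeps the
fastest preset (189 μm/s → 3.9 px/frame) inside the default w = 4 search
range, which is the same feasibility constraint a real acquisition faces
when choosing magnification. `suggested_roi` returns the region covered by
moving texture at every beat phase, shrunk by block/search margins, so all
grid vectors measure wall motion.

What the generator does *not* emulate: phase-contrast optics, out-of-plane
motion, blood-cell flow, valve dynamics, deformation gradients within the
wall (motion is locally rigid), or photobleaching. Passing recovery tests
therefore demonstrates the correctness of the measurement chain on
rigid-translation kinematics with realistic texture and noise, not
robustness to every property of real microscopy video.

Default problem sizes for recovery runs — 10-s, 150-fps, 256×256 videos —
are the package's benchmark operating point: long enough for ~20 beats and
a stable autocorrelation period, small enough to analyse in about a minute
per video.

## Densitometry simulation and binding quantification

Each replicate lane draws an input-band intensity from a positive-truncated
normal (mean 1000, CV 0.1 by default) and an IP-band intensity equal to
true_fold × input × exp(ε), ε ~ N(0, σ²) with σ = 0.25 — multiplicative
log-normal band noise, the natural error model for chemiluminescent
densitometry. Quantification divides IP by input per lane (cancelling
expression differences), then divides by the *mean* reference ratio, so the
reference condition is exactly 1.00 AU and a per-condition s.e.m. is
defined (per-row fold then condition mean; a ratio-of-means estimator would
not pin the reference at 1.00). With n = 10 replicates the estimator's
log-normal bias term, (e^{σ²} − 1)/n ≈ 0.6%, is far inside the Monte-Carlo
tolerance used in the recovery tests. Condition-versus-reference testing is
the unpaired pooled t-test; pairing of replicates across blots is not
reconstructable from published tables, so no pairing structure is assumed.
Significance stars are a configurable threshold map (default *: P < 0.01,
***: P < 0.001) because star conventions differ between journals and even
between figure legends.

## Coordinate arithmetic

Transcript coordinates are 1-based inclusive ("from bp X to bp Y"), protein
coordinates likewise; consistency means bp length = 3 × aa length, in exact
integer arithmetic. The reading frame is anchored by the stated aa_start —
no CDS offset or sequence retrieval is needed, and accessions are opaque
labels. Printed fragment tables that fail the 3:1 rule (two of the six
bundled reference fragments, off by +1 and −2 bp) are surfaced with their
exact discrepancy and never corrected: the ambiguity of *which* endpoint is
wrong cannot be resolved from the printed ranges. Codon translation uses
the standard nuclear table (checked exhaustively against an independent
implementation in the tests); substitutions producing stop codons are
returned flagged rather than raised.

## Known limitations

- Block matching assumes locally rigid, in-plane motion; strain within a
  block and through-focus motion bias the MAE minimum.
- The sub-pixel model assumes a locally linear L1 cost; heavy noise
  flattens the cost near its minimum and the refinement then degrades
  toward the integer estimate.
- Beat segmentation assumes a dominant stable period; strong arrhythmia
  breaks the window anchoring (arrhythmia classification is out of scope).
- The synthetic generator's realism limits are listed above; no claim is
  made about compression artefacts or colour video (inputs must be
  grayscale).
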