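# Methods

`emloop` is a desk-scale re-creation of a feedback-optimized on-the-fly
cryo-EM processing pipeline. Real pipelines of this kind couple a deep
learning particle picker, a GPU 2D classifier, and a CNN class selector
to multi-terabyte acquisitions; none of that is reproducible on a
laptop, and the movies behind the published experiments are not
deposited. This package therefore re-creates the *system*: every stage
contract, the feedback re-training loop, the threshold optimization,
and the evaluation statistics, exercised end to end on synthetic
micrographs with known ground truth. What is preserved is the loop's
logic and its measurable behavior; what is replaced is each heavyweight
learned component, by a deterministic, CPU-cheap reference
implementation honoring the same contract.

## Synthetic data model

A micrograph movie is a stack of frames, each the sum of: particle
templates placed at ground-truth positions (subpixel placement by
linear interpolation), optional high-intensity contamination discs
(2–4× particle diameter), optional filament ridges, a cumulative global
drift of `f · (dx, dy)` pixels at frame `f`, and i.i.d. Gaussian noise
per frame. Defaults: 360×360 px micrographs, 25 particles each,
template peak amplitude 1.0, noise σ = 0.25 per frame — a moderate
single-frame SNR chosen once as representative of a usable cryo-EM
exposure; σ is exposed in `SimConfig` because no published value
constrains it. Particle classes are smooth, radially asymmetric shapes
(solid disc with an off-center lobe; hollow ring; dumbbell) whose
radial profiles differ enough that species are separable by
rotation-invariant features. Class labels are drawn per particle from
the configured abundances; the two-species default is 81%/19%,
emulating a mixture whose rare state is the scientifically interesting
one. Particle centers keep half a diameter from the image edges and at
least 0.9 diameters from each other (excluded volume — solid particles
cannot interpenetrate; without this constraint the truth itself
contains coincident, unresolvable particles).

Not emulated: CTF modulation and envelope decay (the loop operates on
coordinates and class labels, which do not depend on CTF), ice
gradients, local beam-induced motion (drift is global), radiation
damage, and detector artifacts. Consequently, passing tests demonstrate
the *loop's* correctness and its adaptation dynamics, not picker
performance on real micrographs: a template-correlation picker that
recovers synthetic discs says nothing about membrane proteins in vitreous
ice. The quantities that do transfer are the structural ones — batch
semantics, caps, thresholds, trigger counts, and the direction and
shape of the per-round statistics.

## Reference picker

Training windows each labeled box at the anchor size (default: median
labeled box size, forced odd so the template grid aligns with pixel
centers), downsamples patches to 32×32, normalizes them to zero mean
and unit norm, and clusters them into k = 4 templates (k-means).
Inference computes one normalized cross-correlation map per template,
takes local maxima of the pixelwise maximum map (minimum separation
anchor/3, correlation floor 0.08) as candidates, and suppresses
duplicates by IoU > 0.3 non-maximum suppression. A candidate's
confidence is a logistic calibration over k + 1 features: the per-template
correlations plus the local contrast (sliding-window SD over global SD
— noise maxima correlate moderately but show no contrast excess).
Calibration positives are the training locations; negatives are random
locations plus "hard" candidate peaks farther than one anchor from any
positive, the latter capped at twice the positive count so that a
sparsely labeled micrograph (where most true particles are unlabeled)
cannot invert the calibration. The logistic fit uses light
regularization (C = 10): features live in [0, 1] and the classes are
near-separable on clean data, so the calibration must be able to
saturate — an over-regularized fit leaves rejected locations at
mid-range confidences that the permissive 0.1 in-loop threshold would
accept wholesale.

**Momentum across re-trainings.** A re-trained model keeps a reference
to its predecessor and reports
`confidence = 0.5 · own + 0.5 · previous`, evaluated recursively, so
earlier rounds decay geometrically. This is the package's analog of
fine-tuning a neural picker rather than retraining it from scratch: a
from-scratch template picker would jump to its new training set in a
single round, losing the gradual round-over-round adaptation that the
feedback loop is designed around (and that per-round evaluation tables
record). The blend of 0.5 makes a fully suppressed location decay as
0.5 per round from an initial confidence near 1, crossing the 0.1
pick threshold around round 5 — which is exactly the horizon the
five-round protocol assumes. The chain remains deterministic and
independent of micrograph order.

## 2D classification stand-in

Features per particle patch: radial intensity profile concatenated with
the radially averaged Fourier magnitude (translation-tolerant).
Assignment is balanced k-means with `k = max(1, round(N / mean(size
range)))` classes and a hard per-class capacity equal to the range
maximum, iterated at most 20 times; classes ending below the range
minimum are dissolved into the unaccounted set. The class average is
the member mean after two passes of integer translational alignment to
the running mean; the per-member alignment shifts are retained.
Batch semantics: particles accumulate until the pending count reaches
the batch size (default 20,000), at which point *all* pending particles
flush as one batch — classification never starts early, but batches can
exceed the nominal size. At the end of each feedback round the
remainder is force-flushed: a finite desk-scale round would otherwise
never reach the default batch size and nothing would classify. The
filament preset asks for 30–50 members per class instead of 60–100.

## Class selector

A regularized logistic classifier over standardized class-average
features: contrast (SD), edge energy (mean gradient magnitude),
low/high radial power ratio, member count, intensity-centroid offset,
plus a normalized radial intensity profile. The first five separate
structured averages from noise and contamination; the profile block
adds *shape* discrimination, without which the selector could not be
trained to prefer one particle species over another — the mechanism
behind subpopulation targeting, where sharp, perfectly good-looking
averages of the unwanted species must still be labeled bad. Training
requires ≥ 5 examples per label and warns below 20 per label (about 40
balanced examples is where selection becomes reliable). A class is
good iff its good-probability is at least the acceptance threshold,
default 0.1 — deliberately permissive: the selector only rejects what
it actively recognizes as bad. The reference protocols build their
selectors by truth-labeling class averages from an initial
classification, including averages of deliberately randomized picks:
the selector must have seen the kind of junk a degraded picking model
produces, or it cannot police the loop (the in-package analog of
re-training the selector on the first produced class averages).

## Feedback loop

One round: pick every micrograph at threshold 0.1 → window → accumulate
→ classify each batch → select → collect the good-class members'
provenance boxes → re-train the picker on at most 50 micrographs and
20,000 particles sampled from them (micrographs uniformly without
replacement; the particle cap then drops whole micrographs,
last-sampled first). Exactly five re-training cycles run — no early
stopping; convergence shows up in the reports but is not acted on. Good
boxes are re-centered by subtracting each member's classification
alignment shift, and coincident duplicates (within half a box size) are
merged to one box per particle — the desk-scale analog of using 2D
alignment parameters to re-center and deduplicate coordinates before
re-extraction. Without this, pick jitter feeds back into training
windows, templates blur, and the correlation field develops duplicate
peaks that compound across rounds. A round yielding zero good particles
halts the loop with its diagnostic state: re-training on nothing would
silently poison every later round.

After the loop the threshold is finalized: either a grid search over
0.00–1.00 in steps of 0.01 maximizing micro-averaged F2 (counts pooled
over the subset, ties toward the smaller threshold), using the final
round's good-class boxes as the reference set — the loop's own best
estimate of what a true particle is — or a fixed value (default 0.3)
for filaments, where threshold optimization is not supported. Round
numbering follows the evaluation-table convention: round 1 is the
initial model, rounds 2–6 the products of re-trainings 1–5, and the
final thresholded run is labeled `6 + T x.xx`. The relative-good
statistic is `good_particles / (picks_per_mic × n_mics)`, rounded
half-up to two decimals. 3D processing is out of scope; the loop emits
trigger events instead — ab initio once when 200 good classes have
accumulated, one refinement per 40,000 accumulated good particles —
for external adapters to consume.

## Reference protocols and problem sizes

`protocols.recovery_experiment` (≈1 min, one CPU): 70 micrographs of
one species (60 in-loop, 10 held out), a decently initialized picker,
90% of round-1 picks replaced by uniform random coordinates, batch size
2,000 and class sizes 20–40 (the 20,000/60–100 defaults scaled to the
dataset so each round classifies exactly one batch). Success metric:
held-out F2 of the final model at its optimized threshold, relative to
a picker trained on the full ground truth.
`protocols.steering_experiment` (≈1.5 min): 60 micrographs of the
81%/19% mixture, selector trained good = minority only; per-round
models re-pick a fixed 20-micrograph subset to measure the minority's
share of truth-attributable picks, its absolute recall, and the
per-round evaluation table. These problem sizes are the package's
standing study conditions; the loop's qualitative behavior (initial
relative-good near 0.2, steady climb, stable minority recall while the
majority fades) reproduces at them.

## Filament tracing

The ridge map (Gaussian σ = 2, Otsu threshold) is skeletonized;
skeleton pixels with more than two neighbors mark crossings, are
dilated away, and split the skeleton into branchless paths. Each path
is resampled at the box distance along its arc length; traces shorter
than the minimum segment count are discarded before crossing handling,
then segments within one filament width of a crossing point are
removed. Segment confidence is the normalized ridge strength at the
segment center; the threshold applies to the trace-mean confidence
(default 0.3, fixed — no grid search for filaments). Smoothing erodes
roughly half a width from each ridge end, so a length-L filament yields
⌊L/d⌋ or ⌊L/d⌋ + 1 segments.

## Orchestration

Each stage owns a FIFO queue and a worker pool; GPU-class stages
acquire a token from a shared slot pool (a counting semaphore with a
peak-usage probe) before running. Failed tasks retry twice, then land
in quarantine with a JSON error record under `FAILED/`; a handler
exception never aborts the session. Drift alignment estimates integer
shifts by FFT cross-correlation of each frame against the running
average of previously aligned frames and reports the mean Euclidean
shift between consecutive frames. Range rules partition micrographs by
metric windows, listing every violated rule per flagged micrograph.

## File formats and numerical choices

MRC2014 is implemented directly (little-endian; mode 2 float32 written,
modes 1 and 2 read; pixel size in the cell dimensions; unsupported
modes are rejected by number). Movies compress to multi-page TIFF with
LZW, losslessly, via tifffile. Box files come in two dialects:
`center5` (`x_center y_center w h confidence`) and `corner4`
(`x_corner y_corner w h`, corner = center − size/2 rounded half-up,
confidence read back as 1.0). Internally everything is 0-based,
origin top-left, y down, box *centers*. Session-XML metadata extraction
matches elements by tag local name (namespace-agnostic) against a
documented mapping; absent fields stay absent. Transfers record a
SHA-256 per destination, verify compressed copies by
decompress-and-compare, and delete the source only after every
destination verifies. Ties in the threshold grid break toward the
smaller threshold; matching is greedy by descending pick confidence
with a center-distance criterion of half the box size; F-beta returns 0
at precision = recall = 0.

## Known limitations

The picker is translation-only template correlation: no rotation
search, no scale tolerance beyond the template set, and its accuracy
ceiling on crowded or low-SNR fields is far below a CNN's. The
classifier is not a stability-resampling algorithm — it honors the
capacity and rejection contracts but performs no reproducibility
analysis. The selector's features are hand-crafted; genuinely novel
junk morphologies it has never seen can pass the permissive threshold.
Filament tracing assumes bright ridges on flat background and handles
crossings by exclusion, not disentanglement. The scheduler models GPU
slots, not real device memory. All quantitative guarantees in the test
suite hold for the synthetic study conditions above.
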