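# Methods

## Measurement model

A beat cycle is reduced to eight primitive measurements made on high-speed
video: landmarks P₀ (ciliary base), P₁ and P₂ (tip positions before the
power and recovery strokes) in micrometres, and five time-points t₁…t₅ in
seconds. Valid cycles satisfy t₁ < t₂ ≤ t₃ < t₄ ≤ t₅; the equalities allow
zero-length pauses. Twelve kinematic parameters are derived (see README for
the formula table). Three conventions matter:

* **Angles are radians internally.** The distance and area rates only have
  their conventional magnitudes (tens of μm/s for healthy cilia) when the
  beating angle enters in radians; degrees appear only at presentation.
* **Times are ingested as 0-based integer frame indices plus a frame rate**
  and converted once to seconds, preserving bit-exact provenance from the
  video. The default geometry is 355 frames/s, 1,800 frames per movie,
  256 × 192 pixels of (0.13 μm)², and files store pixels/frames while the
  API works in μm/s.
* **Cilia with no complete observable cycle** (tip never returns to its
  starting extreme) are flagged `cycle_observed=False` and contribute zero
  frequency, durations, distance and area by convention, while length and
  angle are still measured from the landmarks where the geometry allows.
  This zero-by-convention path is what produces patient-level weighted
  distances of exactly 0.0 even though beating cilia are detectable in
  virtually all patients.

The per-cycle tip path is counted once (Lc · ∠), i.e. the swept arc, not
power plus recovery separately. The law-of-cosines argument is clamped to
[−1, 1] so collinear landmarks cannot raise a domain error.

## Edge scoring and aggregation

Twenty epithelial areas are scored per patient. The beating-edge score is
restricted to {0, 0.5, 1}; the fraction of beating edges (sum/20) is kept
as a fraction in [0, 1] and multiplies the raw per-cilium rates directly
(the magnitudes of weighted distances for healthy patients are consistent
only with a [0, 1] multiplier, not a 0–100 one). Dyskinesia scores are
accepted as any real in [0, 3], not only integers: patient means such as
0.13 imply fractional bookkeeping upstream, and accepting reals loses
nothing. Per-patient spread uses the sample (n−1) standard deviation,
conventional for 10-cilium samples; identical values yield exactly 0 rather
than the ~1e-17 residue of floating-point mean subtraction. Fewer than 20
edges or 10 cilia triggers a warning, not an error — the protocol is fixed
but partial data should still be analysable.

## Gold standard and diagnostics

The reference rule is: PCD when TEM shows >90% abnormal cilia all sharing
one ultrastructural defect and NOn < 100 nl/min; non-PCD when TEM shows
<20% abnormal cilia and NOn ≥ 100 nl/min; inconclusive otherwise.
Heterogeneous defect phenotypes fail the shared-defect requirement, so they
cannot enter the PCD group regardless of TEM percentage.

The ROC machinery is orientation-parameterised; the default
`lower` means low marker values indicate disease (the weighted distance
convention), and `higher` reuses the same sweep for markers such as pause
durations. A subject is called positive when its value is strictly below
(resp. above) the threshold. Candidate thresholds are every observed value
plus the representable number just above it, so each step of the empirical
curve is visited on both sides; in sweep order both rates are
non-decreasing. The AUC is computed from midranks (tie-corrected), making
the identity AUC = U/(n₁n₂) with the Mann–Whitney statistic exact, ties
included — this identity is enforced by a property test against a pairwise
counting oracle.

Named cutoffs:

* `sens100` — the least extreme threshold attaining sensitivity 1 (misses
  no positive while keeping specificity maximal);
* `spec100` — the least extreme threshold attaining specificity 1;
* `balanced` — the Youden maximiser; when several thresholds tie, the
  midpoint of the first maximising run is returned.

When the two groups separate perfectly, the sensitivity-1 and
specificity-1 regions overlap and the two cutoffs would cross; both are
then collapsed to the centre of the separating gap, preserving the
convention `spec100 ≤ sens100` that the three-zone classifier requires.
Note that the default working cutoffs (10 / 24 / 51 μm for the weighted
distance) are configuration values, not recomputed per run: the selection
rule behind a balanced working cutoff on measurement-level data is a
clinical choice, so the package accepts user-supplied cutoffs and also
derives Youden/100% cutoffs from whatever data it is given.

Three-zone classification uses strict inequalities: a patient exactly at a
cutoff stays indeterminate. This is deliberately conservative — boundary
values should prompt further work-up, not a diagnosis. Mann–Whitney and
Kruskal–Wallis statistics (with tie correction and asymptotic p-values) are
delegated to scipy.

## Simulator

The generative model mirrors the measurement model: a rigid arm of fixed
length whose angular position about the base follows a plateau–ramp cycle —
dwell at the pre-power extreme for Pr, linear sweep through the beating
angle over Dp, dwell for Ps, linear sweep back over Dr. Linear sweeps
(constant angular velocity) are the simplest kinematics consistent with a
five-time-point description, and the annotator only uses endpoints and
dwells, so nothing finer is warranted. Phase durations must sum to the
period (validated at construction, enforced to 1e-9 relative). Per-frame
Gaussian angular noise models tip-localisation jitter; it moves the tip
along the arc, so the base–tip distance is exactly the arm length. The
"circular" beat pattern, which has no dwell structure, is rendered as tip
motion on a 2:1 ellipse about the base — a stated convention of this
simulator, chosen only so that the class exists in synthetic data; the
annotator correctly finds no sweep–dwell cycle in it.

**Rendering** splats densely sampled points of the base→tip segment into
the frame with bilinear weights (0.25 px sampling), applies a Gaussian PSF
(default σ = 0.2 μm ≈ 1.5 px), normalises the peak to 1 and adds Gaussian
noise of standard deviation peak/SNR, clipping to [0, 1]. A cilium whose
base or tip leaves the field of view (1 px margin) is a geometry error.

**Tracking** thresholds each frame at a fraction (default 0.3) of its
maximum, takes the foreground pixel farthest from the base, and refines in
two steps: a 3×3 intensity-weighted centroid fixes the search radius, then
the tip is placed on the arm axis — the ray from the base through the
foreground intensity centroid, which sits on the axis at the segment
midpoint and is therefore insensitive to tip noise — at the point where the
axial intensity profile falls to half its plateau value. For a Gaussian
PSF the half-maximum crossing of a blurred segment end sits exactly at the
endpoint, independent of the (unknown) blur width. Noise-free tracking
error at the native geometry is ≈ 0.12 px RMS; the plain
farthest-pixel-plus-centroid estimate alone is 0.5–0.9 px RMS depending on
threshold.

**Auto-annotation** unwraps the tip's angular position about the base,
optionally smooths it with a moving average (a 5-frame window is
appropriate for image-derived trajectories; simulated trajectories need
none), and classifies inter-frame steps as sweep or dwell by comparing
|Δφ| to a threshold, default 30% of the maximum observed angular speed.
The first sweep–dwell–countersweep–dwell–sweep motif yields t₁…t₅ and the
landmark extremes; trajectories with no such motif (constant, sub-cycle,
circular) return `cycle_observed=False` rather than erroring. The first
observed sweep is taken to be the power stroke, so trajectories should
begin at or before a cycle start (the simulator's do); if a recording
started mid-cycle, Dp and Dr would swap. Frame quantisation bounds the
recovered period error at one frame; the dwell-threshold rule bounds the
amplitude error below one sweep-step (≈ 0.8° at 90° amplitude, 2.5 Hz,
355 fps).

## Synthetic cohorts

`simulate_cohort` draws whole patient groups: per patient a beating
fraction, 20 edge observations and 10 cilium annotations taken directly
from per-cilium model draws (exact model time-points, no rendering — the
image path is exercised separately, and annotation-level draws keep cohort
generation instant and bias-free). Edge beating scores are Bernoulli around
the patient's fraction so the recomputed fraction is consistent with the
draw.

Two bundled profiles represent the ends of the diagnostic spectrum, with
normal distributions (mean, sd) clipped to physical ranges:

| parameter | non-PCD-like | PCD-like |
|---|---|---|
| length (μm) | 6.0 ± 0.5 | 5.5 ± 0.5 |
| beat amplitude (rad) | 1.55 ± 0.15 | 0.35 ± 0.10 |
| frequency (Hz) | 7.0 ± 1.0 | 3.0 ± 1.0 |
| beating fraction | 0.95 ± 0.05 | 0.50 ± 0.15 |
| dyskinesia score | 0.3 ± 0.3 | 2.5 ± 0.4 |
| patterns | 90% normal, 10% stiff | 70% virtually immotile, 30% stiff |
| P(no observable cycle) | 0 | 0.2 |

These centre the weighted distance near 60 μm/s and 2–3 μm/s respectively,
matching the order of magnitude of healthy referred patients and confirmed
PCD. The phase split of the period defaults to 25% power stroke, 10% pause,
45% recovery, 20% pause — the usual asymmetry of mucociliary beating. A
single `numpy` Generator keyed by the user seed drives every draw, so
cohorts are bit-reproducible.

What the generator does *not* emulate: metachronal coordination between
cilia, mucus load, curvature/bending of the axoneme (the arm is rigid, so
the "beating angle as amplitude proxy" caveat of real recordings does not
arise), focus drift, and observer variability in landmark placement.
Passing round-trip tests therefore demonstrate the correctness of the
computational chain, not the accuracy of human annotation on clinical
video.

## Reference cohort

The bundled 34-patient table (`data/pilot_cohort.tsv`) carries per-patient
qualitative percentages, dyskinesia scores, both weighted rates, NOn and
TEM results. The gold-standard group is *recomputed* from the NOn/TEM
columns at load time and cross-checked against the published assignment;
the 10/15/9 split, the 4/2/3 three-zone reclassification of the
inconclusive patients, and the 9/10 + 15/15 concordance at the 24 μm
working cutoff are all recomputed by the test-suite and acceptance script,
never asserted as constants. Patient-level ROC analyses use the 25
conclusive per-patient means; measurement-level AUCs would require the 250
individual cilium measurements, which are not part of the bundled table, so
the package makes no claim to reproduce them and instead verifies the
ROC machinery by the rank identity and on synthetic cohorts.

## Numerical choices and problem sizes

* Cosine clamping to [−1, 1]; sample SD with exact-zero degenerate path;
  report aggregation sorts patients and within-patient observations so
  reports are byte-identical under input row shuffles.
* Tie-handling: AUC and U use midranks (0.5 per tied pair); sensitivity
  counts positives strictly below the cutoff, ties count toward
  specificity.
* Round-trip and acceptance simulations use 1.2 s of video (426 frames) at
  the native 256 × 192 / 355 fps geometry, and synthetic cohorts of 20 + 20
  patients — sizes chosen to exercise several beat cycles and give stable
  patient-level statistics while keeping the whole suite around a few
  seconds.
* All seeds are plain integers below 2³¹; per-cilium simulator seeds are
  drawn from the cohort stream.

## Known limitations

* The annotator assumes a single cilium per trajectory and a fixed base
  point; it does not segment overlapping cilia.
* The tracker assumes one bright structure per frame (the rendered arm);
  clinical frames with multiple edges would need a region-of-interest crop
  first.
* Beat-pattern labels are inputs (human- or simulator-assigned), never
  inferred from video: automatic pattern classification is out of scope.
* The three-zone cutoffs ship as configuration defaults; deriving them
  afresh requires measurement-level data of the user's own cohort.
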