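# Methods

## The counting model

A dSTORM acquisition yields a table of localizations: sub-pixel emitter
positions, one per fluorophore per frame in which it was ON. A fluorophore
that stays ON for `k` consecutive frames contributes `k` localizations but
only one photophysical event, so raw localization totals over-count. The
pipeline's counting unit is therefore the *linked localization*: a maximal
run of localizations in consecutive frames (up to a configurable
dark-frame tolerance) within a spatial gate of the event's running
centroid.

Counting DNA copies then rests on a single assumption, verified by its own
controls: the expected number of linked localizations per DNA strand is a
stable property of the strand (labeling density × length × blinking
kinetics) and is unchanged by encapsulation or temperature. Measuring that
expectation `μ_cal` on isolated strands turns a carrier's linked total
`n` into a copy number `N̂ = n / μ_cal`.

## Linking algorithm

Linking is greedy in frame order. Open events are extended by the nearest
localization in the next non-dark frame within `max_distance_nm` of the
running centroid; ties break by distance, then lowest row id; an event
accepts at most one localization per frame (one emitter emits once per
frame). This is the de-facto SMLM merging convention and, in the dilute
regime the method operates in (emitter spacing ≫ gate ≫ localization
noise), it provably coincides with the exhaustive pairwise transitive
closure — an equivalence the test suite and acceptance script check
against an independent brute-force implementation on randomized instances.

Defaults: `max_distance_nm = 3 ×` median localization precision,
`max_dark_frames = 0` (consecutive frames read strictly). Both are exposed
because the original acquisition parameters are instrument-specific. With
a 3σ gate about 10% of multi-frame bursts split (the tail of the Rayleigh
step-distance distribution); the split rate is identical in calibration
and carrier acquisitions, so it cancels in the copy-number ratio. This is
why the calibration factor must be measured under the same gates and
kinetics as the carrier measurement, never taken from theory.

## Calibration

Events from a dilute DNA-only field are clustered with DBSCAN on event
centroids (defaults eps = 100 nm, min_events = 5; the library delegates to
scikit-learn, and tests cross-check against a textbook reimplementation).
Clusters pass through two gates before entering the calibration:

* an extent gate from AFM-measured single-strand sizes — defaults
  50–200 nm for 500 bp linear DNA (contour 170 nm, coiled extent
  100–150 nm), up to 1000 nm for 3527 bp linear (contour ≈ 1199 nm),
  up to 500 nm for the 3527 bp plasmid;
* an optional linked-count gate.

Rejections are reported with reasons (aggregate/double count vs too small
or too dim). The calibration records the histogram, `n_strands`, mean,
median and CV; the mean is the factor used downstream (the median is
retained for robustness reporting). A per-strand tally counts merged
events, not constituent frames; the alternative is a configuration away
(`dwell_time_distribution` exposes frame counts) but is not used.

## Copy-number uncertainty

The relative variance of `N̂` is propagated as

    var(N̂)/N̂² = cv²/n_strands + cv²/N̂ + 1/n

with `cv` the calibration CV, `n_strands` the calibration sample size and
`n` the carrier's linked total. The three terms are: uncertainty of the
calibration mean; strand-to-strand heterogeneity (a carrier holding `N`
strands sums `N` i.i.d. draws from the calibration distribution, so its
relative SD is `cv/√N`); and a Poisson floor on the linked total. The
middle term dominates for realistic labeling (cv ≈ 0.15, μ_cal ≈ 10²):
dropping it — i.e., treating the carrier total as purely Poisson — makes
nominal 95% intervals under-cover whenever `cv²·μ_cal > 1`. Simulated
coverage of the implemented interval is 96–99% at nominal 95% across the
load grid. Degenerate calibrations (fewer than two strands, undefined CV)
yield a point estimate with a warning instead of a CI.

## Polyplex segmentation and radius

Carrier clusters are segmented with the same density clustering at a
larger eps; clusters with extent below `min_extent_nm` (default 300 nm)
are routed to an "uncomplexed DNA" set — residual free strands are an
expected by-product of polyplex formation. An optional linked-count
override keeps compact but heavily loaded clusters in the carrier set.
Events within the cluster are all attributed to it; protruding
("dangling") chain ends of long linear DNA are captured by the eps margin,
which is configurable because no published attribution rule exists.

The radius estimate is `√2 × R_g` of the event positions, the exact
relation for a uniform disc; it is a disc-equivalent summary, not a model
fit. It needs ≥ 3 events and flags the all-coincident case as degenerate.

## N/P dosing arithmetic

`N/P = (c_PEI / 43.1) / (c_DNA / 330)` with mass concentrations in µg/mL:
43.1 g/mol per protonatable amine of branched PEI and 330 g/mol per
nucleotide phosphate, the common literature conventions. Both constants
are configurable in `DoseSpec` because the protonatable-amine convention
(all N vs primary N only) varies between groups.

## Synthetic acquisitions

The generator emulates the study conditions at the localization level
(camera-frame fitting, EMCCD noise and PSF shape are out of scope — the
analysis starts from tables, as the real pipeline does):

* **Strand geometry.** Linear DNA is a 2D worm-like chain sampled at one
  point per base pair (rise 0.34 nm/bp, persistence length 50 nm —
  standard dsDNA). Plasmids are closed loops: a harmonically perturbed
  ring rescaled to the contour length, a caricature of the relaxed-loop
  conformations seen by AFM. Each of the `2·bp` nucleotides is labeled
  independently (presets: 10% for linear DNA, 2.3% — the midpoint of the
  measured 1.4–3.3% range — for the plasmid) and photoactive with
  probability 0.7, reflecting that not every dye survives labeling and
  buffer chemistry.
* **Carrier architecture.** A core–shell sphere (defaults: core radius
  300 nm, shell 80 nm, matching the ~380 nm hydrodynamic radius at
  25 °C). Strands anchor at radii drawn ∝ r² within the 3D shell and are
  projected to 2D; all coordinates scale by the temperature swelling
  factor (1.0 at 25 °C, 0.55 at 37 °C — the volume phase transition
  collapse to "about half" size). A `dangling_fraction` pushes part of a
  long linear strand's contour outside the shell.
* **Blinking.** Per-fluorophore two-state Markov chain at the 30 ms frame
  clock: geometric ON (mean 2 frames) and OFF (mean 2000 frames) dwells,
  bleaching probability per ON frame, optional stationary start. Each ON
  frame emits one localization at the fluorophore position plus Gaussian
  noise with per-localization precision ~N(10, 2) nm; false localizations
  arrive as a Poisson field (default 10⁻⁵ /frame/µm², the low-background
  HILO regime). Geometric dwells are a deliberate simplification of
  continuous-time photophysics; they preserve everything the counting
  pipeline is sensitive to (multi-frame bursts, duty cycle, finite photon
  budget) and make closed-form expectations testable.
* **Ground truth.** Every localization is attributable to exactly one
  ON-burst (or the false-positive pool); truth records carry per-strand
  fluorophore lists and per-burst frame spans, so linking, clustering,
  calibration and counting are each scored exactly.

What passing tests on these acquisitions does **not** show: robustness to
sample drift, z-defocus, fluorophore re-activation heterogeneity,
structured background, or chromatic effects — none of which the generator
models. The pipeline's correctness claims are about the counting logic,
not about instrument artifacts.

## Problem sizes and numerical choices

Simulated experiments run at desk scale: calibration fields of 300
strands (the reference "several hundred"), 4000-frame acquisitions with
mean OFF time 2000 frames for counting runs, and 30 000-frame, OFF
11 000-frame acquisitions for the density-linearity experiment. The
low duty cycle in the linearity run is physics, not convenience: at higher
duty, simultaneously ON fluorophores on one strand merge under the
spatial gate and bias the doubling ratio below 2, exactly as real dSTORM
requires sparse activation. Counting recovery uses the grid of true loads
{2, 8, 32} × 50 replicates; the load-32 runs double as the estimate of a
fully loaded 500 bp carrier (~32 strands, matching the 30–35 measured at
25 °C).

Tie-breaks and degenerate inputs: linking ties resolve by distance then
row id; empty inputs yield empty outputs everywhere except `calibrate`
(which refuses to produce a factor from zero strands) and the radius
estimator (≥ 3 events). The intermeans threshold iterates the integer
fixed point `t ← ⌊(mean≤t + mean>t)/2⌋` and returns the smallest level `T`
with mask `image ≥ T`; a constant image is rejected as degenerate. On
images whose background mass overwhelms the signal mass the intermeans
fixed point bisects the background rather than separating signal — a known
property of the ImageJ default method; the uptake fixture therefore
emulates the photon-counting regime (background ≈ 0.01 photons/px/plane)
in which the method is actually used.

## Uptake quantification

Sum projection over z; automatic per-image intermeans threshold (the
ImageJ "Default" IsoData variant, hand-implemented and cross-checked
against scikit-image's isodata in tests); per-cell polygon ROIs; the
background is the mean of ROI pixels under the inverted mask, and the
integrated density is the background-subtracted sum under the mask,
floored at zero. A per-cell threshold variant exists behind a flag since
the published order of masking operations is ambiguous. Group comparisons
(Welch's t-test, ANOVA) are left to standard statistics packages; the
module reports the per-cell densities those tests consume.
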