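# dstormcount

Counting DNA molecules inside polymer nano-carriers from dSTORM
single-molecule localization data.

Gene-delivery polyplexes — here, core–shell pNIPAM/bPEI microgels complexed
with Alexa-647-labeled DNA — are only useful if you know how many DNA
copies each carrier actually holds. Ensemble techniques (DLS, gel shift,
zeta potential) average that away. Direct stochastic optical reconstruction
microscopy (dSTORM) resolves single carriers, and because every labeled
DNA strand produces a reproducible number of fluorophore blinking events,
the localization total of a carrier can be converted into a molecular copy
number. This package implements that counting pipeline end to end,
together with a synthetic-acquisition generator that provides exact ground
truth for every stage, and the companion confocal photon-counting analysis
of cellular uptake.

## Method

Starting from a localization table (one row per detected emitter per
camera frame; 30 000 frames at 30 ms exposure, 107 nm pixels in the
reference acquisition):

1. **Blink linking.** Localizations in consecutive frames within a spatial
   gate of the running centroid are merged into one *blinking event*
   ("linked localization"), correcting for fluorophores that stay ON for
   several frames. Gates: `max_distance_nm` (default 3× median
   localization precision) and `max_dark_frames` (default 0).
2. **Per-strand calibration.** In a dilute DNA-only acquisition, events
   are clustered (DBSCAN, eps 100 nm) and clusters are filtered by
   AFM-derived size gates to reject aggregates and double counts. The mean
   linked localizations per accepted strand, `μ_cal` (with CV), is the
   calibration factor. For double-stranded DNA of `b` base pairs at
   labeling density `d`, the expected fluorophore number is `2·b·d`
   (≈100 for 500 bp at 10%, ≈700 for 3527 bp), and the contour length is
   `0.34 nm × b` (≈1200 nm for 3527 bp), which anchors the size gates.
3. **Polyplex counting.** Carrier clusters are segmented from the event
   field; each carrier's DNA copy number is `N̂ = n_linked / μ_cal`, with a
   95% CI propagating calibration-mean uncertainty, strand-to-strand
   heterogeneity, and Poisson counting error in quadrature. The carrier
   radius is estimated as `√2 × R_g` (disc-equivalent radius of gyration).
   Conditions (N/P ratio, temperature, DNA type/shape) are compared as
   per-condition means with SDs and pairwise count ratios.
4. **Cell uptake.** Confocal photon-counting z-stacks are reduced by sum
   projection; per-cell ROIs are masked with an automatic iterative
   intermeans threshold; the inverted mask estimates the background, and
   the background-subtracted raw integrated density is the per-cell DNA
   uptake proxy. LDH absorbances are reported as fold change over the
   positive control.

The synthetic generator emulates the study conditions: worm-like-chain or
closed-loop DNA with binomial labeling, shell-biased strand placement in a
core–shell sphere whose radius contracts ~0.55× between 25 °C and 37 °C,
and geometric ON/OFF blinking with bleaching at the frame clock. Every
emitted localization is attributable to a ground-truth burst, so counting
accuracy is measurable exactly.

## Worked example

```python
import numpy as np
from dstormcount import (KineticsSpec, LinkingParams, PolyplexSpec,
                         STRAND_PRESETS, calibrate, calibration_field,
                         cluster_events, estimate_dna_count, estimate_radius,
                         filter_single_strands, link_events,
                         polyplex_field, segment_polyplexes,
                         simulate_acquisition)

kin = KineticsSpec(mean_off_frames=2000.0, bleach_prob_per_on_frame=0.02)

# 1. calibration: dilute field of isolated 500 bp strands
cfg = calibration_field(STRAND_PRESETS["linear500"], n_strands=300,
                        kinetics=kin, n_frames=4000, seed=42)
table, _ = simulate_acquisition(cfg)
events = link_events(table, LinkingParams(max_distance_nm=30.0))
clusters, _ = cluster_events(events, eps_nm=100.0, min_events=3)
singles, _ = filter_single_strands(clusters, size_gate_nm=(10.0, 300.0))
cal = calibrate(singles, size_gate_nm=(10.0, 300.0))
print(f"calibration: {cal.n_strands} strands, "
      f"{cal.mean_linked:.1f} linked localizations/strand (CV {cal.cv:.2f})")

# 2. counting: one polyplex with 32 encapsulated strands
pcfg = polyplex_field(PolyplexSpec(n_strands=32), STRAND_PRESETS["linear500"],
                      temperature_c=25.0, kinetics=kin, n_frames=4000, seed=7)
ptable, _ = simulate_acquisition(pcfg)
pevents = link_events(ptable, LinkingParams(30.0))
polyplexes, _, _ = segment_polyplexes(pevents, eps_nm=800.0, min_events=5,
                                      min_extent_nm=300.0)
m = estimate_dna_count(polyplexes[0], cal)
lo, hi = m.dna_count_ci
print(f"polyplex: {m.n_linked} linked localizations -> "
      f"{m.dna_count:.1f} DNA strands (95% CI {lo:.1f}-{hi:.1f}), "
      f"radius {estimate_radius(polyplexes[0]):.0f} nm")
```

Output:

```
calibration: 300 strands, 147.0 linked localizations/strand (CV 0.14)
polyplex: 4559 linked localizations -> 31.0 DNA strands (95% CI 29.2-32.9), radius 373 nm
```

The calibration says one isolated 500 bp strand yields ~147 linked
localizations under these blinking kinetics; dividing the carrier's 4559
linked localizations by that factor recovers the 32 encapsulated strands
within its confidence interval, and the disc-equivalent radius matches the
~380 nm carrier geometry.

The same pipeline is scriptable from a shell via the `dstormcount` CLI
(`simulate-fixture`, `link`, `calibrate`, `count`, `uptake`).

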