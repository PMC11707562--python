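import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from dstormcount import (BlinkEvent, DoseSpec, KineticsSpec, LinkingParams,
                         LocalizationTable, PolyplexSpec, STRAND_PRESETS,
                         StrandCalibration, calibrate, calibration_field,
                         cluster_events, compare_conditions,
                         estimate_dna_count, estimate_radius,
                         filter_single_strands, link_events, np_ratio,
                         pei_mass_for_np_ratio, polyplex_field, render_image,
                         segment_polyplexes, simulate_acquisition)
from dstormcount.calibration import StrandCluster
from dstormcount.exceptions import DegenerateInputError
from dstormcount.polyplex import PolyplexMeasurement

from conftest import DESK_KINETICS, DESK_N_FRAMES, make_table


def ev(x, y, frame=0, ids=(0,)):
    return BlinkEvent(frame, frame, 1, x, y, 1000.0, list(ids))


def disc_events(rng, n, radius, center=(0.0, 0.0)):
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return [ev(center[0] + ri * np.cos(t), center[1] + ri * np.sin(t))
            for ri, t in zip(r, th)]


def make_calibration(mean=100.0, cv=0.15, n=300):
    # synthetic calibration summary with a plausible histogram
    counts = np.clip(np.round(np.random.default_rng(0).normal(
        mean, cv * mean, n)).astype(int), 1, None)
    hist = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    return StrandCalibration(hist, n, float(counts.mean()),
                             float(np.median(counts)),
                             float(counts.std(ddof=1) / counts.mean()))


class TestSegmentation:
    def test_extent_separates_polyplexes_from_free_dna(self, rng):
        big = disc_events(rng, 400, 600.0)
        small = [e for k in range(5)
                 for e in disc_events(rng, 12, 60.0, (5000.0 + 3000.0 * k, 8000.0))]
        pps, unc, noise = segment_polyplexes(big + small, eps_nm=300.0,
                                             min_events=5, min_extent_nm=300.0)
        assert len(pps) == 1 and len(unc) == 5
        # count conservation across the three output sets
        total = sum(c.n_linked for c in pps) + sum(c.n_linked for c in unc) \
            + len(noise)
        assert total == len(big) + len(small)

    def test_empty_events(self):
        assert segment_polyplexes([], 300.0, 5, 300.0) == ([], [], [])

    def test_field_of_ten_polyplexes_fully_segmented(self):
        cfg = polyplex_field(PolyplexSpec(n_strands=8),
                             STRAND_PRESETS["linear500"], 25.0,
                             n_polyplexes=10, pitch_um=4.0,
                             kinetics=DESK_KINETICS, n_frames=DESK_N_FRAMES,
                             seed=88)
        table, _ = simulate_acquisition(cfg)
        events = link_events(table, LinkingParams(30.0, 0))
        pps, unc, _ = segment_polyplexes(events, eps_nm=500.0, min_events=10,
                                         min_extent_nm=300.0)
        assert len(pps) == 10


class TestDnaCount:
    def test_exact_ratio(self, rng):
        cal = make_calibration(mean=100.0)
        cl = StrandCluster.from_events(disc_events(rng, 300, 400.0))
        m = estimate_dna_count(cl, cal)
        assert m.dna_count == pytest.approx(300 / cal.mean_linked)
        lo, hi = m.dna_count_ci
        assert lo < m.dna_count < hi

    def test_zero_events_zero_count(self):
        cal = make_calibration()
        cl = StrandCluster([], 0.0, 0.0, 0.0, 0.0)
        m = estimate_dna_count(cl, cal)
        assert m.dna_count == 0.0 and m.dna_count_ci == (0.0, 0.0)

    def test_degenerate_calibration_point_estimate_only(self, rng):
        cal = StrandCalibration({100: 1}, 1, 100.0, 100.0, float("nan"))
        cl = StrandCluster.from_events(disc_events(rng, 50, 100.0))
        with pytest.warns(UserWarning, match="degenerate"):
            m = estimate_dna_count(cl, cal)
        assert m.dna_count == 0.5 and m.dna_count_ci is None


class TestRadius:
    def test_uniform_disc_closed_form(self, rng):
        """sqrt(2) x Rg of a uniform disc converges to the disc radius."""
        R = 500.0
        cl = StrandCluster.from_events(disc_events(rng, 2000, R))
        assert estimate_radius(cl) == pytest.approx(R, rel=0.05)

    def test_degenerate_cases(self):
        coincident = [ev(10.0, 10.0, ids=[i]) for i in range(5)]
        cl = StrandCluster.from_events(coincident)
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_radius(cl) == 0.0
        with pytest.raises(DegenerateInputError):
            estimate_radius(StrandCluster.from_events([ev(0, 0), ev(1, 1)]))

    def test_swelling_shrinks_radius_by_configured_factor(self):
        radii = {}
        pspec = PolyplexSpec(n_strands=32, swelling=((25.0, 1.0), (37.0, 0.5)))
        for temp in (25.0, 37.0):
            cfg = polyplex_field(pspec, STRAND_PRESETS["linear500"], temp,
                                 kinetics=DESK_KINETICS,
                                 n_frames=DESK_N_FRAMES, seed=77)
            table, _ = simulate_acquisition(cfg)
            events = link_events(table, LinkingParams(30.0, 0))
            pps, _, _ = segment_polyplexes(events, 800.0, 5, 0.0)
            radii[temp] = estimate_radius(max(pps, key=lambda c: c.n_linked))
        assert radii[37.0] / radii[25.0] == pytest.approx(0.5, abs=0.05)


def count_one_field(table, calibration, link_gate=30.0, eps=800.0):
    events = link_events(table, LinkingParams(link_gate, 0))
    pps, _, _ = segment_polyplexes(events, eps, 5, 0.0)
    cluster = max(pps, key=lambda c: c.n_linked)
    return estimate_dna_count(cluster, calibration)


def field_calibration(spec, seed, n_strands=100, gate=(10.0, 1200.0)):
    cfg = calibration_field(spec, n_strands=n_strands, pitch_um=3.5,
                            kinetics=DESK_KINETICS, n_frames=DESK_N_FRAMES,
                            seed=seed)
    table, _ = simulate_acquisition(cfg)
    events = link_events(table, LinkingParams(30.0, 0))
    clusters, _ = cluster_events(events, eps_nm=100.0, min_events=3)
    accepted, _ = filter_single_strands(clusters, gate)
    return calibrate(accepted, size_gate_nm=gate)


def test_scale_invariance_of_counting(rng):
    """A global coordinate contraction (with gates scaled along) leaves the
    estimated DNA count bit-identical — counting is size-independent."""
    cfg = polyplex_field(PolyplexSpec(n_strands=8),
                         STRAND_PRESETS["linear500"], 25.0,
                         kinetics=DESK_KINETICS, n_frames=DESK_N_FRAMES,
                         seed=55)
    table, _ = simulate_acquisition(cfg)
    cal = make_calibration()
    base = count_one_field(table, cal)
    for s in (0.5, 0.55, 0.8, 1.0):
        df = table.records.assign(x=table.records.x * s, y=table.records.y * s)
        scaled = LocalizationTable(df, table.pixel_size_nm, table.n_frames)
        m = count_one_field(scaled, cal, link_gate=30.0 * s, eps=800.0 * s)
        assert m.n_linked == base.n_linked
        assert m.dna_count == base.dna_count  # bit-identical


def test_count_recovery_across_density_grid():
    """Recovery holds for sparse plasmid labeling (1.4%) and dense linear
    labeling (10%) alike."""
    grid = [
        (STRAND_PRESETS["linear500"], 71),
        (replace(STRAND_PRESETS["plasmid3527"], labeling_density=0.014), 72),
    ]
    for spec, seed in grid:
        cal = field_calibration(spec, seed, n_strands=60)
        for true_n in (2, 8):
            errs = []
            for rep in range(8):
                cfg = polyplex_field(PolyplexSpec(n_strands=true_n), spec,
                                     25.0, kinetics=DESK_KINETICS,
                                     n_frames=DESK_N_FRAMES,
                                     seed=seed * 1000 + true_n * 10 + rep)
                table, _ = simulate_acquisition(cfg)
                m = count_one_field(table, cal)
                errs.append(abs(m.dna_count - true_n) / true_n)
            assert np.median(errs) < 0.15, (spec.dna_type, true_n, errs)


def test_equal_mass_count_ratio_short_vs_long_dna():
    """At equal encapsulated DNA mass, short 500 bp strands outnumber
    3527 bp strands by the base-pair ratio (~7.05)."""
    short, long_ = STRAND_PRESETS["linear500"], STRAND_PRESETS["linear3527"]
    cal_short = field_calibration(short, 81, n_strands=60)
    cal_long = field_calibration(long_, 82, n_strands=60)
    means = {}
    for spec, cal, n_true, seed in [(short, cal_short, 28, 91),
                                    (long_, cal_long, 4, 92)]:
        counts = []
        for rep in range(8):
            cfg = polyplex_field(PolyplexSpec(n_strands=n_true), spec, 25.0,
                                 kinetics=DESK_KINETICS,
                                 n_frames=DESK_N_FRAMES, seed=seed * 100 + rep)
            table, _ = simulate_acquisition(cfg)
            counts.append(count_one_field(table, cal).dna_count)
        means[spec.dna_type] = np.mean(counts)
    ratio = means["linear500"] / means["linear3527"]
    assert ratio == pytest.approx(28 / 4, rel=0.15)


class TestCompareConditions:
    def test_summary_stats(self):
        ms = [PolyplexMeasurement(i, 0, c, None, 300.0, 1.6, 25.0, "linear500")
              for i, c in enumerate([30.0, 34.0])]
        summary, _ = compare_conditions(ms)
        row = summary.iloc[0]
        assert row["n"] == 2
        assert row["mean_dna_count"] == pytest.approx(32.0)
        assert row["sd_dna_count"] == pytest.approx(2.8284271, rel=1e-6)

    def test_pairwise_ratios_at_matched_conditions(self):
        ms = []
        for i, c in enumerate([30.0, 34.0]):
            ms.append(PolyplexMeasurement(i, 0, c, None, 300.0, 1.6, 25.0,
                                          "linear500"))
        for i, c in enumerate([4.0, 5.0]):
            ms.append(PolyplexMeasurement(10 + i, 0, c, None, 300.0, 1.6, 25.0,
                                          "linear3527"))
        _, ratios = compare_conditions(ms)
        r = ratios.set_index(["dna_type_num", "dna_type_den"])["count_ratio"]
        assert r[("linear500", "linear3527")] == pytest.approx(32.0 / 4.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([])


class TestNpRatio:
    def test_equal_molar_unity(self):
        dose = DoseSpec(dna_mass_conc=330.0, pei_mass_conc=43.1)
        assert np_ratio(dose) == pytest.approx(1.0)

    def test_linearity_in_pei(self):
        d1 = DoseSpec(3.0, 0.5)
        d2 = DoseSpec(3.0, 1.0)
        assert np_ratio(d2) == pytest.approx(2 * np_ratio(d1))

    def test_pei_mass_for_study_ratio(self):
        # hand-computed: 1.6 * (3/330) * 43.1 = 0.62691 ug/mL
        mass = pei_mass_for_np_ratio(1.6, 3.0)
        assert mass == pytest.approx(0.627, abs=5e-4)
        assert np_ratio(DoseSpec(3.0, mass)) == pytest.approx(1.6)

    def test_invalid_dose(self):
        with pytest.raises(ValueError):
            DoseSpec(0.0, 1.0)


class TestRender:
    def test_single_localization_single_hot_bin(self):
        table = make_table([0], [100.0], [50.0])
        img = render_image(table, bin_nm=20.0)
        assert img.sum() == 1.0 and img.max() == 1.0

    def test_no_clipping_at_max_density_one(self, rng):
        table = make_table(np.zeros(50, int), rng.uniform(0, 1000, 50),
                           rng.uniform(0, 1000, 50))
        a = render_image(table, 50.0, max_density=1.0)
        b = render_image(table, 50.0, max_density=1.0)
        np.testing.assert_array_equal(a, b)
        clipped = render_image(table, 50.0, max_density=0.25)
        assert clipped.max() == 1.0  # renormalized after clipping

    def test_mass_conservation_unclipped(self, rng):
        n = 500
        table = make_table(np.zeros(n, int), rng.uniform(0, 5000, n),
                           rng.uniform(0, 5000, n))
        raw = render_image(table, 100.0, normalize=False)
        assert raw.sum() == pytest.approx(n)
        blurred = render_image(table, 20.0, blur="gaussian-by-precision",
                               normalize=False)
        # Gaussian spreading redistributes but conserves mass (kernels
        # normalized on the truncated support)
        assert blurred.sum() == pytest.approx(n, rel=1e-6)
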