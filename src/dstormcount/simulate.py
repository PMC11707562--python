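"""Synthetic dSTORM acquisition generator with exact ground truth.

The generator emulates the study conditions end to end: labeled
double-stranded DNA (linear 500 bp and 3527 bp at ~10% labeling density,
3527 bp plasmid at 1.4-3.3%) laid out as 2D worm-like chains or closed
loops; polyplexes as core-shell spheres (DLS-scale radii, collapsing to
~0.55x between 25 and 37 degrees C) with shell-biased strand placement;
per-fluorophore two-state blinking at the 30 ms frame clock over 30 000
frames with 107 nm camera pixels; Gaussian localization noise; and a
Poisson false-localization background.  Every emitted localization is
attributable to exactly one ground-truth ON-burst or to the false-positive
pool, so each pipeline stage can be scored exactly.

ON and OFF dwell times are geometric (a discrete-time Markov chain at the
frame clock) with an additional per-ON-frame bleaching probability — a
deliberate simplification of continuous-time photophysics that preserves
what the counting pipeline sees: multi-frame bursts, duty cycles, and
finite photon budgets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import RISE_NM_PER_BP
from .exceptions import ConfigurationError
from .loc_io import (DEFAULT_EXPOSURE_MS, DEFAULT_N_FRAMES,
                     DEFAULT_PIXEL_SIZE_NM, LocalizationTable,
                     write_localizations)


@dataclass(frozen=True)
class StrandSpec:
    """Geometry and labeling of one DNA species."""

    dna_type: str
    bp: int
    labeling_density: float
    active_fraction: float = 0.7
    geometry: str = "worm-like-chain"  # or "closed-loop"
    persistence_nm: float = 50.0
    rise_nm_per_bp: float = RISE_NM_PER_BP

    def __post_init__(self) -> None:
        if self.bp <= 0:
            raise ValueError("bp must be > 0")
        if not 0 <= self.labeling_density <= 1:
            raise ValueError("labeling_density must be in [0, 1]")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.geometry not in ("worm-like-chain", "closed-loop"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


#: study presets: labeling densities within the experimentally stated ranges
STRAND_PRESETS = {
    "linear500": StrandSpec("linear500", 500, 0.10),
    "linear3527": StrandSpec("linear3527", 3527, 0.10),
    "plasmid3527": StrandSpec("plasmid3527", 3527, 0.023, geometry="closed-loop"),
}


@dataclass(frozen=True)
class PolyplexSpec:
    """Core-shell carrier architecture."""

    n_strands: int
    core_radius_nm: float = 300.0
    shell_thickness_nm: float = 80.0
    swelling: tuple = ((25.0, 1.0), (37.0, 0.55))
    dangling_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_strands < 0:
            raise ValueError("n_strands must be >= 0")
        if self.core_radius_nm <= 0 or self.shell_thickness_nm < 0:
            raise ValueError("radii must be positive")
        if not 0 <= self.dangling_fraction < 1:
            raise ValueError("dangling_fraction must be in [0, 1)")

    def swelling_factor(self, temperature_c: float) -> float:
        table = dict(self.swelling)
        if temperature_c in table:
            return table[temperature_c]
        raise ValueError(
            f"no swelling factor configured for {temperature_c} degC "
            f"(known: {sorted(table)})"
        )

    @property
    def outer_radius_nm(self) -> float:
        return self.core_radius_nm + self.shell_thickness_nm


@dataclass(frozen=True)
class KineticsSpec:
    """Discrete-time blinking kinetics at the frame clock."""

    p_initial_on: float = 0.0
    mean_on_frames: float = 2.0
    mean_off_frames: float = 2000.0
    bleach_prob_per_on_frame: float = 0.02
    false_localization_rate: float = 1e-5  # per frame per um^2
    precision_mean_nm: float = 10.0
    precision_sd_nm: float = 2.0
    mean_photons: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_initial_on <= 1:
            raise ValueError("p_initial_on must be a probability")
        if not 0 <= self.bleach_prob_per_on_frame <= 1:
            raise ValueError("bleach_prob_per_on_frame must be a probability")
        if self.mean_on_frames < 1 or self.mean_off_frames < 1:
            raise ValueError("mean dwell times must be >= 1 frame")

    @property
    def duty_cycle(self) -> float:
        return self.mean_on_frames / (self.mean_on_frames + self.mean_off_frames)


@dataclass
class AcquisitionConfig:
    """Full generative description of one synthetic acquisition.

    ``strands`` is a list of ``(StrandSpec, x_nm, y_nm)`` placements;
    ``polyplexes`` a list of ``(PolyplexSpec, StrandSpec, temperature_c,
    x_nm, y_nm)``.  A fixed ``seed`` makes the output bit-reproducible.
    """

    strands: list = field(default_factory=list)
    polyplexes: list = field(default_factory=list)
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    n_frames: int = DEFAULT_N_FRAMES
    exposure_ms: float = DEFAULT_EXPOSURE_MS
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    fov_um: float = 40.0
    seed: int = 0


# ---------------------------------------------------------------------------
# strand geometry


def _wlc_backbone(bp: int, rise_nm: float, persistence_nm: float, rng) -> np.ndarray:
    """2D worm-like chain sampled at one point per base pair."""
    sigma = np.sqrt(rise_nm / persistence_nm)
    turns = rng.normal(0.0, sigma, bp - 1) if bp > 1 else np.zeros(0)
    angles = rng.uniform(0, 2 * np.pi) + np.concatenate(([0.0], np.cumsum(turns)))
    steps = rise_nm * np.column_stack((np.cos(angles), np.sin(angles)))
    return np.vstack((np.zeros((1, 2)), np.cumsum(steps, axis=0)))[:bp]


def _loop_backbone(bp: int, rise_nm: float, rng) -> np.ndarray:
    """Closed supercoiled-loop caricature: harmonically perturbed ring
    rescaled to the DNA contour length."""
    contour = bp * rise_nm
    theta = np.linspace(0.0, 2 * np.pi, bp, endpoint=False)
    r = np.ones(bp)
    for k in range(2, 7):
        amp = rng.normal(0.0, 0.2 / k)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    pts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    closed = np.vstack((pts, pts[:1]))
    perimeter = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1)).sum()
    return pts * (contour / perimeter)


def place_fluorophores(spec: StrandSpec, rng) -> np.ndarray:
    """Sample active-fluorophore positions (nm) on one strand's contour.

    Each of the ``2 * bp`` nucleotides is labeled independently with
    probability ``labeling_density`` and photoactive with probability
    ``active_fraction``, so the expected count is
    ``2 * bp * labeling_density * active_fraction``.  Returned coordinates
    are centered on the strand centroid.
    """
    rng = np.random.default_rng(rng)
    if spec.geometry == "closed-loop":
        backbone = _loop_backbone(spec.bp, spec.rise_nm_per_bp, rng)
    else:
        backbone = _wlc_backbone(spec.bp, spec.rise_nm_per_bp,
                                 spec.persistence_nm, rng)
    n_nt = 2 * spec.bp
    active = rng.random(n_nt) < spec.labeling_density * spec.active_fraction
    sites = np.flatnonzero(active) % spec.bp
    pos = backbone[sites]
    return pos - backbone.mean(axis=0)


def build_polyplex(pspec: PolyplexSpec, sspec: StrandSpec,
                   temperature_c: float, rng, center=(0.0, 0.0)):
    """Assemble a carrier: strands at shell-biased radii, scaled by the
    temperature swelling factor.

    Returns ``(positions, truth)``: fluorophore coordinates (nm) and a
    truth record with the exact strand count and per-strand fluorophore
    index slices.
    """
    rng = np.random.default_rng(rng)
    factor = pspec.swelling_factor(temperature_c)
    rc, ro = pspec.core_radius_nm, pspec.outer_radius_nm
    positions, slices = [], []
    start = 0
    for _ in range(pspec.n_strands):
        # radius ~ r^2 density inside the 3D shell, projected to the plane
        u = rng.random()
        r3 = (rc ** 3 + u * (ro ** 3 - rc ** 3)) ** (1.0 / 3.0)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        anchor = r3 * v[:2]
        pts = place_fluorophores(sspec, rng)
        if pspec.dangling_fraction > 0 and sspec.geometry == "worm-like-chain":
            span = pts.max(axis=0) - pts.min(axis=0) if len(pts) else np.zeros(2)
            direction = anchor / max(np.linalg.norm(anchor), 1e-9)
            anchor = anchor + pspec.dangling_fraction * float(span.max()) * direction
        pts = pts + anchor
        positions.append(pts)
        slices.append((start, start + len(pts)))
        start += len(pts)
    all_pts = (np.vstack(positions) if positions else np.zeros((0, 2)))
    all_pts = all_pts * factor + np.asarray(center)
    truth = {
        "n_strands": pspec.n_strands,
        "temperature_c": temperature_c,
        "swelling_factor": factor,
        "strand_slices": slices,
        "outer_radius_nm": ro * factor,
    }
    return all_pts, truth


# ---------------------------------------------------------------------------
# blinking kinetics


def _sample_bursts(n_fluor: int, kin: KineticsSpec, n_frames: int, rng):
    """Vectorized ON-burst sampler.

    Returns ``(fluor_idx, start_frame, duration)`` for every burst that
    intersects the acquisition window, after bleaching and clipping.
    """
    if n_fluor == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z
    p_on = 1.0 / kin.mean_on_frames
    p_off = min(1.0, 1.0 / kin.mean_off_frames)
    mean_cycle = kin.mean_on_frames + kin.mean_off_frames
    k_cycles = int(np.ceil(2.0 * n_frames / mean_cycle
                           + 10.0 * np.sqrt(n_frames / mean_cycle) + 8))
    while True:
        on = rng.geometric(p_on, (n_fluor, k_cycles)).astype(np.int64)
        off = rng.geometric(p_off, (n_fluor, k_cycles)).astype(np.int64)
        init_on = rng.random(n_fluor) < kin.p_initial_on
        off[:, 0] = np.where(init_on, 0, off[:, 0])

        pb = kin.bleach_prob_per_on_frame
        if pb > 0:
            bleach_at = rng.geometric(pb, (n_fluor, k_cycles)).astype(np.int64)
            bleached = bleach_at <= on
            on_eff = np.where(bleached, bleach_at, on)
            any_b = bleached.any(axis=1)
            first_b = np.where(any_b, bleached.argmax(axis=1), k_cycles)
            alive = np.arange(k_cycles)[None, :] <= first_b[:, None]
        else:
            on_eff = on
            alive = np.ones((n_fluor, k_cycles), dtype=bool)

        on_cum = np.cumsum(on_eff, axis=1)
        start = np.cumsum(off, axis=1)
        start[:, 1:] += on_cum[:, :-1]

        exhausted = (start[:, -1] < n_frames) & alive[:, -1]
        if not exhausted.any():
            break
        k_cycles *= 2  # extremely rare: resample with more cycles

    valid = alive & (start < n_frames) & (on_eff > 0)
    dur = np.minimum(on_eff, n_frames - start)
    fi, ci = np.nonzero(valid)
    return fi.astype(np.int64), start[fi, ci], dur[fi, ci]


def simulate_acquisition(config: AcquisitionConfig):
    """Run one synthetic acquisition.

    Returns ``(table, truth)``.  ``truth`` holds the fluorophore field
    (positions, strand ids, object ids), the burst list (one entry per
    ground-truth blinking event) and, per localization id, the index of the
    burst that emitted it (-1 for false localizations).
    """
    rng = np.random.default_rng(config.seed)
    positions, strand_ids, object_ids, object_truth = [], [], [], []
    strand_counter = 0
    for obj_id, (spec, x, y) in enumerate(config.strands):
        pts = place_fluorophores(spec, rng) + np.array([x, y])
        positions.append(pts)
        strand_ids.append(np.full(len(pts), strand_counter))
        object_ids.append(np.full(len(pts), obj_id))
        object_truth.append({"kind": "strand", "dna_type": spec.dna_type,
                             "x": x, "y": y, "n_fluorophores": len(pts)})
        strand_counter += 1
    n_strand_objects = len(config.strands)
    for k, (pspec, sspec, temp, x, y) in enumerate(config.polyplexes):
        obj_id = n_strand_objects + k
        pts, ptruth = build_polyplex(pspec, sspec, temp, rng, center=(x, y))
        positions.append(pts)
        sid = np.full(len(pts), -1)
        for s, (a, b) in enumerate(ptruth["strand_slices"]):
            sid[a:b] = strand_counter + s
        strand_counter += pspec.n_strands
        strand_ids.append(sid)
        object_ids.append(np.full(len(pts), obj_id))
        ptruth.update({"kind": "polyplex", "dna_type": sspec.dna_type,
                       "x": x, "y": y, "n_fluorophores": len(pts)})
        object_truth.append(ptruth)

    fl_pos = np.vstack(positions) if positions else np.zeros((0, 2))
    fl_strand = (np.concatenate(strand_ids) if strand_ids
                 else np.zeros(0, dtype=np.int64))
    fl_object = (np.concatenate(object_ids) if object_ids
                 else np.zeros(0, dtype=np.int64))
    n_fluor = len(fl_pos)

    kin = config.kinetics
    fi, start, dur = _sample_bursts(n_fluor, kin, config.n_frames, rng)

    n_loc = int(dur.sum())
    reps = dur
    loc_fluor = np.repeat(fi, reps)
    burst_idx = np.repeat(np.arange(len(fi)), reps)
    ends = np.cumsum(reps)
    offsets = np.arange(n_loc) - np.repeat(ends - reps, reps)
    frames = np.repeat(start, reps) + offsets

    precision = np.clip(
        rng.normal(kin.precision_mean_nm, kin.precision_sd_nm, n_loc), 1.0, None
    )
    xy = fl_pos[loc_fluor] + rng.normal(0.0, 1.0, (n_loc, 2)) * precision[:, None]
    photons = rng.gamma(2.0, kin.mean_photons / 2.0, n_loc)

    # false localizations, Poisson over field x frames
    area_um2 = config.fov_um ** 2
    n_false = rng.poisson(kin.false_localization_rate * area_um2 * config.n_frames)
    f_frames = rng.integers(0, config.n_frames, n_false)
    f_xy = rng.uniform(0.0, config.fov_um * 1e3, (n_false, 2))
    f_prec = np.clip(
        rng.normal(kin.precision_mean_nm, kin.precision_sd_nm, n_false), 1.0, None
    )
    f_phot = rng.gamma(2.0, kin.mean_photons / 2.0, n_false)

    df = pd.DataFrame({
        "frame": np.concatenate((frames, f_frames)),
        "x": np.concatenate((xy[:, 0], f_xy[:, 0])),
        "y": np.concatenate((xy[:, 1], f_xy[:, 1])),
        "photons": np.concatenate((photons, f_phot)),
        "precision": np.concatenate((precision, f_prec)),
        "id": np.arange(n_loc + n_false, dtype=np.int64),
    })
    table = LocalizationTable(df, config.pixel_size_nm, config.n_frames,
                              config.exposure_ms).sorted_by_frame()

    loc_burst = np.concatenate(
        (burst_idx, np.full(n_false, -1, dtype=np.int64))
    )
    bursts = pd.DataFrame({
        "burst_id": np.arange(len(fi), dtype=np.int64),
        "fluorophore": fi,
        "strand": fl_strand[fi] if n_fluor else fi,
        "object": fl_object[fi] if n_fluor else fi,
        "first_frame": start,
        "n_frames": dur,
    })
    truth = {
        "fluor_positions": fl_pos,
        "fluor_strand": fl_strand,
        "fluor_object": fl_object,
        "objects": object_truth,
        "bursts": bursts,
        "loc_burst": loc_burst,  # indexed by localization id
        "n_false": int(n_false),
    }
    return table, truth


# ---------------------------------------------------------------------------
# canned experiments


def calibration_field(spec: StrandSpec, n_strands: int = 300,
                      pitch_um: float = 2.5, jitter_um: float = 0.2,
                      kinetics: KineticsSpec | None = None,
                      n_frames: int = DEFAULT_N_FRAMES,
                      seed: int = 0) -> AcquisitionConfig:
    """Dilute calibration acquisition: strands on a jittered grid.

    With ``pitch_um - 2 * jitter_um >= 2`` the minimum strand spacing stays
    at or above the 2 um the dilute calibration sample requires.
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_strands)))
    placements = []
    for i in range(n_strands):
        gx = (i % side + 0.5) * pitch_um * 1e3
        gy = (i // side + 0.5) * pitch_um * 1e3
        jx, jy = rng.uniform(-jitter_um * 1e3, jitter_um * 1e3, 2)
        placements.append((spec, gx + jx, gy + jy))
    return AcquisitionConfig(
        strands=placements,
        kinetics=kinetics or KineticsSpec(),
        n_frames=n_frames,
        fov_um=side * pitch_um,
        seed=int(rng.integers(2 ** 31)),
    )


def polyplex_field(pspec: PolyplexSpec, sspec: StrandSpec,
                   temperature_c: float = 25.0, n_polyplexes: int = 1,
                   pitch_um: float = 4.0,
                   kinetics: KineticsSpec | None = None,
                   n_frames: int = DEFAULT_N_FRAMES,
                   seed: int = 0) -> AcquisitionConfig:
    """Field of identical polyplexes on a grid (>= 3 um spacing)."""
    side = int(np.ceil(np.sqrt(n_polyplexes)))
    placements = [
        (pspec, sspec, temperature_c,
         (i % side + 0.5) * pitch_um * 1e3, (i // side + 0.5) * pitch_um * 1e3)
        for i in range(n_polyplexes)
    ]
    return AcquisitionConfig(
        polyplexes=placements,
        kinetics=kinetics or KineticsSpec(),
        n_frames=n_frames,
        fov_um=side * pitch_um,
        seed=seed,
    )


FIXTURE_PRESETS = ("calibration_500bp", "calibration_3527bp",
                   "calibration_plasmid", "polyplex_grid", "uptake_stack")


def make_fixture(name: str, seed: int, outdir, n_frames: int | None = None) -> dict:
    """Write a deterministic fixture (localization table + truth JSON).

    Returns a dict of output paths.  Identical ``(name, seed)`` produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "calibration_500bp":
        cfg = calibration_field(STRAND_PRESETS["linear500"], 300,
                                n_frames=n_frames or DEFAULT_N_FRAMES, seed=seed)
        return _write_table_fixture(cfg, outdir / name)
    if name == "calibration_3527bp":
        cfg = calibration_field(STRAND_PRESETS["linear3527"], 120, pitch_um=3.0,
                                n_frames=n_frames or DEFAULT_N_FRAMES, seed=seed)
        return _write_table_fixture(cfg, outdir / name)
    if name == "calibration_plasmid":
        cfg = calibration_field(STRAND_PRESETS["plasmid3527"], 120, pitch_um=3.0,
                                n_frames=n_frames or DEFAULT_N_FRAMES, seed=seed)
        return _write_table_fixture(cfg, outdir / name)
    if name == "polyplex_grid":
        paths = {}
        rng = np.random.default_rng(seed)
        for count in (2, 8, 32):
            for temp in (25.0, 37.0):
                sub = int(rng.integers(2 ** 31))
                cfg = polyplex_field(PolyplexSpec(n_strands=count),
                                     STRAND_PRESETS["linear500"], temp,
                                     n_frames=n_frames or DEFAULT_N_FRAMES,
                                     seed=sub)
                stem = outdir / f"{name}_n{count}_T{int(temp)}"
                paths.update(_write_table_fixture(cfg, stem))
        return paths
    if name == "uptake_stack":
        from . import uptake

        fixture = uptake.make_uptake_fixture(seed=seed)
        return uptake.write_uptake_fixture(fixture, outdir / name)
    raise ConfigurationError(f"unknown fixture preset {name!r}")


def _truth_json(cfg: AcquisitionConfig, truth: dict) -> dict:
    bursts = truth["bursts"]
    per_strand = bursts.groupby("strand").size() if len(bursts) else pd.Series(dtype=int)
    return {
        "seed": cfg.seed,
        "n_frames": cfg.n_frames,
        "n_fluorophores": int(len(truth["fluor_positions"])),
        "n_bursts": int(len(bursts)),
        "n_false": truth["n_false"],
        "objects": truth["objects"],
        "bursts_per_strand": {int(k): int(v) for k, v in per_strand.items()},
    }


def _write_table_fixture(cfg: AcquisitionConfig, stem: Path) -> dict:
    table, truth = simulate_acquisition(cfg)
    table_path = stem.with_suffix(".csv")
    truth_path = stem.parent / (stem.name + "_truth.json")
    write_localizations(table, table_path, dialect="csv")
    truth_path.write_text(json.dumps(_truth_json(cfg, truth), indent=1,
                                     sort_keys=True, default=_json_default))
    return {str(table_path): "table", str(truth_path): "truth"}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
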