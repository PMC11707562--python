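"""Polyplex-level DNA counting and condition comparison.

Carrier clusters are segmented from the blinking-event field, their
linked-localization totals are divided by the per-strand calibration
factor to give DNA copy numbers, and a disc-equivalent radius is estimated
from the planar radius of gyration.  Conditions (N/P ratio, temperature,
DNA type) are compared as per-condition means with standard deviations and
pairwise DNA-type ratios.

The confidence interval on a copy number propagates three error sources in
quadrature (relative variance):

* ``cv^2 / n_strands`` — uncertainty of the calibration mean itself;
* ``cv^2 / dna_count`` — strand-to-strand heterogeneity: each encapsulated
  strand contributes an independent draw from the calibration distribution;
* ``1 / n_linked`` — Poisson counting floor on the localization total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import StrandCalibration, StrandCluster, cluster_events
from .exceptions import DegenerateInputError

#: molar mass per protonatable amine of branched PEI, g/mol (common convention)
PEI_REPEAT_MASS = 43.1
#: average molar mass per nucleotide phosphate of DNA, g/mol
DNA_PHOSPHATE_MASS = 330.0

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class PolyplexMeasurement:
    """One segmented carrier with its estimated DNA load."""

    cluster_id: int
    n_linked: int
    dna_count: float
    dna_count_ci: tuple | None
    radius_nm: float
    np_ratio: float | None = None
    temperature_c: float | None = None
    dna_type: str | None = None


@dataclass
class DoseSpec:
    """Mass concentrations defining a polyplex formulation."""

    dna_mass_conc: float  # µg/mL
    pei_mass_conc: float  # µg/mL
    pei_repeat_mass: float = PEI_REPEAT_MASS  # g/mol per protonatable amine
    dna_phosphate_mass: float = DNA_PHOSPHATE_MASS  # g/mol per nucleotide

    def __post_init__(self) -> None:
        for name in ("dna_mass_conc", "pei_mass_conc", "pei_repeat_mass",
                     "dna_phosphate_mass"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def np_ratio(dose: DoseSpec) -> float:
    """Molar amine-nitrogen to phosphate ratio of a formulation."""
    n_molar = dose.pei_mass_conc / dose.pei_repeat_mass
    p_molar = dose.dna_mass_conc / dose.dna_phosphate_mass
    return n_molar / p_molar


def pei_mass_for_np_ratio(target_np: float, dna_mass_conc: float,
                          pei_repeat_mass: float = PEI_REPEAT_MASS,
                          dna_phosphate_mass: float = DNA_PHOSPHATE_MASS) -> float:
    """PEI mass concentration (µg/mL) that realizes a target N/P ratio."""
    if not target_np > 0 or not dna_mass_conc > 0:
        raise ValueError("target ratio and DNA concentration must be > 0")
    return target_np * (dna_mass_conc / dna_phosphate_mass) * pei_repeat_mass


def segment_polyplexes(events, eps_nm: float, min_events: int,
                       min_extent_nm: float = 300.0,
                       uncomplexed_max_linked: float | None = None):
    """Segment carrier clusters from an event field.

    Density clusters with extent >= ``min_extent_nm`` are polyplexes;
    smaller clusters (residual uncomplexed DNA) go to the ``uncomplexed``
    set.  If ``uncomplexed_max_linked`` is given, a small-extent cluster
    with more linked localizations than that bound is still treated as a
    polyplex (a compact but heavily loaded carrier).

    Returns ``(polyplexes, uncomplexed, noise)``.
    """
    if eps_nm <= 0 or min_events < 1 or min_extent_nm < 0:
        raise ValueError("segmentation parameters must be positive")
    clusters, noise = cluster_events(events, eps_nm=eps_nm, min_events=min_events)
    polyplexes, uncomplexed = [], []
    for cl in clusters:
        if cl.extent_nm >= min_extent_nm:
            polyplexes.append(cl)
        elif (uncomplexed_max_linked is not None
              and cl.n_linked > uncomplexed_max_linked):
            polyplexes.append(cl)
        else:
            uncomplexed.append(cl)
    return polyplexes, uncomplexed, noise


def estimate_dna_count(cluster: StrandCluster, calibration: StrandCalibration,
                       cluster_id: int = 0, np_ratio: float | None = None,
                       temperature_c: float | None = None,
                       dna_type: str | None = None) -> PolyplexMeasurement:
    """Convert a cluster's linked-localization total into a DNA copy number."""
    if not calibration.mean_linked > 0:
        raise ValueError("calibration mean_linked must be > 0")
    n_linked = cluster.n_linked
    count = n_linked / calibration.mean_linked

    ci = None
    degenerate = calibration.n_strands < 2 or not np.isfinite(calibration.cv)
    if n_linked == 0:
        ci = (0.0, 0.0)
    elif degenerate:
        warnings.warn(
            "degenerate calibration (n_strands < 2 or undefined CV); "
            "returning point estimate without CI"
        )
    else:
        rel_var = (calibration.cv ** 2 / calibration.n_strands
                   + calibration.cv ** 2 / count
                   + 1.0 / n_linked)
        half = _Z95 * count * np.sqrt(rel_var)
        ci = (max(0.0, count - half), count + half)

    radius = np.sqrt(2.0) * cluster.rg_nm
    return PolyplexMeasurement(cluster_id, n_linked, count, ci, radius,
                               np_ratio, temperature_c, dna_type)


def estimate_radius(cluster: StrandCluster) -> float:
    """Disc-equivalent radius: sqrt(2) x planar radius of gyration.

    For events uniform on a disc of radius R the radius of gyration is
    R/sqrt(2), so the estimate converges to R.
    """
    if cluster.n_linked < 3:
        raise DegenerateInputError("radius undefined for clusters with < 3 events")
    r = np.sqrt(2.0) * cluster.rg_nm
    if r == 0.0:
        warnings.warn("all events coincident; radius is degenerate (0)")
    return float(r)


def measurements_to_dataframe(measurements) -> pd.DataFrame:
    rows = []
    for m in measurements:
        lo, hi = (m.dna_count_ci if m.dna_count_ci is not None else (np.nan, np.nan))
        rows.append({
            "cluster_id": m.cluster_id, "n_linked": m.n_linked,
            "dna_count": m.dna_count, "dna_count_lo": lo, "dna_count_hi": hi,
            "radius_nm": m.radius_nm, "np_ratio": m.np_ratio,
            "temperature_c": m.temperature_c, "dna_type": m.dna_type,
        })
    return pd.DataFrame(rows)


def compare_conditions(measurements):
    """Per-condition summary and pairwise DNA-type ratios.

    Returns ``(summary, ratios)``: ``summary`` has one row per
    (dna_type, np_ratio, temperature_c) with n, mean dna_count and sample
    SD; ``ratios`` has one row per ordered DNA-type pair at matched
    (np_ratio, temperature_c) with the ratio of mean counts.
    """
    df = measurements_to_dataframe(measurements)
    if len(df) == 0:
        raise ValueError("need at least one measurement")
    keys = ["dna_type", "np_ratio", "temperature_c"]
    summary = (
        df.groupby(keys, dropna=False)["dna_count"]
        .agg(n="count", mean_dna_count="mean", sd_dna_count=lambda s: s.std(ddof=1))
        .reset_index()
    )
    ratio_rows = []
    for (npr, temp), grp in summary.groupby(["np_ratio", "temperature_c"],
                                            dropna=False):
        types = list(grp["dna_type"])
        for a in types:
            for b in types:
                if a == b:
                    continue
                ma = float(grp.loc[grp["dna_type"] == a, "mean_dna_count"].iloc[0])
                mb = float(grp.loc[grp["dna_type"] == b, "mean_dna_count"].iloc[0])
                if mb > 0:
                    ratio_rows.append({
                        "np_ratio": npr, "temperature_c": temp,
                        "dna_type_num": a, "dna_type_den": b,
                        "count_ratio": ma / mb,
                    })
    ratios = pd.DataFrame(ratio_rows)
    return summary, ratios


def render_image(source, bin_nm: float, blur: str = "none",
                 max_density: float = 1.0, normalize: bool = True,
                 extent=None) -> np.ndarray:
    """Render localizations or events as a 2D histogram image.

    Parameters
    ----------
    source : LocalizationTable or sequence of BlinkEvent
    bin_nm : bin width of the rendering grid, nm.
    blur : {'none', 'gaussian-by-precision'}
        Optional per-localization Gaussian spreading by its precision.
    max_density : float in (0, 1]
        Display clip: values above ``max_density x max bin`` are clipped
        before normalization to [0, 1] (the rendering convention of SMLM
        viewers).  1.0 means no clipping.
    normalize : bool
        If False, return the raw (possibly blurred/clipped) histogram whose
        total mass equals the localization count.
    """
    if not bin_nm > 0:
        raise ValueError("bin_nm must be > 0")
    if not 0 < max_density <= 1:
        raise ValueError("max_density must be in (0, 1]")
    if hasattr(source, "records"):
        xs = source.records["x"].to_numpy()
        ys = source.records["y"].to_numpy()
        prec = source.records["precision"].to_numpy()
    else:
        xs = np.array([ev.x for ev in source])
        ys = np.array([ev.y for ev in source])
        prec = np.full(len(xs), 10.0)
    if len(xs) == 0:
        return np.zeros((1, 1))
    if extent is None:
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
    else:
        x0, x1, y0, y1 = extent
    nx = max(1, int(np.ceil((x1 - x0) / bin_nm)) + 1)
    ny = max(1, int(np.ceil((y1 - y0) / bin_nm)) + 1)
    img = np.zeros((ny, nx))
    if blur == "none":
        ix = np.clip(((xs - x0) / bin_nm).astype(int), 0, nx - 1)
        iy = np.clip(((ys - y0) / bin_nm).astype(int), 0, ny - 1)
        np.add.at(img, (iy, ix), 1.0)
    elif blur == "gaussian-by-precision":
        gx = x0 + np.arange(nx) * bin_nm
        gy = y0 + np.arange(ny) * bin_nm
        for x, y, s in zip(xs, ys, prec):
            half = 4.0 * s
            jx = np.flatnonzero(np.abs(gx - x) <= half)
            jy = np.flatnonzero(np.abs(gy - y) <= half)
            if len(jx) == 0 or len(jy) == 0:
                continue
            kx = np.exp(-0.5 * ((gx[jx] - x) / s) ** 2)
            ky = np.exp(-0.5 * ((gy[jy] - y) / s) ** 2)
            kern = np.outer(ky, kx)
            img[np.ix_(jy, jx)] += kern / kern.sum()
    else:
        raise ValueError(f"unknown blur mode {blur!r}")
    if img.max() > 0 and max_density < 1.0:
        img = np.minimum(img, max_density * img.max())
    if normalize and img.max() > 0:
        img = img / img.max()
    return img
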