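"""Per-strand calibration: linked localizations per isolated DNA strand.

A dilute acquisition of labeled DNA, in which every strand is well
separated from its neighbors, is segmented into density-based clusters of
blinking events.  Clusters whose spatial extent is compatible with a single
strand (size gates taken from AFM measurements of the same DNA) are
accepted; aggregates and double counts are rejected.  The accepted
clusters' linked-localization histogram yields the calibration factor —
mean linked localizations per strand — that converts a carrier's
localization total into a DNA copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .exceptions import CalibrationError
from .linking import BlinkEvent

#: helical rise of B-form double-stranded DNA, nm per base pair
RISE_NM_PER_BP = 0.34

#: default single-strand extent gates (nm) per DNA type, from AFM/dSTORM sizes
SIZE_GATES_NM = {
    "linear500": (50.0, 200.0),
    "linear3527": (50.0, 1000.0),
    "plasmid3527": (50.0, 500.0),
}


@dataclass
class StrandCluster:
    """A density-based cluster of blinking events (candidate single strand)."""

    events: list
    x: float
    y: float
    extent_nm: float
    rg_nm: float

    @property
    def n_linked(self) -> int:
        return len(self.events)

    @classmethod
    def from_events(cls, events: list) -> "StrandCluster":
        pts = np.array([(ev.x, ev.y) for ev in events])
        centroid = pts.mean(axis=0)
        if len(pts) > 1:
            extent = float(pdist(pts).max())
        else:
            extent = 0.0
        rg = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
        return cls(list(events), float(centroid[0]), float(centroid[1]), extent, rg)


@dataclass
class StrandCalibration:
    """Linked-localization statistics over accepted single strands."""

    histogram: dict
    n_strands: int
    mean_linked: float
    median_linked: float
    cv: float
    size_gate_nm: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_strands != sum(self.histogram.values()):
            raise ValueError("histogram mass must equal n_strands")
        if self.n_strands > 0 and not self.mean_linked > 0:
            raise ValueError("mean_linked must be > 0 for a non-empty calibration")

    def to_dict(self) -> dict:
        return {
            "histogram": {int(k): int(v) for k, v in sorted(self.histogram.items())},
            "n_strands": int(self.n_strands),
            "mean_linked": float(self.mean_linked),
            "median_linked": float(self.median_linked),
            "cv": float(self.cv),
            "size_gate_nm": list(self.size_gate_nm) if self.size_gate_nm else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrandCalibration":
        gate = tuple(d["size_gate_nm"]) if d.get("size_gate_nm") else None
        return cls({int(k): int(v) for k, v in d["histogram"].items()},
                   int(d["n_strands"]), float(d["mean_linked"]),
                   float(d["median_linked"]), float(d["cv"]), gate)


def cluster_events(events, eps_nm: float = 100.0, min_events: int = 5):
    """Density-cluster blinking events by their centroids (DBSCAN semantics).

    Returns ``(clusters, noise)``; every event lands in exactly one cluster
    or in the noise list.
    """
    if not eps_nm > 0:
        raise ValueError("eps_nm must be > 0")
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if len(events) == 0:
        return [], []
    pts = np.array([(ev.x, ev.y) for ev in events])
    labels = DBSCAN(eps=eps_nm, min_samples=min_events).fit_predict(pts)
    clusters = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        members = [events[i] for i in np.flatnonzero(labels == lab)]
        clusters.append(StrandCluster.from_events(members))
    noise = [events[i] for i in np.flatnonzero(labels == -1)]
    return clusters, noise


def filter_single_strands(clusters, size_gate_nm=(50.0, 200.0),
                          n_linked_gate=(1, None)):
    """Accept clusters compatible with one DNA strand; report rejections.

    ``size_gate_nm`` bounds the cluster extent (max pairwise span);
    ``n_linked_gate`` optionally bounds the linked-localization count (upper
    bound ``None`` = unbounded).  Returns ``(accepted, rejected)`` where
    ``rejected`` is a list of ``(cluster, reason)`` pairs.
    """
    lo, hi = size_gate_nm
    if hi is not None and lo > hi:
        raise ValueError("size gate must be ordered (min <= max)")
    nlo, nhi = n_linked_gate
    if nhi is not None and nlo > nhi:
        raise ValueError("n_linked gate must be ordered (min <= max)")
    accepted, rejected = [], []
    for cl in clusters:
        if cl.extent_nm < lo:
            rejected.append((cl, "extent below size gate"))
        elif hi is not None and cl.extent_nm > hi:
            rejected.append((cl, "extent above size gate (aggregate/double count)"))
        elif cl.n_linked < nlo:
            rejected.append((cl, "too few linked localizations"))
        elif nhi is not None and cl.n_linked > nhi:
            rejected.append((cl, "too many linked localizations"))
        else:
            accepted.append(cl)
    return accepted, rejected


def calibrate(clusters, size_gate_nm=None) -> StrandCalibration:
    """Summarize accepted single-strand clusters into a calibration factor."""
    if len(clusters) == 0:
        raise CalibrationError("no accepted single-strand clusters to calibrate on")
    counts = np.array([cl.n_linked for cl in clusters], dtype=np.int64)
    hist: dict = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    mean = float(counts.mean())
    median = float(np.median(counts))
    cv = float(counts.std(ddof=1) / mean) if len(counts) > 1 else float("nan")
    return StrandCalibration(hist, len(counts), mean, median, cv, size_gate_nm)


def expected_fluorophores(bp: int, labeling_density: float) -> float:
    """Expected fluorophore count of a double-stranded DNA molecule.

    Double-stranded DNA carries two nucleotides per base pair, so the
    expectation is ``2 * bp * labeling_density``.
    """
    if bp <= 0:
        raise ValueError("bp must be > 0")
    if not 0 < labeling_density <= 1:
        raise ValueError("labeling_density must be in (0, 1]")
    return 2.0 * bp * labeling_density


def contour_length(bp: int) -> float:
    """Contour length of double-stranded DNA in nm (0.34 nm per base pair)."""
    if bp <= 0:
        raise ValueError("bp must be > 0")
    return bp * RISE_NM_PER_BP
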