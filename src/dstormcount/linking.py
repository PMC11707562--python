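"""Merge per-frame localizations into blinking events ("linked localizations").

A fluorophore that stays ON for several camera frames produces one
localization per frame; counting raw localizations therefore over-counts
emitters.  This module merges runs of localizations that appear in
consecutive (or nearly consecutive, up to a dark-frame tolerance) frames at
the same position into single :class:`BlinkEvent` objects.  One merged event
is one *linked localization*, the unit in which all downstream counting is
expressed.

Linking is greedy in frame order: an open event is extended by the nearest
localization in the next non-dark frame that lies within
``max_distance_nm`` of the event's running centroid; ties are broken by
smallest distance, then lowest row id.  An event accepts at most one
localization per frame (one emitter emits once per frame).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loc_io import LocalizationTable


@dataclass(frozen=True)
class LinkingParams:
    """Gates of the linker.

    max_distance_nm : spatial gate between a localization and the running
        event centroid.
    max_dark_frames : number of OFF frames tolerated inside one event
        (0 = strictly consecutive frames).
    weight_by_photons : if True the running centroid is photon-weighted.
    """

    max_distance_nm: float
    max_dark_frames: int = 0
    weight_by_photons: bool = False

    def __post_init__(self) -> None:
        if not self.max_distance_nm > 0:
            raise ValueError("max_distance_nm must be > 0")
        if self.max_dark_frames < 0:
            raise ValueError("max_dark_frames must be >= 0")

    @staticmethod
    def from_table(table: LocalizationTable, k_sigma: float = 3.0,
                   max_dark_frames: int = 0) -> "LinkingParams":
        """Default spatial gate: ``k_sigma`` x median localization precision."""
        med = float(np.median(table.records["precision"])) if len(table) else 10.0
        return LinkingParams(max_distance_nm=k_sigma * med,
                             max_dark_frames=max_dark_frames)


@dataclass(slots=True)
class BlinkEvent:
    """A run of localizations from one ON period of one fluorophore."""

    first_frame: int
    last_frame: int
    n_frames: int
    x: float
    y: float
    total_photons: float
    member_ids: list

    def __post_init__(self) -> None:
        if not (self.last_frame - self.first_frame + 1 >= self.n_frames >= 1):
            raise ValueError("inconsistent frame span for blink event")


class _OpenEvent:
    __slots__ = ("sx", "sy", "wx", "wy", "w", "n", "first", "last",
                 "photons", "ids")

    def __init__(self, frame, x, y, photons, loc_id, weighted):
        w = photons if weighted and photons > 0 else 1.0
        self.sx, self.sy = x, y
        self.wx, self.wy, self.w = w * x, w * y, w
        self.n = 1
        self.first = self.last = frame
        self.photons = photons
        self.ids = [loc_id]

    def centroid(self, weighted):
        if weighted:
            return self.wx / self.w, self.wy / self.w
        return self.sx / self.n, self.sy / self.n

    def extend(self, frame, x, y, photons, loc_id, weighted):
        w = photons if weighted and photons > 0 else 1.0
        self.sx += x
        self.sy += y
        self.wx += w * x
        self.wy += w * y
        self.w += w
        self.n += 1
        self.last = frame
        self.photons += photons
        self.ids.append(loc_id)

    def close(self, weighted) -> BlinkEvent:
        cx, cy = self.centroid(weighted)
        return BlinkEvent(self.first, self.last, self.n, cx, cy,
                          self.photons, list(self.ids))


def link_events(table: LocalizationTable, params: LinkingParams | None = None
                ) -> list[BlinkEvent]:
    """Link localizations in consecutive frames into blinking events.

    Every localization is assigned to exactly one event.  Returned events
    are ordered by (first_frame, lowest member id).
    """
    if params is None:
        params = LinkingParams.from_table(table)
    df = table.records
    if len(df) == 0:
        return []
    # stable sort: frame ascending, then id (row order) for tie-breaking
    df = df.sort_values(["frame", "id"], kind="stable")
    frames = df["frame"].to_numpy()
    xs = df["x"].to_numpy()
    ys = df["y"].to_numpy()
    phot = df["photons"].to_numpy()
    ids = df["id"].to_numpy()

    weighted = params.weight_by_photons
    gate2 = params.max_distance_nm ** 2
    max_gap = params.max_dark_frames + 1

    open_events: list[_OpenEvent] = []
    done: list[BlinkEvent] = []

    boundaries = np.flatnonzero(np.diff(frames)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(frames)]))

    for s, e in zip(starts, stops):
        f = int(frames[s])
        # retire events that can no longer be extended at frame f
        still_open = []
        for ev in open_events:
            if f - ev.last > max_gap:
                done.append(ev.close(weighted))
            else:
                still_open.append(ev)
        open_events = still_open

        idx = range(s, e)
        cand = [ev for ev in open_events if ev.last < f]  # one loc per frame
        if cand:
            cents = np.array([ev.centroid(weighted) for ev in cand])
            lx, ly = xs[s:e], ys[s:e]
            d2 = (cents[:, 0:1] - lx[None, :]) ** 2 + (cents[:, 1:2] - ly[None, :]) ** 2
            ei, li = np.nonzero(d2 <= gate2)
            order = np.lexsort((li, ei, d2[ei, li]))  # distance, event order, id
            used_ev = set()
            used_loc = set()
            for k in order:
                a, b = int(ei[k]), int(li[k])
                if a in used_ev or b in used_loc:
                    continue
                used_ev.add(a)
                used_loc.add(b)
                j = s + b
                cand[a].extend(f, xs[j], ys[j], phot[j], int(ids[j]), weighted)
            idx = [j for j in range(s, e) if (j - s) not in used_loc]
        for j in idx:
            open_events.append(
                _OpenEvent(f, xs[j], ys[j], phot[j], int(ids[j]), weighted)
            )

    done.extend(ev.close(weighted) for ev in open_events)
    done.sort(key=lambda ev: (ev.first_frame, min(ev.member_ids)))
    return done


def event_count(events) -> int:
    """Number of linked localizations (one merged blinking event each)."""
    return len(events)


def dwell_time_distribution(events) -> Counter:
    """Histogram of ON durations (``n_frames``) over events.

    Total mass equals the event count.
    """
    return Counter(ev.n_frames for ev in events)


def events_to_dataframe(events) -> pd.DataFrame:
    """Tabulate events (one row per blinking event) for export or clustering."""
    return pd.DataFrame(
        {
            "first_frame": [ev.first_frame for ev in events],
            "last_frame": [ev.last_frame for ev in events],
            "n_frames": [ev.n_frames for ev in events],
            "x": [ev.x for ev in events],
            "y": [ev.y for ev in events],
            "total_photons": [ev.total_photons for ev in events],
            "member_ids": [";".join(map(str, ev.member_ids)) for ev in events],
        }
    )
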