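"""Independent reference implementations used only to check the package.

These deliberately re-derive results by brute force (exhaustive pairwise
closure, index-ordered textbook DBSCAN, direct histogram iteration) so that
agreement with the package is a two-route check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def closure_link_partition(table, max_distance_nm, max_dark_frames=0):
    """Exhaustive transitive-closure linker over all localization pairs.

    Two localizations are related when their frame gap is between 1 and
    1 + max_dark_frames and their distance is within the spatial gate;
    events are the connected components of that relation.  Returns the
    partition as a set of frozensets of row ids.
    """
    df = table.records
    n = len(df)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    f = df["frame"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            gap = abs(int(f[i]) - int(f[j]))
            if 1 <= gap <= 1 + max_dark_frames:
                if np.hypot(x[i] - x[j], y[i] - y[j]) <= max_distance_nm:
                    union(i, j)
    ids = df["id"].to_numpy()
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(int(ids[i]))
    return {frozenset(g) for g in groups.values()}


def events_partition(events):
    """Partition induced by a list of BlinkEvents (member-id sets)."""
    return {frozenset(ev.member_ids) for ev in events}


def naive_dbscan(points, eps, min_samples):
    """Textbook DBSCAN, index-ordered expansion; labels like sklearn's."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    neighbors = [np.flatnonzero(d2[i] <= eps ** 2) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if not core[i]:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        stack = list(neighbors[i])
        while stack:
            j = stack.pop()
            if labels[j] == -1:
                labels[j] = cluster
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if core[j]:
                stack.extend(neighbors[j])
    labels[labels == -2] = -1
    return labels


def label_partition(labels):
    """Cluster membership sets (noise excluded) from a label vector."""
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == lab).tolist())
            for lab in np.unique(labels) if lab != -1}


def intermeans_by_direct_iteration(values):
    """Iterative intermeans on the raw value array (no histogram)."""
    vals = np.asarray(values, dtype=float).ravel()
    t = float(np.floor(vals.mean()))
    t = min(max(t, vals.min()), vals.max() - 1)
    for _ in range(10_000):
        m1 = vals[vals <= t].mean()
        m2 = vals[vals > t].mean()
        t_new = np.floor((m1 + m2) / 2.0)
        t_new = min(max(t_new, vals.min()), vals.max() - 1)
        if t_new == t:
            break
        t = t_new
    return int(t) + 1


def random_link_instance(rng, n_max=100, gate_nm=60.0, max_dark=0,
                         field_nm=8000.0, n_frames=400):
    """Random burst-structured linking instance.

    Fluorophores are separated by at least five spatial gates and their
    bursts by more dark frames than the tolerance, while within-burst
    jitter is far below the gate — a regime in which greedy frame-ordered
    linking and pairwise transitive closure provably coincide, as in a
    dilute dSTORM acquisition.
    """
    n_fluor = int(rng.integers(2, 10))
    pts = []
    tries = 0
    while len(pts) < n_fluor and tries < 1000:
        cand = rng.uniform(0, field_nm, 2)
        if all(np.hypot(*(cand - p)) > 5 * gate_nm for p in pts):
            pts.append(cand)
        tries += 1
    rows = []
    for fx, fy in pts:
        t = int(rng.integers(0, 30))
        for _ in range(int(rng.integers(1, 5))):
            dur = int(rng.integers(1, 6))
            for k in range(dur):
                if t + k >= n_frames or len(rows) >= n_max:
                    break
                jx, jy = rng.normal(0, gate_nm / 8.0, 2)
                rows.append((t + k, fx + jx, fy + jy))
            t += dur + max_dark + 2 + int(rng.integers(0, 20))
    # sprinkle isolated singletons
    for _ in range(int(rng.integers(0, 6))):
        if len(rows) >= n_max:
            break
        rows.append((int(rng.integers(0, n_frames)),
                     rng.uniform(0, field_nm), rng.uniform(0, field_nm)))
    df = pd.DataFrame(rows, columns=["frame", "x", "y"])
    df["photons"] = 1000.0
    df["precision"] = 10.0
    df["id"] = np.arange(len(df))
    return df
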