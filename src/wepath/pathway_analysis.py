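"""Transition-path-ensemble extraction and descriptive pathway analyses.

A transition path is the portion of a trajectory from its *last* exit of
the initial (unbound) state to its *first* entry into the target (bound)
state — the transient states along a productive binding pathway.  The
weighted-ensemble run records every segment's parent, so the transition
path ensemble (TPE) is recovered by walking each bound-arriving lineage
backwards to its most recent unbound frame.  The weight of a TPE
conformation is the summed weight of the successful arrivals descending
through it.

On top of the TPE this module provides: event-duration (barrier-crossing
time) distributions; weighted contact-probability maps; a weighted
histogram conformational entropy; greedy k-centers clustering with a
Canberra metric and the conformation space network (CSN) built from the
cluster assignments; and equal-area spherical histograms of ligand entry
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "TransitionPath",
    "extract_tpe",
    "tpe_frame_weights",
    "DurationStats",
    "event_durations",
    "weighted_contact_probabilities",
    "histogram_entropy",
    "entropy_bin_scan",
    "canberra",
    "kcenters",
    "build_csn",
    "spherical_entry_map",
    "extract_entry_directions",
]


@dataclass
class TransitionPath:
    """One productive path: ordered (iteration, segment) frame references
    from the frame after the last unbound visit through the first bound
    frame, with the weight of the arriving walker."""

    frames: list[tuple[int, int]]
    weight: float
    root: int
    tau: float
    encounter_flags: list[bool] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return self.n_frames * self.tau


def extract_tpe(records, defs, tau: float) -> list[TransitionPath]:
    """All transition paths ending in a first entry into the target state.

    ``records`` is the iteration-record list of a run (equilibrium mode;
    recycling truncates lineages at each restart).  Lineages that never
    reach the target contribute nothing; no arrivals yields an empty
    list.  Paths with distinct ``root`` values descend from different
    initial-ensemble members and are statistically independent.
    """
    by_iter = {r.iteration: k for k, r in enumerate(records)}
    paths = []
    for k, rec in enumerate(records):
        for seg_idx, to_state, weight, _prev, prev_hist in rec.arrivals:
            if to_state != defs.target or prev_hist != "U":
                continue
            frames = [(rec.iteration, seg_idx)]
            flags = [str(rec.state_labels[seg_idx]) == "encounter"]
            t_k, idx = k, seg_idx
            while True:
                parent = int(records[t_k].parent_idx[idx])
                if parent < 0 or t_k == 0:
                    break
                t_k -= 1
                prev_rec = records[t_k]
                if str(prev_rec.state_labels[parent]) == defs.initial or bool(
                    prev_rec.recycled_flags[parent]
                ):
                    break
                frames.append((prev_rec.iteration, parent))
                flags.append(str(prev_rec.state_labels[parent]) == "encounter")
                idx = parent
            frames.reverse()
            flags.reverse()
            paths.append(
                TransitionPath(
                    frames=frames,
                    weight=float(weight),
                    root=int(rec.roots[seg_idx]),
                    tau=tau,
                    encounter_flags=flags,
                )
            )
    return paths


def tpe_frame_weights(paths: list[TransitionPath]) -> dict[tuple[int, int], float]:
    """Weight of each TPE conformation: sum over the arrival weights of
    all successful paths passing through it."""
    out: dict[tuple[int, int], float] = {}
    for p in paths:
        for fr in p.frames:
            out[fr] = out.get(fr, 0.0) + p.weight
    return out


@dataclass
class DurationStats:
    durations: np.ndarray
    weights: np.ndarray
    hist: np.ndarray
    edges: np.ndarray
    mode: float
    bin_width: float

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def event_durations(
    paths: list[TransitionPath], bin_width: float | None = None
) -> DurationStats:
    """Weighted distribution of barrier-crossing (event) durations."""
    if not paths:
        raise ValueError("empty transition path ensemble")
    durations = np.array([p.duration for p in paths])
    weights = np.array([p.weight for p in paths])
    tau = paths[0].tau
    if bin_width is None:
        bin_width = tau
    edges = np.arange(0.0, durations.max() + 2 * bin_width, bin_width)
    hist, edges = np.histogram(durations, bins=edges, weights=weights)
    mode = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    return DurationStats(durations, weights, hist, edges, mode, bin_width)


def weighted_contact_probabilities(
    distances: np.ndarray, weights: np.ndarray, cutoff: float = 4.5
) -> np.ndarray:
    """Per-pair contact probability over weighted TPE frames.

    ``distances`` is (n_frames, n_pairs); a pair is in contact in a
    frame when its distance is <= cutoff.  The probability is the summed
    weight of in-contact frames over the total TPE weight.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    w = np.asarray(weights, dtype=float)
    if len(w) != len(d):
        raise ValueError("one weight per frame required")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return (w[:, None] * (d <= cutoff)).sum(axis=0) / total


def histogram_entropy(
    samples: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = 20,
    hist_range=None,
) -> float:
    """Shannon entropy of a weighted histogram, in units of R.

    S/R = -sum_i p_i ln p_i over occupied cells of an ``n_bins``-per-axis
    histogram of the samples (scalars or angle vectors).  All-identical
    samples occupy a single cell and give exactly 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if weights is None:
        weights = np.ones(len(x))
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    if np.all(np.ptp(x, axis=0) == 0):
        return 0.0
    hist, _ = np.histogramdd(x, bins=n_bins, range=hist_range, weights=w)
    p = hist.ravel() / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def entropy_bin_scan(
    samples, weights=None, bin_counts=range(15, 36)
) -> pd.DataFrame:
    """Entropy across a range of histogram resolutions (stability check)."""
    rows = [
        {"n_bins": nb, "entropy_R": histogram_entropy(samples, weights, nb)}
        for nb in bin_counts
    ]
    return pd.DataFrame(rows)


def canberra(u: np.ndarray, v: np.ndarray) -> float:
    """Canberra distance sum_i |u_i - v_i| / (|u_i| + |v_i|), 0/0 -> 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    num = np.abs(u - v)
    den = np.abs(u) + np.abs(v)
    terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


def _pairwise_to_all(x: np.ndarray, X: np.ndarray, metric) -> np.ndarray:
    if callable(metric):
        return np.array([metric(x, y) for y in X])
    return cdist(x[None, :], X, metric=metric)[0]


def kcenters(
    features: np.ndarray,
    k: int,
    metric="canberra",
    seed_index: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy farthest-point (k-centers) clustering.

    Starting from ``seed_index``, repeatedly adds the point farthest
    from the current centers (ties to the lowest index), then assigns
    every point to its nearest center.  The covering radius of the
    greedy solution is at most twice the optimum.  Returns
    ``(center_indices, assignments, cover_radius)``; deterministic for a
    given seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n = len(X)
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= {n}, got {k}")
    if not (0 <= seed_index < n):
        raise ValueError("seed_index out of range")
    centers = [seed_index]
    mind = _pairwise_to_all(X[seed_index], X, metric)
    assign = np.zeros(n, dtype=int)
    for _ in range(1, k):
        nxt = int(np.argmax(mind))
        centers.append(nxt)
        d = _pairwise_to_all(X[nxt], X, metric)
        closer = d < mind
        mind[closer] = d[closer]
        assign[closer] = len(centers) - 1
    return np.array(centers, dtype=int), assign, float(mind.max())


def build_csn(
    cluster_ids: np.ndarray,
    frame_weights: np.ndarray,
    sequences: list[np.ndarray],
    seq_weights: np.ndarray | None = None,
    properties: dict[str, np.ndarray] | None = None,
) -> nx.DiGraph:
    """Conformation space network from cluster assignments.

    Nodes are clusters with total statistical weight and weighted
    averages of any supplied per-frame properties; a directed edge i->j
    accumulates the transition weight of every consecutive frame pair in
    ``sequences`` whose clusters differ.  ``sequences`` holds frame-index
    arrays (e.g. one per transition path); ``seq_weights`` the weight
    carried by each sequence (default: the weight of the target frame).
    """
    cluster_ids = np.asarray(cluster_ids, dtype=int)
    w = np.asarray(frame_weights, dtype=float)
    if len(w) != len(cluster_ids):
        raise ValueError("one weight per frame required")
    if properties:
        for name, vals in properties.items():
            if len(vals) != len(cluster_ids):
                raise ValueError(f"property {name!r} length mismatch")
    g = nx.DiGraph()
    for c in np.unique(cluster_ids):
        mask = cluster_ids == c
        cw = float(w[mask].sum())
        attrs = {"weight": cw}
        if properties:
            for name, vals in properties.items():
                vals = np.asarray(vals, dtype=float)
                attrs[name] = float(np.average(vals[mask], weights=w[mask])) if cw > 0 else np.nan
        g.add_node(int(c), **attrs)
    for s, seq in enumerate(sequences):
        seq = np.asarray(seq, dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            ca, cb = int(cluster_ids[a]), int(cluster_ids[b])
            if ca == cb:
                continue
            tw = float(seq_weights[s]) if seq_weights is not None else float(w[b])
            if g.has_edge(ca, cb):
                g[ca][cb]["weight"] += tw
            else:
                g.add_edge(ca, cb, weight=tw)
    return g


def spherical_entry_map(
    directions: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = 30,
) -> pd.DataFrame:
    """Weighted histogram of entry directions on the unit sphere.

    The sphere is cut into ``n_bins`` equal-area latitude bands (uniform
    in z); each band is subdivided in longitude into cells of
    approximately equal solid angle.  Returns one row per cell with its
    bounds, exact solid angle and probability mass; masses sum to 1.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero entry vector")
    d = d / norms[:, None]
    if weights is None:
        weights = np.ones(len(d))
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    z = np.clip(d[:, 2], -1.0, 1.0)
    lon = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    z_edges = np.linspace(-1.0, 1.0, n_bins + 1)
    band = np.clip(np.searchsorted(z_edges, z, side="right") - 1, 0, n_bins - 1)
    rows = []
    for j in range(n_bins):
        z_lo, z_hi = z_edges[j], z_edges[j + 1]
        zc = 0.5 * (z_lo + z_hi)
        ring = 2 * np.pi * np.sqrt(max(1.0 - zc**2, 0.0))
        m = max(1, int(round(ring / (np.pi / n_bins))))
        lon_edges = np.linspace(0.0, 2 * np.pi, m + 1)
        in_band = band == j
        cell = np.clip(
            np.searchsorted(lon_edges, lon[in_band], side="right") - 1, 0, m - 1
        )
        mass = np.bincount(cell, weights=w[in_band], minlength=m)
        omega = (z_hi - z_lo) * 2 * np.pi / m
        for c in range(m):
            rows.append(
                {
                    "z_lo": z_lo,
                    "z_hi": z_hi,
                    "lon_lo": lon_edges[c],
                    "lon_hi": lon_edges[c + 1],
                    "solid_angle": omega,
                    "prob": mass[c] / total,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_bins"] = n_bins
    df.attrs["scheme"] = "equal-area latitude bands, near-equal-area longitude cells"
    return df


def extract_entry_directions(
    records, contact_threshold: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Receptor-to-ligand unit vectors at first contact, with weights.

    A segment is an entry point when its minimum separation first drops
    below ``contact_threshold`` (its parent was beyond it).  Requires
    records stored with dynamic states; the receptor patch frame is the
    lab frame (+z axis), so positions are already in the reference
    orientation.
    """
    dirs, ws = [], []
    for k, rec in enumerate(records):
        if rec.dyn is None:
            raise ValueError("records were stored without dynamic states")
        sep = rec.pcoords[:, 0]
        for i in range(rec.n_segments):
            if sep[i] >= contact_threshold:
                continue
            parent = int(rec.parent_idx[i])
            if k == 0 or parent < 0:
                continue
            if records[k - 1].pcoords[parent, 0] < contact_threshold:
                continue
            v = rec.dyn[i, :3]
            n = np.linalg.norm(v)
            if n == 0:
                continue
            dirs.append(v / n)
            ws.append(rec.weights[i])
    if not dirs:
        return np.zeros((0, 3)), np.zeros(0)
    return np.array(dirs), np.array(ws)
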