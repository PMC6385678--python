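"""HDF5 run store.

Layout (one file per run):

    /iterations/iter_000001/{weights, pcoords, bin_ids, parent_ids,
                             labels, history, roots, recycled, dyn_state,
                             post_weights, post_parent_ids,
                             arrival_*}
    /summary/recycled            per-iteration recycled weight
    /summary/n_segments          per-iteration walker counts
    attrs: tau (time per iteration), tau_steps, seed, and any
           JSON-serialisable metadata passed by the caller.

Weights are unitless probabilities; pcoords are in the reduced Å-like
length units of the model; dyn_state rows are the propagator's flat
state vectors.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .we_engine import IterationRecord

__all__ = ["save_run", "load_run"]

_STR = h5py.string_dtype(encoding="utf-8")


def save_run(records, path, tau: float, meta: dict | None = None) -> None:
    """Write a list of iteration records (and metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["tau"] = float(tau)
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        grp = f.create_group("iterations")
        recycled = []
        counts = []
        for r in records:
            g = grp.create_group(f"iter_{r.iteration:06d}")
            g.create_dataset("weights", data=r.weights)
            g.create_dataset("pcoords", data=r.pcoords)
            g.create_dataset("bin_ids", data=r.bins)
            g.create_dataset("parent_ids", data=r.parent_idx)
            g.create_dataset("labels", data=np.asarray(r.state_labels, dtype=_STR))
            g.create_dataset("history", data=np.asarray(r.history, dtype=_STR))
            g.create_dataset("roots", data=r.roots)
            g.create_dataset("recycled", data=r.recycled_flags)
            g.create_dataset("post_weights", data=r.post_weights)
            g.create_dataset("post_parent_ids", data=r.post_parent_idx)
            if r.dyn is not None:
                g.create_dataset("dyn_state", data=r.dyn)
            if r.arrivals:
                seg, to, w, prev, hist = zip(*r.arrivals)
                g.create_dataset("arrival_seg", data=np.asarray(seg, dtype=int))
                g.create_dataset("arrival_to", data=np.asarray(to, dtype=_STR))
                g.create_dataset("arrival_weight", data=np.asarray(w, dtype=float))
                g.create_dataset("arrival_prev", data=np.asarray(prev, dtype=_STR))
                g.create_dataset("arrival_hist", data=np.asarray(hist, dtype=_STR))
            recycled.append(r.recycled_weight)
            counts.append(r.n_segments)
        s = f.create_group("summary")
        s.create_dataset("recycled", data=np.asarray(recycled))
        s.create_dataset("n_segments", data=np.asarray(counts, dtype=int))


def _decode(arr) -> np.ndarray:
    return np.array([x.decode() if isinstance(x, bytes) else str(x) for x in arr],
                    dtype=object)


def load_run(path):
    """Read a run back into iteration records; returns (records, tau, meta)."""
    records = []
    with h5py.File(path, "r") as f:
        tau = float(f.attrs["tau"])
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
        for name in sorted(f["iterations"]):
            g = f["iterations"][name]
            arrivals = []
            if "arrival_seg" in g:
                seg = g["arrival_seg"][...]
                to = _decode(g["arrival_to"][...])
                w = g["arrival_weight"][...]
                prev = _decode(g["arrival_prev"][...])
                hist = _decode(g["arrival_hist"][...])
                arrivals = [
                    (int(seg[i]), str(to[i]), float(w[i]), str(prev[i]), str(hist[i]))
                    for i in range(len(seg))
                ]
            records.append(
                IterationRecord(
                    iteration=int(name.split("_")[1]),
                    weights=g["weights"][...],
                    pcoords=g["pcoords"][...],
                    bins=g["bin_ids"][...],
                    parent_idx=g["parent_ids"][...],
                    state_labels=_decode(g["labels"][...]),
                    history=_decode(g["history"][...]),
                    roots=g["roots"][...],
                    recycled_flags=g["recycled"][...].astype(bool),
                    arrivals=arrivals,
                    recycled_weight=0.0,
                    post_weights=g["post_weights"][...],
                    post_parent_idx=g["post_parent_ids"][...],
                    dyn=g["dyn_state"][...] if "dyn_state" in g else None,
                )
            )
        rec_w = f["summary"]["recycled"][...]
        for r, w in zip(records, rec_w):
            r.recycled_weight = float(w)
    return records, tau, meta
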