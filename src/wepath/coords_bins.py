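"""Progress coordinates and bin schemes for the binding simulation.

The weighted-ensemble runs in this package resample trajectories on a
two-dimensional progress coordinate:

* ``min_sep`` — the minimum surface-to-surface separation between receptor
  and ligand (Å-like reduced units);
* ``binding_rmsd`` — the RMSD of the ligand "anchor" points from their
  bound pose, after a rigid superposition of the receptor onto its
  reference coordinates.

At large separations the binding RMSD behaves like a distance; near
contact it also encodes the relative orientation of the partners, which is
what lets a single scalar distinguish the native complex from non-native
encounter complexes.

Bin cells are half-open ``[lo, hi)`` with the final cell of each dimension
open-ended, so a value sitting exactly on an edge belongs to the upper
cell (a separation of exactly 5 is "not in contact").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ProgressCoord",
    "BinScheme",
    "kabsch_superpose",
    "binding_rmsd",
    "min_separation",
    "preparatory_edges",
    "binding_scheme",
    "assign_bin",
    "read_xyz",
]


@dataclass(frozen=True)
class ProgressCoord:
    """A single (min_sep, binding_rmsd) progress-coordinate value."""

    min_sep: float
    binding_rmsd: float

    def __post_init__(self) -> None:
        arr = np.array([self.min_sep, self.binding_rmsd], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError(f"progress coordinate must be finite and >= 0, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.min_sep, self.binding_rmsd], dtype=float)


def _check_edges(edges: np.ndarray, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1:
        raise ValueError(f"{name}: need a 1-d array of at least one edge")
    if np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name}: edges must be strictly increasing")
    return edges


@dataclass
class BinScheme:
    """Rectilinear bin partition, optionally conditioned on the first dimension.

    ``edges`` are the left edges of the cells in the first (or only)
    dimension; the final cell is open-ended.  For two-dimensional schemes,
    ``inner_edges[i]`` holds the second-dimension left edges used inside
    first-dimension cell ``i`` — this is what allows the binding scheme to
    subdivide the RMSD coordinate finely in the contact region while
    keeping a single cell elsewhere.
    """

    edges: np.ndarray
    inner_edges: list[np.ndarray] | None = None
    stage: str = "custom"
    label: str = ""

    def __post_init__(self) -> None:
        self.edges = _check_edges(self.edges, "edges")
        if self.inner_edges is not None:
            if len(self.inner_edges) != len(self.edges):
                raise ValueError("need one inner edge array per outer cell")
            self.inner_edges = [
                _check_edges(e, f"inner_edges[{i}]")
                for i, e in enumerate(self.inner_edges)
            ]
            self._offsets = np.concatenate(
                [[0], np.cumsum([len(e) for e in self.inner_edges])]
            )
        else:
            self._offsets = None

    @property
    def ndim(self) -> int:
        return 1 if self.inner_edges is None else 2

    @property
    def n_bins(self) -> int:
        if self.inner_edges is None:
            return len(self.edges)
        return int(self._offsets[-1])

    def assign(self, pcoords: np.ndarray) -> np.ndarray:
        """Map coordinates (n, ndim) or (ndim,) to flat cell indices."""
        pcoords = np.atleast_2d(np.asarray(pcoords, dtype=float))
        if not np.all(np.isfinite(pcoords)):
            raise ValueError("non-finite progress coordinate")
        x = pcoords[:, 0]
        if np.any(x < self.edges[0]):
            raise ValueError(
                f"coordinate below the lowest edge {self.edges[0]}"
            )
        outer = np.searchsorted(self.edges, x, side="right") - 1
        if self.inner_edges is None:
            return outer
        y = pcoords[:, 1]
        flat = np.empty(len(y), dtype=int)
        for i in range(len(self.edges)):
            m = outer == i
            if not np.any(m):
                continue
            inner = self.inner_edges[i]
            if np.any(y[m] < inner[0]):
                raise ValueError(
                    f"second coordinate below the lowest edge {inner[0]}"
                )
            flat[m] = self._offsets[i] + np.searchsorted(
                inner, y[m], side="right"
            ) - 1
        return flat

    def to_dict(self) -> dict:
        d = {"stage": self.stage, "label": self.label,
             "edges": self.edges.tolist()}
        if self.inner_edges is not None:
            d["inner_edges"] = [e.tolist() for e in self.inner_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BinScheme":
        inner = d.get("inner_edges")
        return cls(
            edges=np.asarray(d["edges"], dtype=float),
            inner_edges=None if inner is None else [np.asarray(e) for e in inner],
            stage=d.get("stage", "custom"),
            label=d.get("label", ""),
        )


def assign_bin(pcoord, scheme: BinScheme):
    """Flat cell index of one coordinate (or an array of them)."""
    if isinstance(pcoord, ProgressCoord):
        pcoord = pcoord.as_array()
    arr = np.asarray(pcoord, dtype=float)
    out = scheme.assign(arr)
    return int(out[0]) if arr.ndim == 1 else out


def preparatory_edges() -> BinScheme:
    """One-dimensional RMSD scheme used to relax each isolated binding partner.

    45 cells: every 0.1 Å on [0, 3), every 0.5 Å on [3, 10), and one
    open-ended cell for everything at or beyond 10 Å.
    """
    edges = np.concatenate(
        [np.arange(0.0, 3.0, 0.1), np.arange(3.0, 10.0, 0.5), [10.0]]
    )
    return BinScheme(edges=edges, stage="preparatory", label="heavy-atom RMSD")


def _rmsd_subdivision() -> np.ndarray:
    # fine cells every 0.5 on [0, 10), coarse every 1 on [10, 60), overflow
    return np.concatenate(
        [np.arange(0.0, 10.0, 0.5), np.arange(10.0, 60.0, 1.0), [60.0]]
    )


def binding_scheme(stage: int) -> BinScheme:
    """Two-dimensional scheme for the binding run.

    The separation dimension has two cells, splitting van-der-Waals
    contact (< 5 Å) from no contact (>= 5 Å).  Within the contact cell the
    binding RMSD is finely subdivided in both stages.  Stage 1 applies the
    same RMSD subdivision in the non-contact cell, driving diffusional
    collisions from diverse orientations; stage 2 collapses the
    non-contact cell to a single RMSD cell, which under a fixed global
    trajectory count shifts most sampling effort onto rearrangements of
    the encounter complex.
    """
    if stage not in (1, 2):
        raise ValueError(f"stage must be 1 or 2, got {stage!r}")
    sep_edges = np.array([0.0, 5.0])
    fine = _rmsd_subdivision()
    if stage == 1:
        inner = [fine, fine.copy()]
    else:
        inner = [fine, np.array([0.0])]
    return BinScheme(
        edges=sep_edges,
        inner_edges=inner,
        stage=f"stage{stage}",
        label="min_sep x binding_rmsd",
    )


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_subset: np.ndarray | None = None,
):
    """Least-squares rigid superposition (proper rotation only).

    Finds the rotation ``R`` (det +1) and translation ``t`` minimising the
    RMSD between ``mobile[fit_subset]`` and ``reference[fit_subset]``,
    then applies them to every mobile point.

    Returns ``(transformed, R, t, fit_rmsd)``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile must be (n, 3)")
    idx = np.arange(len(mobile)) if fit_subset is None else np.asarray(fit_subset)
    if len(idx) < 3:
        raise ValueError("need at least 3 fit points")
    P = mobile[idx]
    Q = reference[idx]
    if P.shape != Q.shape:
        raise ValueError("fit subsets must have equal point counts")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # degenerate fit sets (collinear/coincident) leave the rotation
    # under-determined: two near-zero singular values
    if S[1] <= 1e-10 * max(S[0], 1e-300):
        raise ValueError("degenerate fit set (collinear or coincident points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transformed = mobile @ R.T + t
    fit_rmsd = float(np.sqrt(np.mean(np.sum((transformed[idx] - Q) ** 2, axis=1))))
    return transformed, R, t, fit_rmsd


def binding_rmsd(
    receptor: np.ndarray,
    ligand: np.ndarray,
    ref_receptor: np.ndarray,
    ref_ligand: np.ndarray,
    anchors: np.ndarray,
) -> float:
    """Anchor-point RMSD of the ligand after superposing the receptor.

    The frame is rigidly superposed onto the reference using the receptor
    points only; the returned value is the RMSD over the ligand ``anchors``
    index set, i.e. the deviation of the ligand anchor points from their
    bound pose.
    """
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size == 0:
        raise ValueError("anchors must be nonempty")
    receptor = np.asarray(receptor, dtype=float)
    ligand = np.asarray(ligand, dtype=float)
    frame = np.vstack([receptor, ligand])
    ref = np.vstack([np.asarray(ref_receptor, float), np.asarray(ref_ligand, float)])
    fit_idx = np.arange(len(receptor))
    transformed, _, _, _ = kabsch_superpose(frame, ref, fit_idx)
    lig_t = transformed[len(receptor):]
    ref_lig = ref[len(receptor):]
    d2 = np.sum((lig_t[anchors] - ref_lig[anchors]) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def min_separation(
    a: np.ndarray, b: np.ndarray, radii: tuple[float, float] = (0.0, 0.0)
) -> float:
    """Minimum surface separation between two point sets.

    With zero radii this is the minimum inter-set point distance; nonzero
    ``radii`` treat the points as sphere centres (surface separation,
    clamped at zero for overlapping spheres).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be nonempty")
    d = cdist(a, b).min() - radii[0] - radii[1]
    return float(max(d, 0.0))


def read_xyz(path) -> np.ndarray:
    """Read a whitespace-delimited xyz coordinate table (n rows, 3 cols)."""
    arr = np.loadtxt(path, dtype=float)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, got {arr.shape[1]}")
    return arr
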