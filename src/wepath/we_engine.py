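"""Weighted-ensemble iteration: propagate, label, recycle, resample.

The weighted-ensemble (WE) strategy runs many trajectories ("walkers")
in parallel, each carrying a statistical weight.  After every fixed
propagation interval tau the walkers are binned on a progress coordinate
and resampled: bins with too few walkers have their highest-weight
walkers split (weight divided evenly among children), bins with too many
have their lowest-weight walkers merged pairwise (survivor drawn with
probability proportional to weight).  Splitting and merging change the
number of trajectories but never the total probability, so any weighted
average over walkers is an unbiased estimate of the same average over
ordinary brute-force trajectories.

Two operating modes are supported:

* equilibrium (default): nothing is ever removed; state definitions can
  be chosen after the run and kinetics recovered through the
  history-label decomposition (see :mod:`wepath.kinetics`);
* steady state ("recycling"): walkers arriving in the target state are
  restarted from the initial ensemble with their weight intact, which
  drives a nonequilibrium steady state whose arrival flux obeys the
  Hill relation (flux = 1 / mean first-passage time).

The engine is agnostic about the dynamics: a propagator object provides
``propagate_many(states, n_steps, rng) -> states`` and
``pcoords(states) -> (n, d)`` over flat per-walker state arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .coords_bins import BinScheme

__all__ = [
    "Walker",
    "ResamplePolicy",
    "IterationRecord",
    "initialize",
    "split_walker",
    "merge_pair",
    "resample",
    "run_iteration",
    "WESimulation",
]

WEIGHT_TOL = 1e-12


@dataclass
class Walker:
    """One trajectory segment.

    ``idx`` is the position within its iteration's segment table;
    ``parent_idx`` points into the previous iteration's table (negative
    for segments started directly from the initial ensemble).  ``root``
    identifies the initial-ensemble member the lineage descends from.
    ``history`` is the steady-state label: 'U' if the lineage was more
    recently in the initial (unbound) state than the target, 'B'
    otherwise.
    """

    idx: int
    parent_idx: int
    weight: float
    state: np.ndarray
    pcoord: np.ndarray | None = None
    bin: int = -1
    state_label: str = "none"
    history: str = "U"
    root: int = -1
    recycled: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0 + 1e-9):
            raise ValueError(f"walker weight must be in (0, 1], got {self.weight}")


@dataclass
class ResamplePolicy:
    """How many walkers to keep where, and whether to recycle.

    ``mode='per_bin_target'`` keeps ``target`` walkers in every occupied
    bin.  ``mode='fixed_total'`` keeps the global walker count exactly at
    ``target``, distributing ``max(1, total // n_occupied)`` per occupied
    bin and handing leftover slots to occupied bins in descending order
    of bin weight.
    """

    mode: str = "fixed_total"
    target: int = 1600
    recycle: bool = False
    target_state: str = "bound"
    initial_state: str = "unbound"

    def __post_init__(self) -> None:
        if self.mode not in ("per_bin_target", "fixed_total"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.target < 1:
            raise ValueError("target must be >= 1")


@dataclass
class IterationRecord:
    """Everything recorded about one WE iteration.

    The per-segment arrays describe the walkers *after* propagation and
    (in recycling mode) after any recycling, but *before* resampling.
    ``arrivals`` lists every state-entry event as
    ``(seg_idx, to_state, weight, prev_state, prev_history)``.
    """

    iteration: int
    weights: np.ndarray
    pcoords: np.ndarray
    bins: np.ndarray
    parent_idx: np.ndarray
    state_labels: np.ndarray
    history: np.ndarray
    roots: np.ndarray
    recycled_flags: np.ndarray
    arrivals: list[tuple[int, str, float, str, str]]
    recycled_weight: float
    post_weights: np.ndarray
    post_parent_idx: np.ndarray
    dyn: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(np.sum(self.weights))


def initialize(initial_states, copies_per_state: int) -> list[Walker]:
    """Start ``copies_per_state`` walkers from each initial state.

    Every walker receives weight ``1 / (n_states * copies)`` and the
    'U' history label (the run begins unbound).
    """
    states = [np.asarray(s, dtype=float) for s in initial_states]
    if not states:
        raise ValueError("initial_states must be nonempty")
    if copies_per_state < 1:
        raise ValueError("copies_per_state must be >= 1")
    n = len(states) * copies_per_state
    w = 1.0 / n
    walkers = []
    for i, s in enumerate(states):
        for _ in range(copies_per_state):
            walkers.append(
                Walker(
                    idx=len(walkers),
                    parent_idx=-1,
                    weight=w,
                    state=s.copy(),
                    root=i,
                )
            )
    return walkers


def split_walker(w: Walker, k: int) -> list[Walker]:
    """Split into ``k`` children with identical state and weight w/k each."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return [dataclasses.replace(w, state=w.state.copy())]
    child_w = w.weight / k
    return [
        dataclasses.replace(w, weight=child_w, state=w.state.copy())
        for _ in range(k)
    ]


def merge_pair(w1: Walker, w2: Walker, rng: np.random.Generator) -> Walker:
    """Merge two same-bin walkers; the survivor's configuration is drawn
    with probability proportional to weight, and it inherits the summed
    weight, so any weighted observable is preserved in expectation."""
    if w1.bin != w2.bin:
        raise ValueError(f"cannot merge walkers from bins {w1.bin} and {w2.bin}")
    if w1.weight <= 0 or w2.weight <= 0:
        raise ValueError("merge requires strictly positive weights")
    total = w1.weight + w2.weight
    survivor = w1 if rng.random() < w1.weight / total else w2
    return dataclasses.replace(survivor, weight=total, state=survivor.state.copy())


def _bin_targets(walkers, policy: ResamplePolicy) -> dict[int, int]:
    occupied: dict[int, float] = {}
    for w in walkers:
        occupied[w.bin] = occupied.get(w.bin, 0.0) + w.weight
    if policy.mode == "per_bin_target":
        return {b: policy.target for b in occupied}
    n_occ = len(occupied)
    if policy.target < n_occ:
        raise ValueError(
            f"fixed_total target {policy.target} is below the number of "
            f"occupied bins ({n_occ}): bins {sorted(occupied)}"
        )
    base = policy.target // n_occ
    leftover = policy.target - base * n_occ
    targets = {b: base for b in occupied}
    for b, _ in sorted(occupied.items(), key=lambda kv: (-kv[1], kv[0]))[:leftover]:
        targets[b] += 1
    return targets


def resample(
    walkers: list[Walker],
    scheme: BinScheme,
    policy: ResamplePolicy,
    rng: np.random.Generator,
) -> list[Walker]:
    """Split/merge walkers to reach the per-bin targets.

    Splitting always takes the current highest-weight walker in an
    undersubscribed bin (ties to the lowest index) and divides it as
    evenly as the remaining deficit allows; merging repeatedly combines
    the two lowest-weight walkers.  The returned walkers have fresh
    consecutive indices and ``parent_idx`` pointing at their source
    segment, ready to start the next iteration.
    """
    for w in walkers:
        if w.bin < 0:
            raise ValueError(f"walker {w.idx} is not binned")
    targets = _bin_targets(walkers, policy)
    by_bin: dict[int, list[Walker]] = {}
    for w in walkers:
        src = dataclasses.replace(w, parent_idx=w.idx)
        by_bin.setdefault(w.bin, []).append(src)

    out: list[Walker] = []
    for b in sorted(by_bin):
        group = by_bin[b]
        target = targets[b]
        bin_weight = sum(w.weight for w in group)
        while len(group) < target:
            deficit = target - len(group)
            i = min(
                range(len(group)), key=lambda j: (-group[j].weight, group[j].idx)
            )
            w = group.pop(i)
            ideal = bin_weight / target
            k = int(min(deficit + 1, max(2, round(w.weight / ideal))))
            group.extend(split_walker(w, k))
        while len(group) > target:
            order = sorted(
                range(len(group)), key=lambda j: (group[j].weight, group[j].idx)
            )
            i, j = order[0], order[1]
            merged = merge_pair(group[i], group[j], rng)
            group = [g for n, g in enumerate(group) if n not in (i, j)]
            group.append(merged)
        out.extend(group)
    for new_idx, w in enumerate(out):
        w.idx = new_idx
    return out


def run_iteration(
    walkers: list[Walker],
    propagator,
    tau_steps: int,
    scheme: BinScheme,
    policy: ResamplePolicy,
    rng: np.random.Generator,
    state_defs=None,
    initial_pool: list[np.ndarray] | None = None,
    iteration: int = 1,
    store_dyn: bool = True,
) -> tuple[list[Walker], IterationRecord]:
    """One WE iteration: propagate tau, relabel, recycle, record, resample."""
    if tau_steps < 1:
        raise ValueError("tau_steps must be >= 1")
    if policy.recycle and initial_pool is None:
        raise ValueError("recycling requires an initial_pool to restart from")

    states = np.array([w.state for w in walkers], dtype=float)
    new_states = np.asarray(
        propagator.propagate_many(states, tau_steps, rng), dtype=float
    )
    pcoords = np.asarray(propagator.pcoords(new_states), dtype=float)

    if state_defs is not None:
        labels = np.asarray(state_defs.assign(pcoords), dtype=object)
    else:
        labels = np.full(len(walkers), "none", dtype=object)

    arrivals: list[tuple[int, str, float, str, str]] = []
    recycled_weight = 0.0
    recycled_flags = np.zeros(len(walkers), dtype=bool)
    segments: list[Walker] = []
    for i, w in enumerate(walkers):
        new_label = str(labels[i])
        if new_label not in ("none", w.state_label) :
            arrivals.append((i, new_label, w.weight, w.state_label, w.history))
        if new_label == policy.initial_state:
            hist = "U"
        elif new_label == policy.target_state:
            hist = "B"
        else:
            hist = w.history
        root = w.root
        recycled = False
        if policy.recycle and new_label == policy.target_state:
            recycled_weight += w.weight
            j = int(rng.integers(0, len(initial_pool)))
            new_states[i] = np.asarray(initial_pool[j], dtype=float)
            pcoords[i] = propagator.pcoords(new_states[i][None, :])[0]
            new_label = (
                str(state_defs.assign(pcoords[i][None, :])[0])
                if state_defs is not None
                else "none"
            )
            hist = "U"
            root = j
            recycled = True
            recycled_flags[i] = True
        segments.append(
            Walker(
                idx=i,
                parent_idx=w.parent_idx,
                weight=w.weight,
                state=new_states[i],
                pcoord=pcoords[i],
                state_label=new_label,
                history=hist,
                root=root,
                recycled=recycled,
            )
        )

    bins = scheme.assign(pcoords)
    for i, w in enumerate(segments):
        w.bin = int(bins[i])

    starters = resample(segments, scheme, policy, rng)

    record = IterationRecord(
        iteration=iteration,
        weights=np.array([w.weight for w in segments]),
        pcoords=pcoords,
        bins=np.asarray(bins, dtype=int),
        parent_idx=np.array([w.parent_idx for w in segments], dtype=int),
        state_labels=np.array([w.state_label for w in segments], dtype=object),
        history=np.array([w.history for w in segments], dtype=object),
        roots=np.array([w.root for w in segments], dtype=int),
        recycled_flags=recycled_flags,
        arrivals=arrivals,
        recycled_weight=recycled_weight,
        post_weights=np.array([w.weight for w in starters]),
        post_parent_idx=np.array([w.parent_idx for w in starters], dtype=int),
        dyn=new_states.copy() if store_dyn else None,
    )
    return starters, record


class WESimulation:
    """Orchestrates a WE run and accumulates per-iteration records.

    All randomness derives from ``seed``: iteration ``t`` uses a
    generator spawned from ``SeedSequence([seed, t])``, so runs are
    reproducible and walkers replicated by a split receive independent
    noise immediately (each walker draws from its own row of the
    iteration stream).
    """

    def __init__(
        self,
        propagator,
        scheme: BinScheme,
        policy: ResamplePolicy,
        tau_steps: int,
        tau: float,
        seed: int,
        state_defs=None,
        initial_states=None,
        copies_per_state: int = 1,
        recycle_states=None,
        store_dyn: bool = True,
    ):
        self.propagator = propagator
        self.scheme = scheme
        self.policy = policy
        self.tau_steps = int(tau_steps)
        self.tau = float(tau)
        self.seed = int(seed)
        self.state_defs = state_defs
        self.store_dyn = store_dyn
        start_states = [np.asarray(s, dtype=float) for s in initial_states]
        # recycled walkers restart from this pool; by default the same
        # ensemble the run was started from
        self.initial_pool = (
            start_states
            if recycle_states is None
            else [np.asarray(s, dtype=float) for s in recycle_states]
        )
        self.walkers = initialize(start_states, copies_per_state)
        # label/bin the starting walkers so arrivals at iteration 1 are
        # detected relative to the true initial configuration
        pc = np.asarray(propagator.pcoords(np.array([w.state for w in self.walkers])))
        lab = (
            np.asarray(state_defs.assign(pc), dtype=object)
            if state_defs is not None
            else np.full(len(self.walkers), "none", dtype=object)
        )
        for i, w in enumerate(self.walkers):
            w.pcoord = pc[i]
            w.state_label = str(lab[i])
        self.records: list[IterationRecord] = []
        self.iteration = 0
        self._roots_all = set(w.root for w in self.walkers)
        self._roots_encountered: set[int] = set()

    # ------------------------------------------------------------------

    @property
    def total_weight(self) -> float:
        return float(sum(w.weight for w in self.walkers))

    def _rng_for(self, iteration: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, iteration]))

    def run(self, n_iterations: int, progress_callback=None) -> list[IterationRecord]:
        new_records = []
        for _ in range(n_iterations):
            self.iteration += 1
            rng = self._rng_for(self.iteration)
            self.walkers, record = run_iteration(
                self.walkers,
                self.propagator,
                self.tau_steps,
                self.scheme,
                self.policy,
                rng,
                state_defs=self.state_defs,
                initial_pool=self.initial_pool,
                iteration=self.iteration,
                store_dyn=self.store_dyn,
            )
            if abs(record.total_weight - 1.0) > 1e-9:
                raise RuntimeError(
                    f"weight conservation violated at iteration {self.iteration}: "
                    f"total {record.total_weight}"
                )
            for seg_idx, to_state, _, _, _ in record.arrivals:
                if to_state == "encounter":
                    self._roots_encountered.add(int(record.roots[seg_idx]))
            self.records.append(record)
            new_records.append(record)
            if progress_callback is not None:
                progress_callback(self, record)
        return new_records

    def switch_scheme(self, new_scheme: BinScheme) -> None:
        """Swap the bin scheme between iterations.

        Trajectory weights are independent of the bins, so weights and
        dynamic states are untouched; only future resampling changes.
        """
        self.scheme = new_scheme

    def stage1_complete(self) -> bool:
        """Stage-switch trigger: every initial-state lineage has either
        produced a descendant that visited the encounter state or has no
        live descendants."""
        live_roots = set(w.root for w in self.walkers)
        pending = live_roots - self._roots_encountered
        return len(pending) == 0
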