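"""State assignment, steady-state decomposition, and rate constants.

An equilibrium weighted-ensemble run is decomposed into a "binding" and
an "unbinding" steady state by a history label carried on every walker:
a trajectory more recently in the initial (unbound) state than in the
target (bound) state belongs to the binding steady state ('U' label),
and vice versa ('B').  Visits to intermediate states never change the
label.

Rate constants follow from conditional probability fluxes.  With
``flux(A -> B | binding)`` the probability per unit time carried by
binding-steady-state trajectories arriving in B, and ``p_A^binding``
the steady-state population of A restricted to the same label:

    k_on = flux(unbound -> bound | binding)    / (p_unbound^binding * C0)
    k_1  = flux(unbound -> encounter | binding) / (p_unbound^binding * C0)
    k_2  = flux(encounter -> bound | binding)   / p_encounter^binding

where ``C0 = 1/(N_A V)`` is the effective molar concentration a single
pair of molecules has in a container of volume V.  The percentage of
productive collisions is ``100 * flux(U->B|binding) / flux(U->E|binding)``.

State entries are detected once per tau (the analysis resolution of the
run), so recrossings faster than tau are invisible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import N_A

__all__ = [
    "StateDefs",
    "BindingStateDefs",
    "RegionStateDefs",
    "FluxSeries",
    "assign_state",
    "update_history",
    "conditional_flux",
    "arrival_series",
    "labeled_population",
    "effective_concentration",
    "rate_bimolecular",
    "rate_unimolecular",
    "productive_percentage",
    "rate_table",
]


class StateDefs:
    """Interface: map progress coordinates to named metastable states."""

    initial = "unbound"
    target = "bound"

    def assign(self, pcoords: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def names(self) -> tuple[str, ...]:  # pragma: no cover
        raise NotImplementedError


@dataclass
class BindingStateDefs(StateDefs):
    """Threshold-based states on the (min_sep, binding_rmsd) coordinate.

    Defaults: unbound is any conformation with minimum separation
    >= 20 Å; the encounter complex has binding RMSD in [4, 20] Å at a
    separation <= 3 Å; the bound state has binding RMSD <= 3.5 Å at a
    separation <= 3 Å.  Conformations matching no region are labelled
    'none' (e.g. the deliberate RMSD gap between 3.5 and 4 Å).
    """

    unbound_min_sep: float = 20.0
    contact_min_sep: float = 3.0
    encounter_rmsd: tuple[float, float] = (4.0, 20.0)
    bound_rmsd: float = 3.5

    def __post_init__(self) -> None:
        lo, hi = self.encounter_rmsd
        if not (0 <= lo <= hi):
            raise ValueError("encounter RMSD band must satisfy 0 <= lo <= hi")
        if self.bound_rmsd >= lo:
            raise ValueError(
                "bound and encounter regions overlap: need bound_rmsd < "
                f"encounter lower edge, got {self.bound_rmsd} >= {lo}"
            )
        if self.contact_min_sep >= self.unbound_min_sep:
            raise ValueError("unbound region overlaps the contact region")

    @property
    def names(self) -> tuple[str, ...]:
        return ("unbound", "encounter", "bound")

    def assign(self, pcoords: np.ndarray) -> np.ndarray:
        pc = np.atleast_2d(np.asarray(pcoords, dtype=float))
        if not np.all(np.isfinite(pc)):
            raise ValueError("non-finite progress coordinate")
        sep, rmsd = pc[:, 0], pc[:, 1]
        out = np.full(len(pc), "none", dtype=object)
        out[sep >= self.unbound_min_sep] = "unbound"
        contact = sep <= self.contact_min_sep
        lo, hi = self.encounter_rmsd
        out[contact & (rmsd >= lo) & (rmsd <= hi)] = "encounter"
        out[contact & (rmsd <= self.bound_rmsd)] = "bound"
        return out


@dataclass
class RegionStateDefs(StateDefs):
    """States given as arbitrary predicates on the progress coordinate.

    ``regions`` maps state name -> callable(pcoords (n, d)) -> bool mask.
    Overlapping regions raise at assignment time (each coordinate must
    belong to at most one state).
    """

    regions: dict
    initial: str = "unbound"
    target: str = "bound"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def assign(self, pcoords: np.ndarray) -> np.ndarray:
        pc = np.atleast_2d(np.asarray(pcoords, dtype=float))
        out = np.full(len(pc), "none", dtype=object)
        claimed = np.zeros(len(pc), dtype=bool)
        for name, pred in self.regions.items():
            mask = np.asarray(pred(pc), dtype=bool)
            if np.any(mask & claimed):
                raise ValueError(f"state regions overlap at {name!r}")
            out[mask] = name
            claimed |= mask
        return out


def assign_state(pcoord, defs: StateDefs) -> str:
    """State label of a single progress-coordinate value."""
    arr = pcoord.as_array() if hasattr(pcoord, "as_array") else np.asarray(pcoord)
    return str(defs.assign(arr[None, :] if arr.ndim == 1 else arr)[0])


def update_history(history: str, current_state: str, defs: StateDefs) -> str:
    """New steady-state label after visiting ``current_state``.

    Entering the initial state sets 'U', entering the target sets 'B';
    intermediate states and unassigned regions leave the label unchanged.
    """
    if current_state == defs.initial:
        return "U"
    if current_state == defs.target:
        return "B"
    return history


@dataclass
class FluxSeries:
    """Per-iteration conditional probability flux for one transition."""

    values: np.ndarray
    tau: float
    from_state: str
    to_state: str
    direction: str = "binding"
    iterations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("flux values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _window_records(records, window):
    if window is None:
        return list(records)
    lo, hi = window
    out = [r for r in records if lo <= r.iteration < hi]
    if not out:
        raise ValueError(f"window {window} selects no iterations")
    return out


def _qualifies(from_state: str, prev_state: str, prev_history: str,
               direction: str, defs: StateDefs) -> bool:
    want = "U" if direction == "binding" else "B"
    if from_state == defs.initial:
        return prev_history == "U" if direction == "binding" else False
    if from_state == defs.target:
        return prev_history == "B" if direction == "unbinding" else False
    # intermediate origin: require the walker to actually come from it,
    # carrying the requested steady-state label
    return prev_state == from_state and prev_history == want


def conditional_flux(
    records,
    from_state: str,
    to_state: str,
    tau: float,
    defs: StateDefs,
    window=None,
    direction: str = "binding",
) -> FluxSeries:
    """Per-iteration flux of probability from one state into another.

    For each iteration, sums the weights of walkers on the requested
    steady-state side (label 'U' for the binding direction) that enter
    ``to_state`` during that iteration, divided by tau.  Entries are
    counted at tau resolution, so at most once per walker per iteration.
    """
    recs = _window_records(records, window)
    vals = np.zeros(len(recs))
    its = np.zeros(len(recs), dtype=int)
    for k, r in enumerate(recs):
        its[k] = r.iteration
        s = 0.0
        for _, arr_to, weight, prev_state, prev_hist in r.arrivals:
            if arr_to == to_state and _qualifies(
                from_state, prev_state, prev_hist, direction, defs
            ):
                s += weight
        vals[k] = s / tau
    return FluxSeries(vals, tau, from_state, to_state, direction, its)


def arrival_series(records, to_state: str, defs: StateDefs, window=None,
                   direction: str = "binding", from_state: str | None = None):
    """Counts and weights of qualifying arrivals per iteration."""
    recs = _window_records(records, window)
    counts = np.zeros(len(recs), dtype=int)
    weights = np.zeros(len(recs))
    for k, r in enumerate(recs):
        for _, arr_to, weight, prev_state, prev_hist in r.arrivals:
            if arr_to != to_state:
                continue
            if from_state is not None and not _qualifies(
                from_state, prev_state, prev_hist, direction, defs
            ):
                continue
            if from_state is None and direction == "binding" and prev_hist != "U":
                continue
            counts[k] += 1
            weights[k] += weight
    return counts, weights


def labeled_population(records, state: str, label: str, window=None) -> float:
    """Time-averaged probability in ``state`` carrying history ``label``."""
    recs = _window_records(records, window)
    if not recs:
        raise ValueError("empty window")
    vals = [
        float(np.sum(r.weights[(r.state_labels == state) & (r.history == label)]))
        for r in recs
    ]
    return float(np.mean(vals))


_NM3_TO_L = 1e-24


def effective_concentration(volume: float, unit: str = "nm^3") -> float:
    """Effective molar concentration of one molecule in ``volume``:
    C0 = 1/(N_A V), in mol/L."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    factors = {"nm^3": 1e-24, "A^3": 1e-27, "L": 1.0}
    try:
        v_litre = volume * factors[unit]
    except KeyError:
        raise ValueError(f"unknown volume unit {unit!r}") from None
    return 1.0 / (N_A * v_litre)


def rate_bimolecular(flux_mean: float, pop: float, c0: float) -> float:
    """k = flux / (p * C0).  Flux in 1/time gives k in 1/(M * time); the
    caller converts the time unit (e.g. ps -> s) at reporting."""
    if pop <= 0:
        raise ValueError("state never populated in window")
    if c0 <= 0:
        raise ValueError("C0 must be positive")
    return flux_mean / (pop * c0)


def rate_unimolecular(flux_mean: float, pop: float) -> float:
    """k = flux / p, in inverse time units of the flux."""
    if pop <= 0:
        raise ValueError("state never populated in window")
    return flux_mean / pop


def productive_percentage(flux_ub: float, flux_ue: float) -> float:
    """Percentage of collisions that proceed to the bound state:
    100 * flux(U->B|binding) / flux(U->E|binding)."""
    if flux_ue <= 0:
        raise ValueError("unbound->encounter flux must be positive")
    return 100.0 * flux_ub / flux_ue


def rate_table(
    records,
    defs: StateDefs,
    tau: float,
    c0: float,
    window=None,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """k1, k2, kon and the productive percentage with bootstrap CIs.

    Fluxes are averaged over ``window`` (default: all recorded
    iterations); confidence intervals come from Monte Carlo blocked
    bootstrapping of the per-iteration flux series
    (:mod:`wepath.uncertainty`).  Rates are in the inverse time unit of
    ``tau``; multiply by the appropriate factor to convert to seconds.
    """
    from .uncertainty import blocked_bootstrap_ci, flux_autocorr_tc, ratio_ci

    rows = []
    fluxes = {}
    for name, (a, b) in {
        "k1": ("unbound", "encounter"),
        "k2": ("encounter", "bound"),
        "kon": ("unbound", "bound"),
    }.items():
        fs = conditional_flux(records, a, b, tau, defs, window=window)
        pop = labeled_population(records, a, "U", window=window)
        rng = np.random.default_rng(np.random.SeedSequence([seed, len(rows)]))
        if np.all(fs.values == fs.values[0]):
            tc = 1
        else:
            tc = flux_autocorr_tc(fs.values, n_boot=min(n_boot, 200), conf=conf,
                                  rng=rng)
        ci = blocked_bootstrap_ci(fs.values, tc, n_boot=n_boot, conf=conf, rng=rng)
        fluxes[name] = ci
        if name == "k2":
            k = rate_unimolecular(fs.mean, pop) if pop > 0 else np.nan
            scale = 1.0 / pop if pop > 0 else np.nan
        else:
            k = rate_bimolecular(fs.mean, pop, c0) if pop > 0 else np.nan
            scale = 1.0 / (pop * c0) if pop > 0 else np.nan
        rows.append(
            {
                "quantity": name,
                "value": k,
                "ci_lo": ci.lo * scale,
                "ci_hi": ci.hi * scale,
                "flux_mean": fs.mean,
                "population": pop,
                "t_c": tc,
                "n_iterations": len(fs),
                "units": "1/(M*tau)" if name != "k2" else "1/tau",
            }
        )
    try:
        pr = ratio_ci(fluxes["kon"], fluxes["k1"])
        rows.append(
            {
                "quantity": "productive_pct",
                "value": 100.0 * pr.point,
                "ci_lo": 100.0 * pr.lo,
                "ci_hi": 100.0 * pr.hi,
                "flux_mean": np.nan,
                "population": np.nan,
                "t_c": np.nan,
                "n_iterations": len(records) if window is None else np.nan,
                "units": "%",
            }
        )
    except ValueError:
        pass
    df = pd.DataFrame(rows)
    df.attrs["C0"] = c0
    df.attrs["conf"] = conf
    df.attrs["window"] = window
    return df
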