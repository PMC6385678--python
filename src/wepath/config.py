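"""YAML run configuration.

A configuration file has up to five sections::

    system:            # ToyParams fields (reduced units)
      eps: 12.0
      ...
    we:
      tau_steps: 25    # propagator steps per iteration
      mode: fixed_total
      target: 400      # global total or per-bin M
      recycle: false
      n_initial: 100
      copies_per_state: 4
      min_sep_initial: 20.0
      seed: 42
      iterations: 200
      switch_at: null  # iteration at which to switch stage 1 -> stage 2
    bins:
      stage: 1         # or explicit {edges: [...], inner_edges: [[...], ...]}
    states:            # BindingStateDefs thresholds (optional)
      unbound_min_sep: 20.0
      ...
    output:
      path: run.h5
"""

from __future__ import annotations

import numpy as np
import yaml

from .coords_bins import BinScheme, binding_scheme
from .kinetics import BindingStateDefs
from .toy_binding_sim import ToyParams, ToyPropagator, make_initial_ensemble
from .we_engine import ResamplePolicy, WESimulation

__all__ = ["load_config", "build_simulation"]

_WE_DEFAULTS = {
    "tau_steps": 25,
    "mode": "fixed_total",
    "target": 400,
    "recycle": False,
    "n_initial": 100,
    "copies_per_state": 4,
    "min_sep_initial": 20.0,
    "seed": 42,
    "iterations": 200,
    "switch_at": None,
    "store_dyn": True,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for section in ("system", "we", "bins", "states", "output"):
        cfg.setdefault(section, {})
    we = dict(_WE_DEFAULTS)
    we.update(cfg["we"] or {})
    cfg["we"] = we
    return cfg


def _scheme_from_cfg(bins_cfg) -> BinScheme:
    if not bins_cfg:
        return binding_scheme(1)
    if "stage" in bins_cfg:
        return binding_scheme(int(bins_cfg["stage"]))
    return BinScheme.from_dict(bins_cfg)


def build_simulation(cfg: dict, seed: int | None = None) -> WESimulation:
    """Construct a toy-system WE simulation from a parsed configuration."""
    params = ToyParams(**(cfg.get("system") or {}))
    we = dict(_WE_DEFAULTS)
    we.update(cfg.get("we") or {})
    seed = int(we["seed"] if seed is None else seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    ensemble = make_initial_ensemble(
        int(we["n_initial"]), float(we["min_sep_initial"]), params, rng
    )
    policy = ResamplePolicy(
        mode=we["mode"], target=int(we["target"]), recycle=bool(we["recycle"])
    )
    defs = BindingStateDefs(**(cfg.get("states") or {}))
    sim = WESimulation(
        propagator=ToyPropagator(params),
        scheme=_scheme_from_cfg(cfg.get("bins")),
        policy=policy,
        tau_steps=int(we["tau_steps"]),
        tau=int(we["tau_steps"]) * params.dt,
        seed=seed,
        state_defs=defs,
        initial_states=[s.as_array() for s in ensemble],
        copies_per_state=int(we["copies_per_state"]),
        store_dyn=bool(we["store_dyn"]),
    )
    sim.params = params
    return sim
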