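"""Patchy-sphere Brownian-dynamics model of bimolecular binding.

The model replaces an atomistic receptor--ligand pair with two rigid
spheres in a reflecting spherical container.  The receptor is fixed at
the origin with a sticky "patch" along +z; the ligand diffuses
(translation and rotation, overdamped Langevin dynamics) and carries its
own patch plus two fixed surface "anchor" points that play the role of
the ligand anchor residues in the binding-RMSD progress coordinate.

The interaction energy has three ingredients chosen to reproduce the
unbound / encounter-complex / native-complex topology that the analysis
modules assume:

* a soft-core repulsion below sphere--sphere contact,
* a patch--patch attraction of depth ``eps`` requiring both patches to
  face each other (the native bound basin), and
* a weak, orientationally broad attraction of depth ``~ eps * w_enc``
  active whenever the spheres touch (the metastable encounter basin:
  non-native collision complexes that may rearrange to the native pose).

With perfectly aligned patches at sphere contact the energy is exactly
``-eps`` (the broad and specific terms are blended convexly).

All quantities are in reduced units: ``kT = 1``, lengths in Å-like
units, times in ps-like units, so a diffusion coefficient of 1 means
1 Å²/ps-like.  Dynamics are integrated with the Euler--Maruyama scheme.

The module also provides brute-force and closed-form mean-first-passage
oracles used to validate weighted-ensemble rate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ToyState",
    "ToyParams",
    "toy_energy",
    "propagate",
    "make_initial_ensemble",
    "brute_force_mfpt",
    "shell_mfpt_analytic",
    "MFPTResult",
    "shell_steady_positions",
    "RenewalStats",
    "renewal_rate_oracle",
    "ToyPropagator",
]


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention, batch-friendly)

def _quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    w2, x2, y2, z2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def _quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors v (..., 3) by unit quaternions q (..., 4)."""
    qv = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def _rotvec_to_quat(rv: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    small = angle < 1e-12
    axis = np.where(small, 0.0, rv / np.where(small, 1.0, angle))
    half = 0.5 * angle
    return np.concatenate([np.cos(half), np.sin(half) * axis], axis=-1)


# ---------------------------------------------------------------------------
# model definition


@dataclass
class ToyParams:
    """Parameters of the patchy-sphere binding model (reduced units).

    ``R_rec``/``R_lig`` are the sphere radii, so contact occurs at a
    centre distance of ``R_rec + R_lig`` and the minimum separation
    coordinate is the centre distance minus that sum.  ``eps`` is the
    native-well depth in kT; ``p_rec``/``p_lig`` sharpen the angular
    dependence of the specific attraction; ``w_enc`` sets the relative
    depth of the broad encounter shoulder.  ``anchor_tilt_deg`` places
    the two anchor points on the ligand surface at that polar angle from
    the ligand patch axis, at azimuths +-90 degrees.
    """

    R_rec: float = 3.0
    R_lig: float = 2.0
    eps: float = 12.0
    p_rec: float = 2.0
    p_lig: float = 2.0
    w_enc: float = 0.3
    D_t: float = 2.0
    D_r: float = 0.6
    dt: float = 0.02
    kT: float = 1.0
    R_out: float = 30.0
    r_cut: float = 8.0
    k_rep: float = 20.0
    anchor_tilt_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D_t < 0 or self.D_r < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.R_out <= self.R_rec + self.R_lig + 20.0:
            raise ValueError(
                "R_out must exceed contact distance + 20 so an unbound "
                "state (min_sep >= 20) exists inside the container"
            )
        if not (self.R_rec + self.R_lig < self.r_cut <= self.R_out):
            raise ValueError("need contact < r_cut <= R_out")

    @property
    def sigma(self) -> float:
        """Centre distance at sphere--sphere contact."""
        return self.R_rec + self.R_lig

    @property
    def volume(self) -> float:
        """Container volume accessible to the ligand centre (reduced Å³)."""
        return 4.0 / 3.0 * np.pi * self.R_out**3

    # geometry ------------------------------------------------------------

    @property
    def patch_body(self) -> np.ndarray:
        """Ligand patch axis in the body frame (faces the receptor when bound)."""
        return np.array([0.0, 0.0, -1.0])

    @property
    def anchors_body(self) -> np.ndarray:
        """Anchor points on the ligand surface, body frame (2, 3)."""
        a = np.deg2rad(self.anchor_tilt_deg)
        s, c = np.sin(a), np.cos(a)
        return self.R_lig * np.array([[0.0, s, -c], [0.0, -s, -c]])

    def bound_pose(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference bound pose: ligand centre and identity orientation."""
        return self.sigma * np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0, 0.0])

    def reference_anchors(self) -> np.ndarray:
        pos, quat = self.bound_pose()
        return pos + _quat_rotate(quat, self.anchors_body)

    def receptor_points(self) -> np.ndarray:
        """Four fixed receptor surface points (for generic superposition)."""
        r = self.R_rec
        return r * np.array(
            [[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [-1.0, 0, 0]]
        )

    def anchors_lab(self, pos: np.ndarray, quat: np.ndarray) -> np.ndarray:
        """Anchor points in the lab frame for batched states."""
        pos = np.atleast_2d(pos)
        quat = np.atleast_2d(quat)
        out = pos[:, None, :] + _quat_rotate(quat[:, None, :], self.anchors_body)
        return out

    def pcoords(self, pos: np.ndarray, quat: np.ndarray) -> np.ndarray:
        """(min_sep, binding_rmsd) for batched states, shape (n, 2)."""
        pos = np.atleast_2d(pos)
        quat = np.atleast_2d(quat)
        r = np.linalg.norm(pos, axis=-1)
        min_sep = np.maximum(r - self.sigma, 0.0)
        ref = self.reference_anchors()
        d2 = np.sum((self.anchors_lab(pos, quat) - ref) ** 2, axis=-1)
        rmsd = np.sqrt(d2.mean(axis=-1))
        return np.stack([min_sep, rmsd], axis=-1)

    def to_dict(self) -> dict:
        return {
            k: float(getattr(self, k))
            for k in (
                "R_rec R_lig eps p_rec p_lig w_enc D_t D_r dt kT "
                "R_out r_cut k_rep anchor_tilt_deg".split()
            )
        }


@dataclass
class ToyState:
    """Configuration of the ligand relative to the fixed receptor."""

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(4)
        if not np.all(np.isfinite(self.position)) or not np.all(
            np.isfinite(self.orientation)
        ):
            raise ValueError("non-finite state")
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"orientation quaternion norm {n} != 1")

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.position, self.orientation])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ToyState":
        arr = np.asarray(arr, dtype=float).reshape(7)
        q = arr[3:]
        return cls(arr[:3], q / np.linalg.norm(q))


# ---------------------------------------------------------------------------
# energy and forces


def _angular_terms(pos, quat, params):
    """Unit separation vector, patch direction, and alignment cosines."""
    r = np.linalg.norm(pos, axis=-1)
    rhat = pos / r[..., None]
    u = _quat_rotate(quat, params.patch_body)
    cr = rhat[..., 2]                      # receptor patch axis is +z
    cl = -np.sum(u * rhat, axis=-1)        # ligand patch toward receptor
    return r, rhat, u, cr, cl


def _radial_switch(r, params):
    """Smooth switch: 1 inside contact, 0 at and beyond r_cut."""
    sigma, rc = params.sigma, params.r_cut
    s = np.clip((r - sigma) / (rc - sigma), 0.0, 1.0)
    f = (1.0 - s**2) ** 2
    fp = np.where((r > sigma) & (r < rc), -4.0 * s * (1.0 - s**2) / (rc - sigma), 0.0)
    return f, fp


def _gpow(x, p):
    g = np.maximum(x, 0.0)
    return g**p


def _gpow_deriv(x, p):
    g = np.maximum(x, 1e-300)
    return np.where(x > 0.0, p * g ** (p - 1.0), 0.0)


def _energy_arrays(pos, quat, params):
    r, _, _, cr, cl = _angular_terms(pos, quat, params)
    urep = 0.5 * params.k_rep * np.where(r < params.sigma, (params.sigma - r) ** 2, 0.0)
    f, _ = _radial_switch(r, params)
    specific = _gpow(cr, params.p_rec) * _gpow(cl, params.p_lig)
    broad = 0.25 * (2.0 + cr + cl)
    attract = (1.0 - params.w_enc) * specific + params.w_enc * broad
    return urep - params.eps * f * attract


def toy_energy(state: ToyState, params: ToyParams) -> float:
    """Interaction energy in kT; exactly 0 at separations >= r_cut and
    exactly ``-eps`` for perfectly aligned patches at sphere contact."""
    if not np.all(np.isfinite(state.position)):
        raise ValueError("non-finite coordinates")
    return float(_energy_arrays(state.position, state.orientation, params))


def _forces(pos, quat, params):
    """Force on the ligand centre and torque about its centre, batched."""
    r, rhat, u, cr, cl = _angular_terms(pos, quat, params)
    f, fp = _radial_switch(r, params)
    g_cr = _gpow(cr, params.p_rec)
    g_cl = _gpow(cl, params.p_lig)
    A = (1.0 - params.w_enc) * (g_cr * g_cl) + params.w_enc * 0.25 * (2.0 + cr + cl)
    dA_dcr = (1.0 - params.w_enc) * _gpow_deriv(cr, params.p_rec) * g_cl + params.w_enc * 0.25
    dA_dcl = (1.0 - params.w_enc) * g_cr * _gpow_deriv(cl, params.p_lig) + params.w_enc * 0.25
    durep = -params.k_rep * np.where(r < params.sigma, params.sigma - r, 0.0)
    dU_dr = durep - params.eps * fp * A
    dU_dcr = -params.eps * f * dA_dcr
    dU_dcl = -params.eps * f * dA_dcl

    zhat = np.zeros_like(rhat)
    zhat[..., 2] = 1.0
    grad_cr = (zhat - cr[..., None] * rhat) / r[..., None]
    grad_cl = (-u - cl[..., None] * rhat) / r[..., None]
    gradU = (
        dU_dr[..., None] * rhat
        + dU_dcr[..., None] * grad_cr
        + dU_dcl[..., None] * grad_cl
    )
    force = -gradU
    torque = dU_dcl[..., None] * np.cross(u, rhat)
    return force, torque


def _reflect_radial(pos, lo, hi):
    r = np.linalg.norm(pos, axis=-1)
    over = r > hi
    if np.any(over):
        pos[over] *= ((2.0 * hi - r[over]) / r[over])[:, None]
    r = np.linalg.norm(pos, axis=-1)
    under = r < lo
    if np.any(under):
        pos[under] *= ((2.0 * lo - r[under]) / r[under])[:, None]
    return pos


def propagate_arrays(
    pos: np.ndarray,
    quat: np.ndarray,
    params: ToyParams,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Overdamped Langevin propagation of a batch of states.

    ``pos`` (n, 3) and ``quat`` (n, 4) are not modified in place.
    Translation: Euler--Maruyama with drift ``(D_t/kT) F dt`` and noise
    variance ``2 D_t dt`` per component, reflecting at ``R_out`` and at a
    small inner core (half the contact distance) that the soft repulsion
    alone cannot strictly forbid.  Rotation: composition with a random
    rotation of variance ``2 D_r dt`` per axis plus torque drift.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    pos = np.array(pos, dtype=float, copy=True)
    quat = np.array(quat, dtype=float, copy=True)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    quat = np.atleast_2d(quat)
    dt = params.dt
    trans_noise = np.sqrt(2.0 * params.D_t * dt)
    rot_noise = np.sqrt(2.0 * params.D_r * dt)
    mob_t = params.D_t / params.kT * dt
    mob_r = params.D_r / params.kT * dt
    core = 0.5 * params.sigma
    for _ in range(n_steps):
        force, torque = _forces(pos, quat, params)
        drift = mob_t * force
        step_max = np.max(np.linalg.norm(drift, axis=-1))
        if step_max > params.R_rec:
            raise RuntimeError(
                f"drift step {step_max:.3g} exceeds R_rec; reduce dt"
            )
        pos += drift + trans_noise * rng.standard_normal(pos.shape)
        pos = _reflect_radial(pos, core, params.R_out)
        rotvec = mob_r * torque + rot_noise * rng.standard_normal(pos.shape)
        quat = _quat_multiply(_rotvec_to_quat(rotvec), quat)
        quat /= np.linalg.norm(quat, axis=-1, keepdims=True)
    if single:
        return pos[0], quat[0]
    return pos, quat


def propagate(
    state: ToyState, params: ToyParams, n_steps: int, rng: np.random.Generator
) -> ToyState:
    """Propagate one state; identical rng streams give identical output."""
    pos, quat = propagate_arrays(state.position, state.orientation, params, n_steps, rng)
    return ToyState(pos, quat)


# ---------------------------------------------------------------------------
# initial ensembles


def make_initial_ensemble(
    n_pairs: int,
    min_sep: float,
    params: ToyParams,
    rng: np.random.Generator,
) -> list[ToyState]:
    """Unbound pairs: separation >= min_sep, orientations uniform on SO(3).

    Ligand centres are uniform in the spherical shell between the
    ``min_sep`` surface and the container wall, emulating an initial
    ensemble of well-separated, randomly oriented binding partners.
    """
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    a = params.sigma + min_sep
    if a >= params.R_out:
        raise ValueError(
            f"infeasible: contact+min_sep={a} leaves no room inside R_out={params.R_out}"
        )
    u = rng.random(n_pairs)
    radius = (u * (params.R_out**3 - a**3) + a**3) ** (1.0 / 3.0)
    direction = rng.standard_normal((n_pairs, 3))
    direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
    quats = Rotation.random(n_pairs, rng=rng).as_quat(scalar_first=True)
    return [
        ToyState(radius[i] * direction[i], quats[i]) for i in range(n_pairs)
    ]


# ---------------------------------------------------------------------------
# mean-first-passage oracles


@dataclass
class MFPTResult:
    """First-passage statistics from direct simulation."""

    times: np.ndarray
    n_censored: int
    step_cap: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.times))

    @property
    def se(self) -> float:
        n = len(self.times)
        return float(np.std(self.times, ddof=1) / np.sqrt(n)) if n > 1 else np.nan


def brute_force_mfpt(
    params: ToyParams,
    target,
    n_replicas: int,
    rng: np.random.Generator,
    initial_states: list[ToyState] | None = None,
    min_sep: float = 20.0,
    step_cap: int = 2_000_000,
    check_every: int = 1,
) -> MFPTResult:
    """Direct, unbiased first-passage simulation into ``target``.

    ``target`` is a predicate on progress coordinates: it receives an
    (n, 2) array of (min_sep, binding_rmsd) values and returns a boolean
    mask.  The target condition is checked every ``check_every`` steps;
    reported times are ``steps * dt``.  Replicas exceeding ``step_cap``
    are counted in ``n_censored`` rather than silently dropped.
    """
    if n_replicas < 10:
        raise ValueError("need at least 10 replicas")
    if initial_states is None:
        initial_states = make_initial_ensemble(n_replicas, min_sep, params, rng)
    else:
        idx = rng.integers(0, len(initial_states), size=n_replicas)
        initial_states = [initial_states[i] for i in idx]
    pos = np.array([s.position for s in initial_states])
    quat = np.array([s.orientation for s in initial_states])
    times = np.full(n_replicas, np.nan)
    active = np.arange(n_replicas)
    hit0 = np.asarray(target(params.pcoords(pos, quat)), dtype=bool)
    times[active[hit0]] = 0.0
    active = active[~hit0]
    pos, quat = pos[~hit0], quat[~hit0]
    steps = 0
    while len(active) and steps < step_cap:
        pos, quat = propagate_arrays(pos, quat, params, check_every, rng)
        steps += check_every
        hit = np.asarray(target(params.pcoords(pos, quat)), dtype=bool)
        if np.any(hit):
            times[active[hit]] = steps * params.dt
            active = active[~hit]
            pos, quat = pos[~hit], quat[~hit]
    return MFPTResult(
        times=times[np.isfinite(times)], n_censored=len(active), step_cap=step_cap
    )


def shell_steady_positions(
    n: int,
    b: float,
    a: float,
    R: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample radii from the steady-state density of the recycling
    source/sink diffusion problem.

    Absorbing sphere at ``b``, reflecting wall at ``R``, absorbed
    particles reinserted uniformly (in volume) in the shell ``[a, R]``.
    The steady concentration solves a constant-current diffusion profile:
    ``c(r) = const * \\int_b^r G(s)/s^2 ds`` with ``G(s)`` the fraction of
    the source lying beyond ``s``; the radial density is ``r^2 c(r)``.
    Starting a recycling WE run from this profile removes the slow
    container-scale relaxation transient, so the measured flux is the
    maintained steady-state flux from the start.
    """
    if not (0 < b < a < R):
        raise ValueError("need 0 < b < a < R")
    r = np.linspace(b, R, 4000)
    G = np.where(r < a, 1.0, (R**3 - r**3) / (R**3 - a**3))
    integrand = G / r**2
    c = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r))])
    dens = r**2 * c
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(r))])
    cdf /= cdf[-1]
    radii = np.interp(rng.random(n), cdf, r)
    direction = rng.standard_normal((n, 3))
    direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
    return radii[:, None] * direction


@dataclass
class RenewalStats:
    """Per-replica statistics of a brute-force binding renewal process.

    Each replica runs from the unbound initial ensemble until its first
    entry into the bound state, with states evaluated every tau (the
    same analysis resolution as a WE run).  ``n_bound`` is 0 for
    censored replicas (step cap reached), else 1.
    """

    t_total: np.ndarray
    time_unbound: np.ndarray
    time_encounter: np.ndarray
    n_enc_entries: np.ndarray
    n_bound_from_enc: np.ndarray
    n_bound: np.ndarray
    tau: float

    @property
    def n_censored(self) -> int:
        return int(np.sum(self.n_bound == 0))

    def rates(self, c0: float) -> dict:
        """Point estimates of k1, k2, kon from the pooled renewal process."""
        T = self.t_total.sum()
        p_u = self.time_unbound.sum() / T
        p_e = self.time_encounter.sum() / T
        return {
            "kon": self.n_bound.sum() / T / (p_u * c0),
            "k1": self.n_enc_entries.sum() / T / (p_u * c0),
            "k2": (self.n_bound_from_enc.sum() / T / p_e) if p_e > 0 else np.nan,
        }

    def bootstrap_rates(self, c0: float, n_boot: int = 1000, conf: float = 0.95,
                        rng: np.random.Generator | None = None) -> dict:
        """Percentile CIs of the rates by resampling whole replicas."""
        if rng is None:
            rng = np.random.default_rng()
        n = len(self.t_total)
        idx = rng.integers(0, n, size=(n_boot, n))
        T = self.t_total[idx].sum(axis=1)
        tu = self.time_unbound[idx].sum(axis=1)
        te = self.time_encounter[idx].sum(axis=1)
        kon = self.n_bound[idx].sum(axis=1) / tu / c0
        k1 = self.n_enc_entries[idx].sum(axis=1) / tu / c0
        with np.errstate(divide="ignore", invalid="ignore"):
            k2 = self.n_bound_from_enc[idx].sum(axis=1) / te
        alpha = 1.0 - conf
        qs = [alpha / 2, 1 - alpha / 2]
        return {
            "kon": tuple(np.quantile(kon, qs)),
            "k1": tuple(np.quantile(k1, qs)),
            "k2": tuple(np.quantile(k2[np.isfinite(k2)], qs)),
        }


def renewal_rate_oracle(
    params: ToyParams,
    defs,
    n_replicas: int,
    tau_steps: int,
    rng: np.random.Generator,
    min_sep: float = 20.0,
    step_cap: int = 500_000,
) -> RenewalStats:
    """Brute-force oracle for the WE rate pipeline.

    Runs ``n_replicas`` unbiased trajectories from the unbound ensemble
    until they first bind, evaluating state membership every
    ``tau_steps`` integrator steps (matching WE analysis resolution) and
    accumulating the state-entry counts and occupancies from which
    k1, k2 and kon follow.  All trajectories carry the binding-direction
    history label by construction (none has visited the bound state).
    """
    tau = tau_steps * params.dt
    states = make_initial_ensemble(n_replicas, min_sep, params, rng)
    pos = np.array([s.position for s in states])
    quat = np.array([s.orientation for s in states])
    prev = defs.assign(params.pcoords(pos, quat))
    n = n_replicas
    t_total = np.zeros(n)
    time_u = np.zeros(n)
    time_e = np.zeros(n)
    n_ue = np.zeros(n, dtype=int)
    n_eb = np.zeros(n, dtype=int)
    n_b = np.zeros(n, dtype=int)
    active = np.arange(n)
    steps = 0
    while len(active) and steps < step_cap:
        pos, quat = propagate_arrays(pos, quat, params, tau_steps, rng)
        steps += tau_steps
        cur = defs.assign(params.pcoords(pos, quat))
        t_total[active] += tau
        bound = cur == "bound"
        enc_entry = (cur == "encounter") & (prev != "encounter")
        n_ue[active[enc_entry]] += 1
        n_eb[active[bound & (prev == "encounter")]] += 1
        n_b[active[bound]] += 1
        alive = ~bound
        time_u[active[alive & (cur == "unbound")]] += tau
        time_e[active[alive & (cur == "encounter")]] += tau
        active = active[alive]
        pos, quat, prev = pos[alive], quat[alive], cur[alive]
    return RenewalStats(t_total, time_u, time_e, n_ue, n_eb, n_b, tau)


def shell_mfpt_analytic(b: float, R: float, r0: float, D: float) -> float:
    """Mean first-passage time of 3-d diffusion from radius ``r0`` to an
    absorbing sphere at ``b`` inside a reflecting sphere at ``R``:

        T(r0) = (1/D) [ (R^3/3)(1/b - 1/r0) - (r0^2 - b^2)/6 ]
    """
    if not (0 < b <= r0 <= R) or D <= 0:
        raise ValueError(f"need 0 < b <= r0 <= R and D > 0, got {(b, r0, R, D)}")
    return (R**3 / 3.0 * (1.0 / b - 1.0 / r0) - (r0**2 - b**2) / 6.0) / D


# ---------------------------------------------------------------------------
# engine adapter


class ToyPropagator:
    """Adapter exposing the toy model through the generic engine protocol.

    Walker dynamic states are flat float arrays ``[x, y, z, qw, qx, qy, qz]``.
    """

    state_size = 7

    def __init__(self, params: ToyParams):
        self.params = params

    def propagate_many(self, states: np.ndarray, n_steps: int, rng) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        pos, quat = propagate_arrays(
            states[:, :3], states[:, 3:], self.params, n_steps, rng
        )
        return np.concatenate([pos, quat], axis=-1)

    def pcoords(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        return self.params.pcoords(states[:, :3], states[:, 3:])

    @staticmethod
    def pack(state: ToyState) -> np.ndarray:
        return state.as_array()
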