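"""One-dimensional double-well Langevin system.

A minimal stochastic system with a known equilibrium distribution,
used to validate that weighted-ensemble resampling is unbiased: the
time-averaged WE bin probabilities must match both a long brute-force
trajectory histogram and the Boltzmann weights of the potential

    V(x) = h (x^2 - 1)^2

which has minima at x = +-1 separated by a barrier of height ``h`` (kT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = ["DoubleWell", "DoubleWellPropagator"]


@dataclass
class DoubleWell:
    """Overdamped particle in V(x) = h (x^2 - 1)^2, reduced units (kT=1)."""

    h: float = 3.0
    D: float = 1.0
    dt: float = 0.005
    kT: float = 1.0

    def potential(self, x):
        return self.h * (np.asarray(x) ** 2 - 1.0) ** 2

    def force(self, x):
        return -4.0 * self.h * x * (x**2 - 1.0)

    def propagate_batch(self, x: np.ndarray, n_steps: int, rng) -> np.ndarray:
        x = np.array(x, dtype=float, copy=True)
        drift = self.D / self.kT * self.dt
        noise = np.sqrt(2.0 * self.D * self.dt)
        for _ in range(n_steps):
            x += drift * self.force(x) + noise * rng.standard_normal(x.shape)
        return x

    def equilibrium_bin_probs(self, edges: np.ndarray) -> np.ndarray:
        """Boltzmann probability of each cell of a 1-d scheme.

        ``edges`` are left cell edges; the first cell extends to -inf and
        the last to +inf, matching the open-ended bin convention.
        """
        edges = np.asarray(edges, dtype=float)
        bounds = np.concatenate([[-np.inf], edges[1:], [np.inf]])
        dens = lambda x: np.exp(-self.potential(x) / self.kT)
        z = quad(dens, -np.inf, np.inf)[0]
        probs = np.array(
            [quad(dens, bounds[i], bounds[i + 1])[0] for i in range(len(edges))]
        )
        return probs / z


class DoubleWellPropagator:
    """Engine adapter: dynamic state is a length-1 array, pcoord is x itself."""

    state_size = 1

    def __init__(self, system: DoubleWell, ):
        self.system = system

    def propagate_many(self, states: np.ndarray, n_steps: int, rng) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        x = self.system.propagate_batch(states[:, 0], n_steps, rng)
        return x[:, None]

    def pcoords(self, states: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(states, dtype=float))[:, :1]
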