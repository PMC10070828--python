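"""Gravitational-search optimization of label confidences.

Each newly labeled batch of a self-training wave gets a confidence vector
mu^r in (0, 1]^I, chosen to minimize the propagation objective when those
confidences are plugged into the label-fit term.  Candidate vectors are the
positions of N particles that attract one another with forces proportional
to fitness-derived masses; the gravitational constant decays as
G(t) = G0 exp(-alpha t / T).  The best (minimum-fitness) position ever
visited is returned; a literal flag restores the final-population minimum.

Because F depends linearly on the confidences once (L + U) is fixed, the
fitness is an exact quadratic form in the particle position; the
:class:`ConfidenceProblem` precomputes that form so each evaluation costs
O(I^2) instead of a linear solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .config import Config
from .propagation import objective_value

logger = logging.getLogger(__name__)

POSITION_FLOOR = 1e-6   # confidences live in (0, 1]; 0 is disallowed


@dataclass
class GSAState:
    positions: np.ndarray        # (N, I), entries in (0, 1]
    velocities: np.ndarray       # (N, I)
    fitness: np.ndarray | None   # (N,) at current positions
    t: int
    best_fitness: float = np.inf
    best_position: np.ndarray | None = None


class ConfidenceProblem:
    """Fitness context for one self-training wave.

    Holds the Laplacian, the label-fit weights (which already include the
    wave's newly labeled rows), the frozen confidences of all previously
    labeled items, and the wave's row indices/classes.  ``fitness_of``
    evaluates a candidate confidence vector by recomputing F under it;
    ``fitness_batch`` evaluates a population through the precomputed
    quadratic form (identical values up to rounding).
    """

    def __init__(self, Lap: np.ndarray, U_diag: np.ndarray, Y: np.ndarray,
                 mu_fixed: np.ndarray, new_indices: np.ndarray,
                 new_classes: np.ndarray):
        self.Lap = np.asarray(Lap, dtype=float)
        self.U_diag = np.asarray(U_diag, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        self.mu_fixed = np.asarray(mu_fixed, dtype=float)
        self.new_indices = np.asarray(new_indices, dtype=int)
        self.new_classes = np.asarray(new_classes, dtype=int)
        self.I = len(self.new_indices)
        K = self.Lap + np.diag(self.U_diag)
        self._cho = cho_factor(K)
        self._quad = None

    # -- direct route -----------------------------------------------------
    def embed(self, conf: np.ndarray) -> np.ndarray:
        """Full mu matrix with the candidate confidences at the wave rows."""
        mu = self.mu_fixed.copy()
        mu[self.new_indices, self.new_classes] = conf
        return mu

    def solve_full(self, conf: np.ndarray) -> np.ndarray:
        """Prediction matrix F under the candidate confidence vector."""
        mu = self.embed(conf)
        rhs = self.U_diag[:, None] * (mu * self.Y)
        return cho_solve(self._cho, rhs)

    def fitness_of(self, conf: np.ndarray) -> float:
        conf = np.asarray(conf, dtype=float)
        mu = self.embed(conf)
        F = self.solve_full(conf)
        return objective_value(F, self.Lap, self.U_diag, mu, self.Y)

    # -- quadratic route --------------------------------------------------
    def _quadratic(self):
        """Exact (Q, b, c) with fitness(v) = v^T Q v + b^T v + c.

        Fitted from 1 + 2I + I(I-1)/2 direct evaluations; exact because the
        objective is quadratic in the confidences.
        """
        if self._quad is not None:
            return self._quad
        I = self.I
        f = self.fitness_of
        c0 = f(np.zeros(I))
        b = np.zeros(I)
        Q = np.zeros((I, I))
        e = np.eye(I)
        f1 = np.array([f(e[i]) for i in range(I)])
        f2 = np.array([f(2 * e[i]) for i in range(I)])
        for i in range(I):
            Q[i, i] = (f2[i] - 2 * f1[i] + c0) / 2.0
            b[i] = f1[i] - c0 - Q[i, i]
        for i in range(I):
            for j in range(i + 1, I):
                fij = f(e[i] + e[j])
                Q[i, j] = Q[j, i] = (fij - c0 - b[i] - b[j]
                                     - Q[i, i] - Q[j, j]) / 2.0
        self._quad = (Q, b, c0)
        return self._quad

    def fitness_batch(self, positions: np.ndarray) -> np.ndarray:
        Q, b, c0 = self._quadratic()
        P = np.atleast_2d(positions)
        return np.einsum("ai,ij,aj->a", P, Q, P) + P @ b + c0


def init_particles(I: int, N: int, rng: np.random.Generator) -> GSAState:
    """Positions uniform on (0, 1], velocities exactly zero, t = 0."""
    if I < 1:
        raise ValueError("need at least one dimension")
    if N < 1:
        raise ValueError("need at least one particle")
    positions = 1.0 - rng.random((N, I))        # (0, 1]
    return GSAState(positions=positions, velocities=np.zeros((N, I)),
                    fitness=None, t=0)


def gravitational_constant(t: float, G0: float = 100.0, alpha: float = 20.0,
                           T: int = 100) -> float:
    """G(t) = G0 * exp(-alpha * t / T)."""
    return float(G0 * np.exp(-alpha * t / T))


def masses_from_fitness(fitness: np.ndarray) -> np.ndarray:
    """Normalized inertial masses for a minimization problem.

    m_a = (fitness_a - worst)/(best - worst) with best = min, worst = max,
    then M = m / sum(m).  All-equal fitness degenerates to uniform 1/N with
    a warning.
    """
    fitness = np.asarray(fitness, dtype=float)
    N = len(fitness)
    best, worst = fitness.min(), fitness.max()
    if best == worst:
        warnings.warn("all particles share one fitness value; uniform masses",
                      RuntimeWarning, stacklevel=2)
        return np.full(N, 1.0 / N)
    m = (fitness - worst) / (best - worst)
    return m / m.sum()


def gsa_step(state: GSAState, masses: np.ndarray, G: float, eps: float,
             rng: np.random.Generator) -> GSAState:
    """One synchronous swarm update (forces, accelerations, velocities,
    positions) with fresh random weights; positions clamped into (0, 1]."""
    pos, vel = state.positions, state.velocities
    N, I = pos.shape
    diff = pos[None, :, :] - pos[:, None, :]            # [a, b, i] = mu_b - mu_a
    R = np.linalg.norm(diff, axis=2)                    # (N, N)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = G * (masses[:, None] * masses[None, :]) / (R + eps)
    np.fill_diagonal(coef, 0.0)                         # force sums over b != a
    rand_b = rng.random((N, N, I))                      # per pair, per dimension
    force = (rand_b * coef[:, :, None] * diff).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = np.where(masses[:, None] > 0, force / masses[:, None], 0.0)
    rand_a = rng.random(N)                              # per particle
    vel = rand_a[:, None] * vel + acc
    pos = np.clip(pos + vel, POSITION_FLOOR, 1.0)
    return GSAState(positions=pos, velocities=vel, fitness=None,
                    t=state.t + 1, best_fitness=state.best_fitness,
                    best_position=state.best_position)


def _record_best(state: GSAState, fitness: np.ndarray) -> None:
    k = int(np.argmin(fitness))
    state.fitness = fitness
    if fitness[k] < state.best_fitness:
        state.best_fitness = float(fitness[k])
        state.best_position = state.positions[k].copy()


def optimize_confidence(problem: ConfidenceProblem, config: Config,
                        seed: int, T: int | None = None,
                        exact_fitness: bool = False
                        ) -> tuple[np.ndarray, list[float]]:
    """Run the swarm for T steps; return (confidence vector, fitness trace).

    The trace records the best fitness seen up to each time step (elitist,
    hence non-increasing).  With a single particle the optimizer degenerates
    to returning its clamped initial position.
    """
    if T is None:
        T = config.gsa_T
    rng = np.random.default_rng(seed)
    N, I = config.gsa_N, problem.I
    state = init_particles(I, N, rng)

    def evaluate(positions: np.ndarray) -> np.ndarray:
        if exact_fitness:
            return np.array([problem.fitness_of(p) for p in positions])
        return problem.fitness_batch(positions)

    fit = evaluate(state.positions)
    _record_best(state, fit)
    trace = [state.best_fitness]
    if N == 1:
        return np.clip(state.positions[0], POSITION_FLOOR, 1.0), trace
    for t in range(1, T + 1):
        masses = masses_from_fitness(state.fitness)
        G = gravitational_constant(t, config.gsa_G0, config.gsa_alpha, T)
        state = gsa_step(state, masses, G, config.epsilon, rng)
        fit = evaluate(state.positions)
        _record_best(state, fit)
        trace.append(state.best_fitness)
    if config.literal_final_population:
        return state.positions[int(np.argmin(state.fitness))].copy(), trace
    return state.best_position.copy(), trace
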