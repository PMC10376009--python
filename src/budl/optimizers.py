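"""Population-based binary metaheuristics for wrapper feature selection.

Ten optimizers search the continuous box [0, 1]^d; positions are thresholded
into binary feature masks (strictly above 0.5 by default), all-zero masks are
repaired to a random single feature, and masks are scored by the SVM cost of
:mod:`budl.fitness`.  A global best is maintained across the run (elitism),
so the convergence trace is non-increasing for every scheme.

The update schemes follow the canonical equations of each algorithm's
original publication:

* MPA  — marine predators: Brownian / mixed / Levy predation phases with
  memory saving and a fish-aggregating-devices (FADs) perturbation.
* GNDO — generalized-normal-distribution sampling around the population
  mean/best, alternated with random pairwise exploration jumps.
* SMA  — slime mould: fitness-ranked weights and an oscillation amplitude
  shrinking as arctanh(1 - t/T), with a small random-restart probability.
* EO   — equilibrium optimizer: pool of the four best-ever states plus their
  mean, exponential concentration decay and a generation-rate term.
* MRFO — manta rays: chain / cyclone / somersault foraging.
* ASO  — atoms with Lennard-Jones-style interaction forces and a bond
  constraint toward the best atom, integrated through velocities.
* HHO  — Harris hawks: escape-energy schedule switching exploration, soft and
  hard besiege, and Levy-flight rapid dives.
* HGSO — Henry-law gas clusters with temperature-driven solubility updates
  and worst-agent re-initialization.
* PFA  — pathfinder: perturbed leader update plus follower moves with
  neighbour interaction and decaying vibration.
* PRO  — poor-and-rich: rich half repelled from the best poor agent, poor
  half pulled toward a rich exemplar pattern, with sparse random mutation.

All randomness flows through one ``numpy`` Generator seeded from the config,
so a run is fully determined by (algorithm, seed, fitness).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .extraction import FeatureTable
from .fitness import CostConfig, FitnessEvaluator, HoldoutSplit, SVMSettings, make_fitness

__all__ = [
    "ALGORITHMS",
    "OptimizerConfig",
    "ConvergenceTrace",
    "SelectionResult",
    "ContinuousResult",
    "binarize",
    "repair_mask",
    "run_optimizer",
    "minimize_continuous",
]

ALGORITHMS = ("mpa", "gndo", "sma", "eo", "mrfo", "aso", "hho", "hgso", "pfa", "pro")


@dataclass(frozen=True)
class OptimizerConfig:
    """Search-budget and algorithm parameters for one optimizer run."""

    algorithm: str
    population_size: int = 10
    max_iterations: int = 100
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    seed: int = 0
    binarize_threshold: float = 0.5
    algo_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid names: {', '.join(ALGORITHMS)}"
            )
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in (0, 1)")


@dataclass
class ConvergenceTrace:
    """Per-iteration global-best cost (and, in binary mode, accuracy/size)."""

    best_cost: list[float] = field(default_factory=list)
    best_accuracy: list[float] = field(default_factory=list)
    best_n_selected: list[int] = field(default_factory=list)

    def append(self, cost: float, accuracy: float | None, n_selected: int | None) -> None:
        self.best_cost.append(float(cost))
        if accuracy is not None:
            self.best_accuracy.append(float(accuracy))
        if n_selected is not None:
            self.best_n_selected.append(int(n_selected))

    def __len__(self) -> int:
        return len(self.best_cost)

    @property
    def is_monotone(self) -> bool:
        c = self.best_cost
        return all(c[i + 1] <= c[i] + 1e-15 for i in range(len(c) - 1))


@dataclass
class SelectionResult:
    """Outcome of one wrapper-based feature-selection run."""

    best_mask: np.ndarray
    best_cost: float
    best_accuracy: float
    n_selected: int
    trace: ConvergenceTrace
    elapsed_seconds: float
    algorithm: str
    seed: int
    feature_ids: list[str] | None = None

    @property
    def selected_feature_ids(self) -> list[str]:
        if self.feature_ids is None:
            raise ValueError("result carries no feature provenance")
        return [fid for fid, m in zip(self.feature_ids, self.best_mask) if m]


@dataclass
class ContinuousResult:
    """Outcome of a raw-continuous benchmark run (no binarization)."""

    best_position: np.ndarray
    best_value: float
    trace: ConvergenceTrace
    algorithm: str
    seed: int


# ---------------------------------------------------------------------------
# Binarization and repair
# ---------------------------------------------------------------------------


def binarize(position, threshold: float = 0.5) -> np.ndarray:
    """Map a continuous position to a 0/1 mask: bit set iff coordinate > threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(position, dtype=float) > threshold).astype(np.int8)


def repair_mask(mask, rng: np.random.Generator) -> np.ndarray:
    """Activate one uniformly chosen bit if the mask is all-zero; else identity."""
    mask = np.asarray(mask, dtype=np.int8)
    if mask.sum() == 0:
        mask = mask.copy()
        mask[rng.integers(mask.shape[0])] = 1
    return mask


# ---------------------------------------------------------------------------
# Objectives: masks scored by the SVM cost, or raw continuous functions
# ---------------------------------------------------------------------------


class _MaskObjective:
    """Binarize + repair a position and score its mask; tracks the global best.

    Ties are broken first-found: the incumbent is replaced only on a strictly
    smaller cost, so for a fixed seed the reported best is stable.
    """

    def __init__(self, evaluator: FitnessEvaluator, rng: np.random.Generator, threshold: float):
        self._evaluator = evaluator
        self._rng = rng
        self._threshold = threshold
        self.best_cost = math.inf
        self.best_position: np.ndarray | None = None
        self.best_mask: np.ndarray | None = None
        self.best_fit = None

    @property
    def best_accuracy(self):
        return None if self.best_fit is None else self.best_fit.accuracy

    @property
    def best_n_selected(self):
        return None if self.best_fit is None else self.best_fit.n_selected

    def evaluate(self, position: np.ndarray) -> float:
        mask = repair_mask(binarize(position, self._threshold), self._rng)
        fit = self._evaluator(mask)
        if fit.cost < self.best_cost:
            self.best_cost = fit.cost
            self.best_position = np.asarray(position, dtype=float).copy()
            self.best_mask = mask.copy()
            self.best_fit = fit
        return fit.cost


class _FunctionObjective:
    """Raw-continuous test mode: score the position itself."""

    def __init__(self, fun: Callable[[np.ndarray], float]):
        self._fun = fun
        self.best_cost = math.inf
        self.best_position: np.ndarray | None = None
        self.best_accuracy = None
        self.best_n_selected = None

    def evaluate(self, position: np.ndarray) -> float:
        value = float(self._fun(np.asarray(position, dtype=float)))
        if value < self.best_cost:
            self.best_cost = value
            self.best_position = np.asarray(position, dtype=float).copy()
        return value


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------


def _levy(rng: np.random.Generator, shape, beta: float = 1.5) -> np.ndarray:
    # Mantegna's algorithm for Levy-stable step lengths
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma, shape)
    v = rng.normal(0.0, 1.0, shape)
    return u / np.abs(v) ** (1 / beta)


def _evaluate_rows(positions: np.ndarray, objective) -> np.ndarray:
    return np.array([objective.evaluate(p) for p in positions])


def _greedy(pos, costs, new_pos, objective, lb, ub):
    """Evaluate candidate positions; accept per-agent only on improvement."""
    new_pos = np.clip(new_pos, lb, ub)
    new_costs = _evaluate_rows(new_pos, objective)
    better = new_costs < costs
    pos[better] = new_pos[better]
    costs[better] = new_costs[better]
    return pos, costs


def _replace(new_pos, objective, lb, ub):
    """Evaluate candidate positions and adopt them unconditionally."""
    new_pos = np.clip(new_pos, lb, ub)
    return new_pos, _evaluate_rows(new_pos, objective)


def initialize_population(d: int, config: OptimizerConfig, objective, rng: np.random.Generator):
    """Uniform positions in the box, evaluated; returns (positions, costs)."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    lb, ub = config.lower_bound, config.upper_bound
    pos = lb + rng.random((config.population_size, d)) * (ub - lb)
    return pos, _evaluate_rows(pos, objective)


# ---------------------------------------------------------------------------
# The ten update schemes
# ---------------------------------------------------------------------------


def _step_mpa(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    P = params.get("constant_p", 0.5)
    fads = params.get("fads", 0.2)
    elite = np.tile(objective.best_position, (N, 1))
    CF = (1.0 - t / T) ** (2.0 * t / T)
    R = rng.random((N, d))
    new = pos.copy()
    if t <= T / 3:  # high-velocity prey: Brownian exploration
        RB = rng.standard_normal((N, d))
        step = RB * (elite - RB * pos)
        new = pos + P * R * step
    elif t <= 2 * T / 3:  # unit-velocity: half Levy prey, half Brownian predator
        half = N // 2
        RL = _levy(rng, (N, d))
        RB = rng.standard_normal((N, d))
        step1 = RL[:half] * (elite[:half] - RL[:half] * pos[:half])
        new[:half] = pos[:half] + P * R[:half] * step1
        step2 = RB[half:] * (RB[half:] * elite[half:] - pos[half:])
        new[half:] = elite[half:] + P * CF * step2
    else:  # low-velocity prey: Levy predator
        RL = _levy(rng, (N, d))
        step = RL * (RL * elite - pos)
        new = elite + P * CF * step
    pos, costs = _greedy(pos, costs, new, objective, lb, ub)  # memory saving

    # FADs effect / eddy formation
    r = rng.random()
    if r < fads:
        U = (rng.random((N, d)) < fads).astype(float)
        new = pos + CF * (lb + rng.random((N, d)) * (ub - lb)) * U
    else:
        p1 = rng.permutation(N)
        p2 = rng.permutation(N)
        new = pos + (fads * (1 - r) + r) * (pos[p1] - pos[p2])
    return _greedy(pos, costs, new, objective, lb, ub)


def _step_gndo(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    best = objective.best_position
    mean = pos.mean(axis=0)
    new = pos.copy()
    for i in range(N):
        if rng.random() > 0.5:
            # local exploitation: sample a generalized-normal model around
            # (agent, best, population mean)
            mu = (pos[i] + best + mean) / 3.0
            delta = np.sqrt(((pos[i] - mu) ** 2 + (best - mu) ** 2 + (mean - mu) ** 2) / 3.0)
            lam1 = rng.random(d)
            lam2 = rng.random(d)
            if rng.random() <= 0.5:
                eta = np.sqrt(-np.log(np.maximum(lam1, 1e-300))) * np.cos(2 * np.pi * lam2)
            else:
                eta = np.sqrt(-np.log(np.maximum(lam1, 1e-300))) * np.cos(2 * np.pi * lam2 + np.pi)
            new[i] = mu + delta * eta
        else:
            # global exploration: random pairwise jumps
            others = [k for k in range(N) if k != i]
            p1, p2, p3 = rng.choice(others, size=3, replace=False)
            v1 = pos[i] - pos[p1] if costs[i] < costs[p1] else pos[p1] - pos[i]
            v2 = pos[p2] - pos[p3] if costs[p2] < costs[p3] else pos[p3] - pos[p2]
            beta = rng.random()
            lam3 = rng.standard_normal(d)
            lam4 = rng.standard_normal(d)
            new[i] = pos[i] + beta * np.abs(lam3) * v1 + (1 - beta) * np.abs(lam4) * v2
    return _greedy(pos, costs, new, objective, lb, ub)


def _step_sma(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    z = params.get("restart_prob", 0.03)
    order = np.argsort(costs)
    bF, wF = costs[order[0]], costs[order[-1]]
    spread = bF - wF - 1e-300
    W = np.ones((N, d))
    for rank, i in enumerate(order):
        frac = np.log10((bF - costs[i]) / spread + 1.0)
        if rank < N // 2:
            W[i] = 1.0 + rng.random(d) * frac
        else:
            W[i] = 1.0 - rng.random(d) * frac
    a = np.arctanh(max(1.0 - t / T, 1e-12))
    b = 1.0 - t / T
    best = objective.best_position
    p = np.tanh(np.abs(costs - objective.best_cost))
    new = pos.copy()
    for i in range(N):
        if rng.random() < z:
            new[i] = lb + rng.random(d) * (ub - lb)
        elif rng.random() < p[i]:
            vb = rng.uniform(-a, a, d)
            A, B = rng.integers(0, N, size=2)
            new[i] = best + vb * (W[i] * pos[A] - pos[B])
        else:
            vc = rng.uniform(-b, b, d)
            new[i] = vc * pos[i]
    return _replace(new, objective, lb, ub)


def _step_eo(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    a1 = params.get("constant1", 2.0)
    a2 = params.get("constant2", 1.0)
    GP = params.get("generation_prob", 0.5)
    V = 1.0

    # equilibrium pool: four best states seen so far, plus their mean
    if "eo_pool" not in aux:
        order = np.argsort(costs)[:4]
        aux["eo_pool"] = [pos[i].copy() for i in order]
        aux["eo_pool_costs"] = [float(costs[i]) for i in order]
    pool, pool_costs = aux["eo_pool"], aux["eo_pool_costs"]
    for i in range(N):
        for s in range(len(pool)):
            if costs[i] < pool_costs[s]:
                pool.insert(s, pos[i].copy())
                pool_costs.insert(s, float(costs[i]))
                del pool[4:], pool_costs[4:]
                break
    candidates = pool + [np.mean(pool, axis=0)]

    t_factor = (1.0 - t / T) ** (a2 * t / T)
    lam = rng.random((N, d))
    r = rng.random((N, d))
    choice = rng.integers(0, len(candidates), size=N)
    Ceq = np.array([candidates[c] for c in choice])
    F = a1 * np.sign(r - 0.5) * (np.exp(-lam * t_factor) - 1.0)
    r1 = rng.random(N)
    r2 = rng.random(N)
    GCP = np.where(r2 >= GP, 0.5 * r1, 0.0)[:, None]
    G0 = GCP * (Ceq - lam * pos)
    G = G0 * F
    new = Ceq + (pos - Ceq) * F + (G / (lam * V + 1e-300)) * (1.0 - F)
    return _replace(new, objective, lb, ub)


def _step_mrfo(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    S = params.get("somersault", 2.0)
    best = objective.best_position
    new = pos.copy()
    for i in range(N):
        prev = new[i - 1] if i > 0 else None
        if rng.random() < 0.5:  # cyclone foraging
            r1 = rng.random()
            beta = 2.0 * math.exp(r1 * (T - t + 1) / T) * math.sin(2 * math.pi * r1)
            r = rng.random(d)
            if t / T < rng.random():  # spiral around a random reference (exploration)
                xrand = lb + rng.random(d) * (ub - lb)
                anchor = prev if prev is not None else xrand
                new[i] = xrand + r * (anchor - pos[i]) + beta * (xrand - pos[i])
            else:  # spiral around the best (exploitation)
                anchor = prev if prev is not None else best
                new[i] = best + r * (anchor - pos[i]) + beta * (best - pos[i])
        else:  # chain foraging
            r = rng.random(d)
            alpha = 2.0 * r * np.sqrt(np.abs(np.log(np.maximum(r, 1e-300))))
            anchor = prev if prev is not None else best
            new[i] = pos[i] + r * (anchor - pos[i]) + alpha * (best - pos[i])
    pos, costs = _greedy(pos, costs, new, objective, lb, ub)

    # somersault foraging around the updated best
    best = objective.best_position
    r2 = rng.random((N, d))
    r3 = rng.random((N, d))
    new = pos + S * (r2 * best - r3 * pos)
    return _greedy(pos, costs, new, objective, lb, ub)


def _step_aso(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    alpha = params.get("depth_weight", 50.0)
    beta = params.get("multiplier_weight", 0.2)
    vel = aux.setdefault("aso_vel", np.zeros((N, d)))
    best = objective.best_position

    best_c, worst_c = costs.min(), costs.max()
    M = np.exp(-(costs - best_c) / (worst_c - best_c + 1e-12))
    m = M / M.sum()
    G = math.exp(-20.0 * t / T)
    K = max(2, int(math.ceil(N - (N - 2) * math.sqrt(t / T))))
    kidx = np.argsort(costs)[:K]
    mean_k = pos[kidx].mean(axis=0)
    eta = alpha * (1.0 - (t - 1) / T) ** 3 * G

    F = np.zeros_like(pos)
    for i in range(N):
        sigma = np.linalg.norm(pos[i] - mean_k) + 1e-12
        for j in kidx:
            if j == i:
                continue
            diff = pos[j] - pos[i]
            r = np.linalg.norm(diff) + 1e-12
            h = min(max(r / sigma, 1.1), 1.24)
            # LJ-window force: repulsive below the equilibrium ratio,
            # attractive above it (keeps the swarm cohesive around Kbest)
            F[i] += rng.random(d) * eta * -(2.0 * h ** -13 - h ** -7) * diff / r
    Gc = beta * G * (best - pos)  # bond-length constraint toward the best atom
    acc = (F + Gc) / m[:, None]
    np.clip(acc, -(ub - lb), ub - lb, out=acc)  # cap blow-up at early iterations
    vel = rng.random((N, d)) * vel + acc
    aux["aso_vel"] = vel
    return _replace(pos + vel, objective, lb, ub)


def _step_hho(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    rabbit = objective.best_position
    xmean = pos.mean(axis=0)
    new_pos = pos.copy()
    new_costs = costs.copy()
    for i in range(N):
        E0 = 2.0 * rng.random() - 1.0
        E = 2.0 * E0 * (1.0 - t / T)
        J = 2.0 * (1.0 - rng.random())
        if abs(E) >= 1.0:  # exploration
            if rng.random() >= 0.5:
                xr = pos[rng.integers(N)]
                cand = xr - rng.random() * np.abs(xr - 2.0 * rng.random() * pos[i])
            else:
                cand = (rabbit - xmean) - rng.random() * (lb + rng.random() * (ub - lb))
            cand = np.clip(cand, lb, ub)
            new_pos[i], new_costs[i] = cand, objective.evaluate(cand)
        else:
            r = rng.random()
            if r >= 0.5 and abs(E) >= 0.5:  # soft besiege
                cand = (rabbit - pos[i]) - E * np.abs(J * rabbit - pos[i])
                cand = np.clip(cand, lb, ub)
                new_pos[i], new_costs[i] = cand, objective.evaluate(cand)
            elif r >= 0.5:  # hard besiege
                cand = rabbit - E * np.abs(rabbit - pos[i])
                cand = np.clip(cand, lb, ub)
                new_pos[i], new_costs[i] = cand, objective.evaluate(cand)
            else:  # progressive rapid dives (Levy flights), greedy
                base = pos[i] if abs(E) >= 0.5 else xmean
                Y = np.clip(rabbit - E * np.abs(J * rabbit - base), lb, ub)
                fY = objective.evaluate(Y)
                if fY < costs[i]:
                    new_pos[i], new_costs[i] = Y, fY
                else:
                    Z = np.clip(Y + rng.random(d) * _levy(rng, d), lb, ub)
                    fZ = objective.evaluate(Z)
                    if fZ < costs[i]:
                        new_pos[i], new_costs[i] = Z, fZ
    return new_pos, new_costs


def _step_hgso(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    n_types = int(params.get("n_gas_types", 2))
    n_reinit = int(params.get("worst_reinit", 1))
    if "hgso_H" not in aux:
        aux["hgso_cluster"] = np.arange(N) * n_types // N
        aux["hgso_H"] = 5e-2 * rng.random(n_types)   # Henry constants
        aux["hgso_P"] = 100.0 * rng.random(N)        # partial pressures
        aux["hgso_C"] = 1e-2 * rng.random(n_types)   # van 't Hoff constants
    cluster = aux["hgso_cluster"]
    Ttemp = math.exp(-t / T)
    T0 = 298.15
    aux["hgso_H"] = aux["hgso_H"] * np.exp(-aux["hgso_C"] * (1.0 / Ttemp - 1.0 / T0))
    S = aux["hgso_H"][cluster] * aux["hgso_P"]  # solubility, Henry's law

    best = objective.best_position
    eps = 0.05
    gamma = np.exp(-(objective.best_cost + eps) / (costs + eps))
    # best agent of each gas cluster
    cl_best = np.empty((N, d))
    for c in range(n_types):
        members = np.flatnonzero(cluster == c)
        cl_best[members] = pos[members[np.argmin(costs[members])]]
    Fdir = np.where(rng.random(N) < 0.5, 1.0, -1.0)[:, None]
    r1 = rng.random((N, d))
    r2 = rng.random((N, d))
    new = (
        pos
        + Fdir * r1 * gamma[:, None] * (cl_best - pos)
        + Fdir * r2 * (S[:, None] * best - pos)
    )
    pos, costs = _replace(new, objective, lb, ub)

    # rank worst agents and re-initialize them
    worst = np.argsort(costs)[::-1][:n_reinit]
    for i in worst:
        pos[i] = lb + rng.random(d) * (ub - lb)
        costs[i] = objective.evaluate(pos[i])
    return pos, costs


def _step_pfa(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    leader = int(np.argmin(costs))
    prev = aux.setdefault("pfa_prev", pos[leader].copy())

    # pathfinder update with decaying vibration A
    u2 = rng.uniform(-1.0, 1.0, d)
    A = u2 * math.exp(-2.0 * t / T)
    cand = pos[leader] + 2.0 * rng.random() * (pos[leader] - prev) + A
    aux["pfa_prev"] = pos[leader].copy()
    cand = np.clip(cand, lb, ub)
    fc = objective.evaluate(cand)
    if fc < costs[leader]:
        pos[leader], costs[leader] = cand, fc

    # follower updates toward a neighbour and the pathfinder
    alpha = rng.uniform(1.0, 2.0)
    beta = rng.uniform(1.0, 2.0)
    path = pos[leader]
    new = pos.copy()
    for i in range(N):
        if i == leader:
            continue
        j = rng.integers(N - 1)
        j = j if j < i else j + 1
        epsilon = (1.0 - t / T) * rng.uniform(-1.0, 1.0, d) * np.linalg.norm(pos[i] - pos[j])
        new[i] = (
            pos[i]
            + alpha * rng.random(d) * (pos[j] - pos[i])
            + beta * rng.random(d) * (path - pos[i])
            + epsilon
        )
    return _greedy(pos, costs, new, objective, lb, ub)


def _step_pro(pos, costs, aux, t, T, rng, objective, lb, ub, params):
    N, d = pos.shape
    pmut = params.get("mutation_prob", 0.06)
    order = np.argsort(costs)
    half = max(1, N // 2)
    rich, poor = order[:half], order[half:]
    rich_best = pos[order[0]]
    rich_mean = pos[rich].mean(axis=0)
    poor_best = pos[poor[0]] if poor.size else pos[order[-1]]

    new = pos.copy()
    for i in rich:  # rich widen the gap from the best poor agent
        new[i] = pos[i] + rng.random(d) * (pos[i] - poor_best)
    pattern = (rich_best + rich_mean) / 2.0
    for i in poor:  # poor imitate a rich exemplar pattern
        new[i] = pos[i] + rng.random(d) * (pattern - pos[i])
    mutate = rng.random((N, d)) < pmut
    new = np.where(mutate, lb + rng.random((N, d)) * (ub - lb), new)
    return _greedy(pos, costs, new, objective, lb, ub)


_STEP_FUNCS = {
    "mpa": _step_mpa,
    "gndo": _step_gndo,
    "sma": _step_sma,
    "eo": _step_eo,
    "mrfo": _step_mrfo,
    "aso": _step_aso,
    "hho": _step_hho,
    "hgso": _step_hgso,
    "pfa": _step_pfa,
    "pro": _step_pro,
}

_PARAM_DEFAULTS = {
    "mpa": {"fads": 0.2, "constant_p": 0.5},
    "gndo": {},
    "sma": {"restart_prob": 0.03},
    "eo": {"constant1": 2.0, "constant2": 1.0, "generation_prob": 0.5},
    "mrfo": {"somersault": 2.0},
    "aso": {"depth_weight": 50.0, "multiplier_weight": 0.2},
    "hho": {},
    "hgso": {"n_gas_types": 2, "worst_reinit": 1},
    "pfa": {},
    "pro": {"mutation_prob": 0.06},
}


def update_population(algorithm, pos, costs, aux, t, T, rng, objective, lb, ub, algo_params=None):
    """Apply one full iteration of the named scheme; returns (positions, costs).

    Positions are clipped to the box, candidate masks are binarized/repaired
    and evaluated inside the objective, and the global best can only improve.
    """
    if algorithm not in _STEP_FUNCS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid names: {', '.join(ALGORITHMS)}"
        )
    params = dict(_PARAM_DEFAULTS[algorithm])
    params.update(algo_params or {})
    if not 1 <= t <= T:
        raise ValueError("iteration index t must satisfy 1 <= t <= T")
    return _STEP_FUNCS[algorithm](pos, costs, aux, t, T, rng, objective, lb, ub, params)


def _run_search(objective, d: int, config: OptimizerConfig) -> ConvergenceTrace:
    rng = np.random.default_rng(config.seed)
    pos, costs = initialize_population(d, config, objective, rng)
    aux: dict = {}
    trace = ConvergenceTrace()
    T = config.max_iterations
    for t in range(1, T + 1):
        pos, costs = update_population(
            config.algorithm, pos, costs, aux, t, T, rng, objective,
            config.lower_bound, config.upper_bound, config.algo_params,
        )
        trace.append(objective.best_cost, objective.best_accuracy, objective.best_n_selected)
    return trace


def run_optimizer(
    table: FeatureTable,
    split: HoldoutSplit,
    cost_config: CostConfig,
    optimizer_config: OptimizerConfig,
    svm_settings: SVMSettings = SVMSettings(),
    fitness: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Run one wrapper-based feature-selection search over a feature table.

    An existing :class:`FitnessEvaluator` may be passed to share its mask
    cache across runs on the same table/split (results are unaffected).
    """
    if table.n_features == 0:
        raise ValueError("feature table has no columns")
    if len(table.classes) < 2:
        raise ValueError("feature table must contain at least 2 classes")
    evaluator = fitness or make_fitness(table, split, cost_config, svm_settings)
    rng_repair = np.random.default_rng(optimizer_config.seed)
    objective = _MaskObjective(evaluator, rng_repair, optimizer_config.binarize_threshold)
    start = time.perf_counter()
    trace = _run_search(objective, table.n_features, optimizer_config)
    elapsed = time.perf_counter() - start
    return SelectionResult(
        best_mask=objective.best_mask.copy(),
        best_cost=objective.best_cost,
        best_accuracy=objective.best_fit.accuracy,
        n_selected=objective.best_fit.n_selected,
        trace=trace,
        elapsed_seconds=elapsed,
        algorithm=optimizer_config.algorithm,
        seed=optimizer_config.seed,
        feature_ids=list(table.feature_ids),
    )


def minimize_continuous(fun, d: int, config: OptimizerConfig) -> ContinuousResult:
    """Raw-continuous test mode: minimize ``fun`` over the box, no binarization."""
    objective = _FunctionObjective(fun)
    trace = _run_search(objective, d, config)
    return ContinuousResult(
        best_position=objective.best_position.copy(),
        best_value=objective.best_cost,
        trace=trace,
        algorithm=config.algorithm,
        seed=config.seed,
    )
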