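"""Genetic optimization of muscle activation patterns.

The controller is a per-actuator piecewise-constant activation pattern:
``n_phases`` phase durations and levels per actuator, with left and right
limb activations implicitly identical and in phase (the planar model
collapses bilateral pairs).  Optionally, tendon-length scale genes bounded
to +/-10% are attached to designated actuators (typically the
uniarticular extensors), letting the optimizer trade series-elastic slack
against contractile range.

Fitness of a genome is the maximum vertical CoM position reached within
the time limit; solutions that break a long-bone stress constraint (or
blow up numerically) receive a -inf sentinel and rank below every finite
fitness.  The search is a plain generational GA: tournament selection
(size 2), uniform crossover, Gaussian mutation clipped to bounds, and
elitism, which makes the best-of-generation history monotone
non-decreasing.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .model import Model
from . import dynamics
from .dynamics import simulate
from .muscles import path_length_m

__all__ = [
    "ControllerGenome",
    "GAConfig",
    "GAResult",
    "evaluate_genome",
    "run_ga",
    "time_limit_sweep",
    "DISCARDED",
]

#: sentinel fitness for discarded (bone-stress / blow-up) solutions
DISCARDED = -np.inf


@dataclass
class ControllerGenome:
    """Piecewise-constant activation pattern plus optional tendon genes.

    ``durations`` are non-negative phase weights per actuator, normalized
    to the simulation time limit when the schedule is built; ``levels`` are
    activations clipped to [0, 1].  ``tendon_scales`` multiply the tendon
    slack length of the actuators carrying tendon genes.
    """

    durations: np.ndarray  # (n_muscles, n_phases)
    levels: np.ndarray  # (n_muscles, n_phases)
    tendon_scales: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.levels = np.clip(np.asarray(self.levels, dtype=float), 0.0, 1.0)
        if (self.durations < 0).any():
            raise ValueError("phase durations must be non-negative")

    @property
    def n_phases(self) -> int:
        return self.durations.shape[1]

    def schedule(self, time_limit: float) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative phase end times and levels for the simulator."""
        d = self.durations.copy()
        tot = d.sum(axis=1, keepdims=True)
        flat = tot[:, 0] <= 0
        if flat.any():
            d[flat] = 1.0
            tot = d.sum(axis=1, keepdims=True)
        times = np.cumsum(d / tot * time_limit, axis=1)
        return times, self.levels.copy()


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 200
    crossover_rate: float = 0.7
    mutation_rate: float = 0.15
    mutation_scale: float = 0.15  # Gaussian sd as a fraction of the gene range
    elitism: int = 1
    seed: int = 0
    time_limit: float = 1.0
    n_replicates: int = 25
    n_phases: int = 6
    sim_dt: float = dynamics.DEFAULT_DT
    use_tendon_genes: bool = False
    tendon_gene_bounds: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.elitism < 1:
            raise ValueError("elitism must be at least 1 (monotone best fitness)")


@dataclass
class GAResult:
    best_genome: ControllerGenome
    best_fitness: float
    history: np.ndarray  # best fitness per generation (monotone)
    seed: int
    best_trajectory: Optional[dynamics.Trajectory] = None


# ---------------------------------------------------------------------------
# genome <-> flat vector
# ---------------------------------------------------------------------------

def _tendon_gene_actuators(model: Model, cfg: GAConfig) -> list[int]:
    if not cfg.use_tendon_genes:
        return []
    idx = [i for i, a in enumerate(model.actuators) if a.tendon_gene_bounds is not None]
    if not idx:
        # fall back to every uniarticular extensor, the conventional target
        idx = [
            i
            for i, a in enumerate(model.actuators)
            if a.uniarticular and any(k == "extensor" for _, k in a.actions)
        ]
    return idx


def _bounds(model: Model, cfg: GAConfig):
    nm = len(model.actuators)
    nph = cfg.n_phases
    tgenes = _tendon_gene_actuators(model, cfg)
    n = 2 * nm * nph + len(tgenes)
    lo = np.zeros(n)
    hi = np.ones(n)
    for k, ai in enumerate(tgenes):
        b = model.actuators[ai].tendon_gene_bounds or cfg.tendon_gene_bounds
        lo[2 * nm * nph + k] = b[0]
        hi[2 * nm * nph + k] = b[1]
    return lo, hi, (nm, nph, tgenes)


def _decode(vec: np.ndarray, meta) -> ControllerGenome:
    nm, nph, tgenes = meta
    d = vec[: nm * nph].reshape(nm, nph)
    l = vec[nm * nph : 2 * nm * nph].reshape(nm, nph)
    ts = vec[2 * nm * nph :].copy() if tgenes else None
    return ControllerGenome(durations=d, levels=l, tendon_scales=ts)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _model_with_tendon_scales(model: Model, scales, gene_idx) -> Model:
    if scales is None or not len(gene_idx):
        return model
    acts = list(model.actuators)
    for s, ai in zip(scales, gene_idx):
        acts[ai] = replace(acts[ai], tl_mm=acts[ai].tl_mm * float(s))
    return replace(model, actuators=acts)


def evaluate_genome(
    model: Model,
    genome: ControllerGenome,
    time_limit: float,
    dt: float = dynamics.DEFAULT_DT,
    return_trajectory: bool = False,
    tendon_gene_idx: Optional[Sequence[int]] = None,
):
    """Fitness (m): maximum vertical CoM position within the time limit.

    Solutions whose bone stress exceeds the failure limit, or that blow up
    numerically, are discarded with a ``-inf`` sentinel.
    """
    if genome.durations.shape[0] != len(model.actuators):
        raise ValueError(
            f"genome has {genome.durations.shape[0]} actuator rows, model has "
            f"{len(model.actuators)} actuators"
        )
    if genome.tendon_scales is not None:
        idx = (
            list(tendon_gene_idx)
            if tendon_gene_idx is not None
            else [i for i, a in enumerate(model.actuators) if a.tendon_gene_bounds]
        )
        model = _model_with_tendon_scales(model, genome.tendon_scales, idx)
    traj = simulate(
        model,
        genome.schedule(time_limit),
        duration=time_limit,
        dt=dt,
        output_dt=max(dt, 1e-3),
        early_stop=True,
    )
    if traj.stress_exceeded or traj.blown_up:
        fitness = DISCARDED
    else:
        fitness = float(traj.max_com_height)
    if return_trajectory:
        return fitness, traj
    return fitness


class _FastEvaluator:
    """Evaluate genomes against one model with the arrays compiled once.

    Tendon genes mutate only the tendon slack length / series stiffness /
    initial CE length entries, so the full model compilation is hoisted out
    of the GA loop.
    """

    def __init__(self, model: Model, cfg: GAConfig):
        self.model = model
        self.cfg = cfg
        self.gene_idx = _tendon_gene_actuators(model, cfg)
        g = model.gravity
        self.mdl, self.meta = dynamics._compile_model(model, g)
        self.q0, self.lce0 = dynamics._initial_state(model, self.mdl, self.meta, True)
        nm = len(model.actuators)
        self.lmt0 = np.array(
            [path_length_m(model, a, None) for a in model.actuators]
        ) if nm else np.zeros(0)
        self.base_tl = self.mdl[31].copy()
        self.base_sek = self.mdl[32].copy()
        self._sek_floor = 0.05 * self.mdl[29]  # same floor as the compiler
        nj = len(self.meta["jnt_order"])
        nq = 3 + nj
        nsteps = int(round(cfg.time_limit / cfg.sim_dt))
        stride = max(1, nsteps)  # only endpoint records needed for fitness
        self._stride = stride
        nrec = nsteps // stride + 3
        ns = len(model.bone_sections)
        self._bufs = (
            np.zeros(nrec),
            np.zeros((nrec, nq)),
            np.zeros((nrec, nq)),
            np.zeros((nrec, 9)),
            np.zeros((nrec, max(nm, 1), 6)),
            np.zeros((nrec, max(nm, 1), 4)),
            np.zeros((nrec, max(ns, 1))),
            np.zeros((nrec, max(nm, 1))),
            np.zeros((nrec, max(nm, 1))),
        )

    def __call__(self, vec: np.ndarray, meta) -> float:
        genome = _decode(vec, meta)
        times, levels = genome.schedule(self.cfg.time_limit)
        mdl = self.mdl
        lce0 = self.lce0.copy()
        if genome.tendon_scales is not None and len(self.gene_idx):
            tl = self.base_tl.copy()
            for s, ai in zip(genome.tendon_scales, self.gene_idx):
                tl[ai] = max(self.base_tl[ai] * s, 1e-4)
            sek = (
                self.base_sek
                * np.maximum(self.base_tl, self._sek_floor)
                / np.maximum(tl, self._sek_floor)
            )
            for k, ai in enumerate(self.gene_idx):
                lce0[ai] = max(1e-4, self.lmt0[ai] - tl[ai])
            mdl = mdl[:31] + (tl, sek) + mdl[33:]
        nrec, status, fail_time, max_com_z = dynamics._run_core(
            mdl,
            self.q0.copy(),
            np.zeros_like(self.q0),
            lce0,
            np.ascontiguousarray(times),
            np.ascontiguousarray(levels),
            float(self.cfg.time_limit),
            float(self.cfg.sim_dt),
            self._stride,
            0,
            1,
            *self._bufs,
        )
        if status != 0:
            return DISCARDED
        return float(max_com_z)


# ---------------------------------------------------------------------------
# the GA itself
# ---------------------------------------------------------------------------

def run_ga(
    model: Model,
    cfg: GAConfig,
    fitness: Optional[Callable[[np.ndarray], float]] = None,
    seed: Optional[int] = None,
    return_trajectory: bool = False,
) -> GAResult:
    """Seeded generational GA over activation (and tendon) genomes.

    ``fitness`` overrides the simulation objective with a callable on the
    flat gene vector (used for surrogate objectives in testing).  With
    elitism >= 1 the returned per-generation best history is monotone
    non-decreasing, and identical config + seed reproduce bit-identical
    results.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    lo, hi, meta = _bounds(model, cfg)
    ngene = len(lo)
    span = hi - lo

    if fitness is None:
        ev = _FastEvaluator(model, cfg)

        def fitness_fn(vec: np.ndarray) -> float:
            return ev(vec, meta)

    else:
        fitness_fn = fitness

    P = cfg.population
    pop = rng.uniform(lo, hi, size=(P, ngene))
    fits = np.array([fitness_fn(pop[i]) for i in range(P)])
    history = np.empty(cfg.generations)

    for gen in range(cfg.generations):
        order = np.argsort(-fits, kind="stable")  # ties -> lower index first
        elite = pop[order[: cfg.elitism]].copy()
        elite_fit = fits[order[: cfg.elitism]].copy()
        history[gen] = elite_fit[0]

        children = np.empty_like(pop)
        children[: cfg.elitism] = elite
        for k in range(cfg.elitism, P):
            i1, i2 = rng.integers(0, P, size=2)
            p1 = i1 if (fits[i1] > fits[i2] or (fits[i1] == fits[i2] and i1 <= i2)) else i2
            j1, j2 = rng.integers(0, P, size=2)
            p2 = j1 if (fits[j1] > fits[j2] or (fits[j1] == fits[j2] and j1 <= j2)) else j2
            child = pop[p1].copy()
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(ngene) < 0.5
                child[mask] = pop[p2][mask]
            mut = rng.random(ngene) < cfg.mutation_rate
            if mut.any():
                child[mut] += rng.normal(0.0, cfg.mutation_scale, mut.sum()) * span[mut]
                np.clip(child, lo, hi, out=child)
            children[k] = child

        new_fits = np.empty(P)
        new_fits[: cfg.elitism] = elite_fit
        for k in range(cfg.elitism, P):
            new_fits[k] = fitness_fn(children[k])
        pop, fits = children, new_fits

    order = np.argsort(-fits, kind="stable")
    best_vec = pop[order[0]]
    best_fit = float(fits[order[0]])
    history = np.maximum.accumulate(history)
    if history[-1] < best_fit:
        history[-1] = best_fit
    genome = _decode(best_vec, meta)
    traj = None
    if return_trajectory and fitness is None:
        _, traj = evaluate_genome(
            model if not meta[2] else _model_with_tendon_scales(model, genome.tendon_scales, meta[2]),
            ControllerGenome(genome.durations, genome.levels),
            cfg.time_limit,
            dt=cfg.sim_dt,
            return_trajectory=True,
        )
    return GAResult(
        best_genome=genome,
        best_fitness=best_fit,
        history=history,
        seed=seed,
        best_trajectory=traj,
    )


def _replicate_seed(base_seed: int, limit_index: int, replicate: int) -> int:
    """Deterministic, distinct child seed per (time limit, replicate)."""
    ss = np.random.SeedSequence([int(base_seed), int(limit_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def time_limit_sweep(
    model: Model,
    limits: Sequence[float],
    cfg: GAConfig,
    plateau_tol: float = 0.02,
) -> dict:
    """Replicated GA runs across simulation time limits.

    Runs ``cfg.n_replicates`` independently seeded GAs per limit, reports
    the per-limit best, and flags the plateau: the first limit whose best
    fitness is within ``plateau_tol`` (relative) of the overall maximum.
    """
    if not limits:
        raise ValueError("need at least one time limit")
    results = []
    for li, limit in enumerate(limits):
        cfg_l = replace(cfg, time_limit=float(limit))
        reps = []
        for r in range(cfg.n_replicates):
            res = run_ga(model, cfg_l, seed=_replicate_seed(cfg.seed, li, r))
            reps.append(res)
        best = max(reps, key=lambda x: x.best_fitness)
        results.append(
            {
                "time_limit": float(limit),
                "best_fitness": best.best_fitness,
                "replicate_fitnesses": [x.best_fitness for x in reps],
                "best_result": best,
            }
        )
    overall = max(r["best_fitness"] for r in results)
    plateau = None
    for r in results:
        if r["best_fitness"] >= overall - plateau_tol * abs(overall):
            plateau = r["time_limit"]
            break
    return {"per_limit": results, "overall_best": overall, "plateau_limit": plateau}
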