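"""Feasible-ensemble generation: Latin hypercube screening and a modified
differential evolution whose selection step is gated by pluggable
feasibility criteria.

The three criteria are:

* FC1 — the trial vector's simulated phenotypes match every required
  phenotype of the training constraint (always enforced; judged on the
  32-bit-truncated copy of the vector);
* FC2 — swapping the trial in for its parent strictly increases the parent
  population's estimated (log) bounding-box volume;
* FC3 — the trial's prediction vector over the prediction panel has not
  been produced by any vector seen so far in this run.

Every FC1-passing trial is recorded into the result whether or not it is
accepted as a parent, mirroring how feasible ensembles are accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import qmc

from . import model_core
from .ensemble_metrics import predict_vector, volume_key
from .model_core import ModelSpec

__all__ = [
    "TrainingConstraint",
    "DEConfig",
    "DEResult",
    "check_fc1",
    "truncate32",
    "lhs_sample",
    "de_mutate",
    "de_crossover",
    "de_select",
    "run_de",
    "select_initial_population",
    "FC1",
    "FC2",
    "FC3",
]

FC1 = "FC1"
FC2 = "FC2"
FC3 = "FC3"


@dataclass(frozen=True)
class TrainingConstraint:
    """Strains with required phenotype codes (the must-capture set)."""

    strains: tuple  # tuple of (StrainSpec, required code)

    def __post_init__(self):
        if not self.strains:
            # an empty constraint is allowed and vacuously satisfied
            return
        for _, code in self.strains:
            if code not in (0, 1, 2):
                raise ValueError("required phenotypes must be in {0, 1, 2}")


@dataclass
class DEConfig:
    """Settings of one differential-evolution run."""

    population_size: int = 19
    scale_factor: float = 0.1  # F
    crossover_prob: float = 0.5  # C
    generations: int = 400  # t_max
    criteria: tuple = (FC1,)
    volume_axes: Optional[tuple] = None  # names or indices; None = all params
    seed: int = 0
    dt: float = model_core.DEFAULT_DT
    horizon: float = model_core.DEFAULT_HORIZON
    size_cap: float = model_core.DEFAULT_SIZE_CAP
    band: float = model_core.DEFAULT_BAND

    def __post_init__(self):
        if not (0 < self.scale_factor < 1):
            raise ValueError("scale factor F must satisfy 0 < F < 1")
        if not (0 <= self.crossover_prob <= 1):
            raise ValueError("crossover probability C must be in [0, 1]")
        if self.population_size < 4:
            raise ValueError("population size must be >= 4 "
                             "(mutation needs three distinct parents)")
        unknown = set(self.criteria) - {FC1, FC2, FC3}
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        if FC1 not in self.criteria:
            raise ValueError("FC1 is always enforced")


@dataclass
class DEResult:
    """Everything recorded across one DE run."""

    recorded: list = field(default_factory=list)  # all FC1-feasible vectors
    accept_log: list = field(default_factory=list)  # one entry per trial
    volume_trace: list = field(default_factory=list)  # per generation
    unique_predictions: set = field(default_factory=set)
    parents: Optional[np.ndarray] = None  # final parent population
    parent_history: Optional[list] = None
    n_trials: int = 0

    @property
    def n_feasible(self) -> int:
        return len(self.recorded)

    def recorded_matrix(self) -> np.ndarray:
        if not self.recorded:
            return np.empty((0, 0))
        return np.vstack(self.recorded)


def truncate32(pv: np.ndarray) -> np.ndarray:
    """Round each value to the nearest 32-bit IEEE single, returned as
    float64.  Idempotent; raises if a value overflows to infinity."""
    pv = np.asarray(pv, dtype=float)
    with np.errstate(over="ignore"):
        out = pv.astype(np.float32).astype(np.float64)
    if np.any(np.isinf(out) & np.isfinite(pv)):
        raise OverflowError("value overflows 32-bit single precision")
    return out


def check_fc1(pv: np.ndarray, model: ModelSpec,
              constraint: TrainingConstraint,
              dt: float = model_core.DEFAULT_DT,
              horizon: float = model_core.DEFAULT_HORIZON,
              size_cap: float = model_core.DEFAULT_SIZE_CAP,
              band: float = model_core.DEFAULT_BAND) -> bool:
    """True iff every constrained strain's phenotype matches its required
    code, evaluated on the 32-bit-truncated vector.  Short-circuits on the
    first miss."""
    from .model_core import (WILD_TYPE, classify_phenotype, simulate_strain)

    if not constraint.strains:
        return True
    tpv = truncate32(pv)
    wt_traj = simulate_strain(model, tpv, WILD_TYPE, dt=dt, horizon=horizon,
                              store_states=False)
    wt_seed = wt_traj.last_post_division_state
    for strain, required in constraint.strains:
        if strain.is_wild_type:
            code = classify_phenotype(wt_traj, size_cap, band).code
        elif wt_seed is None:
            code = model_core.INVIABLE
        else:
            traj = simulate_strain(model, tpv, strain, dt=dt, horizon=horizon,
                                   init=wt_seed, store_states=False)
            code = classify_phenotype(traj, size_cap, band).code
        if code != required:
            return False
    return True


def lhs_sample(bounds: Sequence, n: int, seed: int) -> np.ndarray:
    """Latin hypercube sample: one point per stratum along every axis.

    ``bounds`` is a sequence of (min, max) pairs; degenerate axes are
    allowed.  Returns an (n, D) array, deterministic in ``seed``.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo > hi):
        raise ValueError("lower bound exceeds upper bound")
    sampler = qmc.LatinHypercube(d=len(bounds), rng=np.random.default_rng(seed))
    unit = sampler.random(n=n)
    return lo + unit * (hi - lo)


def de_mutate(population: np.ndarray, i: int, F: float,
              rng: np.random.Generator,
              donors: Optional[tuple] = None) -> np.ndarray:
    """Mutant v = x_i + F * (x_i' - x_i'') with i', i'' distinct from each
    other and from i.  ``donors`` is a test hook forcing (i', i'')."""
    population = np.asarray(population, dtype=float)
    N = population.shape[0]
    if N < 3:
        raise ValueError("population must have at least three members")
    if donors is None:
        others = [k for k in range(N) if k != i]
        ip, ipp = rng.choice(others, size=2, replace=False)
    else:
        ip, ipp = donors
    return population[i] + F * (population[ip] - population[ipp])


def de_crossover(parent: np.ndarray, mutant: np.ndarray, C: float,
                 rng: np.random.Generator,
                 draws: Optional[np.ndarray] = None) -> np.ndarray:
    """Coordinate j takes the mutant value when U_j <= C, else the parent
    value.  ``draws`` is a test hook injecting the uniform variates."""
    parent = np.asarray(parent, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if parent.shape != mutant.shape:
        raise ValueError("parent and mutant must have the same length")
    u = rng.uniform(size=parent.shape) if draws is None else np.asarray(draws)
    return np.where(u <= C, mutant, parent)


class _RunState:
    """Mutable book-keeping carried through one DE run."""

    def __init__(self, model: ModelSpec, constraint: TrainingConstraint,
                 cfg: DEConfig, parents: np.ndarray,
                 prediction_strains: Sequence):
        self.model = model
        self.constraint = constraint
        self.cfg = cfg
        self.parents = np.asarray(parents, dtype=float)
        self.prediction_strains = tuple(prediction_strains or ())
        self.axes_idx = _axes_indices(model, cfg.volume_axes)
        self.unique_predictions: set = set()

    def fc1(self, pv) -> bool:
        return check_fc1(pv, self.model, self.constraint,
                         dt=self.cfg.dt, horizon=self.cfg.horizon,
                         size_cap=self.cfg.size_cap, band=self.cfg.band)

    def predict(self, pv) -> tuple:
        return predict_vector(truncate32(pv), self.model,
                              self.prediction_strains,
                              dt=self.cfg.dt, horizon=self.cfg.horizon,
                              size_cap=self.cfg.size_cap, band=self.cfg.band)

    def volume(self, matrix) -> tuple:
        return volume_key(matrix, self.axes_idx)


def _axes_indices(model: ModelSpec, axes) -> np.ndarray:
    if axes is None:
        return np.arange(model.n_params)
    idx = []
    for a in axes:
        idx.append(model.param_index(a) if isinstance(a, str) else int(a))
    return np.asarray(idx, dtype=int)


def de_select(parent_index: int, trial: np.ndarray, state: _RunState):
    """Apply the active criteria to one trial.

    Returns ``(accepted, recorded, prediction)`` where ``recorded`` is True
    for any FC1-passing trial and ``prediction`` is the trial's prediction
    vector when it was computed (FC3 active), else None.
    """
    cfg = state.cfg
    if not state.fc1(trial):
        return False, False, None
    accepted = True
    if FC2 in cfg.criteria:
        swapped = state.parents.copy()
        swapped[parent_index] = trial
        accepted = state.volume(swapped) > state.volume(state.parents)
    prediction = None
    if accepted and FC3 in cfg.criteria:
        prediction = state.predict(trial)
        accepted = prediction not in state.unique_predictions
    return accepted, True, prediction


def run_de(model: ModelSpec, constraint: TrainingConstraint,
           initial_population: np.ndarray, cfg: DEConfig,
           prediction_strains: Sequence = (),
           keep_history: bool = False,
           check_initial: bool = True) -> DEResult:
    """Run mutation/crossover/selection for ``cfg.generations`` generations.

    Every stochastic draw comes from a single generator seeded with
    ``cfg.seed`` and is consumed in a fixed order (per parent: two donor
    indices, then D crossover variates), so runs replay exactly.
    """
    parents = np.array(initial_population, dtype=float)
    if parents.ndim != 2 or parents.shape[0] != cfg.population_size:
        raise ValueError(
            f"initial population must be ({cfg.population_size}, D)")
    state = _RunState(model, constraint, cfg, parents, prediction_strains)
    if check_initial:
        for k, pv in enumerate(parents):
            if not state.fc1(pv):
                raise ValueError(f"initial population member {k} is not "
                                 "FC1-feasible")
    result = DEResult(parent_history=[] if keep_history else None)
    result.recorded.extend(truncate32(pv) for pv in parents)
    if FC3 in cfg.criteria:
        for pv in parents:
            state.unique_predictions.add(state.predict(pv))
        result.unique_predictions = state.unique_predictions

    rng = np.random.default_rng(cfg.seed)
    result.volume_trace.append(state.volume(state.parents))
    for t in range(cfg.generations):
        for i in range(cfg.population_size):
            mutant = de_mutate(state.parents, i, cfg.scale_factor, rng)
            trial = de_crossover(state.parents[i], mutant,
                                 cfg.crossover_prob, rng)
            accepted, recorded, prediction = de_select(i, trial, state)
            result.n_trials += 1
            if recorded:
                result.recorded.append(truncate32(trial))
            if accepted:
                state.parents[i] = trial
                if prediction is not None:
                    state.unique_predictions.add(prediction)
            result.accept_log.append({
                "generation": t,
                "parent": i,
                "recorded": recorded,
                "accepted": accepted,
                "volume": state.volume(state.parents)[1],
            })
        result.volume_trace.append(state.volume(state.parents))
        if keep_history:
            result.parent_history.append(state.parents.copy())
    result.parents = state.parents
    result.unique_predictions = state.unique_predictions
    return result


def select_initial_population(ensemble: np.ndarray, N: int, mode: str,
                              model: Optional[ModelSpec] = None,
                              prediction_strains: Sequence = (),
                              seed: int = 0,
                              volume_axes=None,
                              predictions: Optional[Sequence] = None,
                              dt: float = model_core.DEFAULT_DT,
                              horizon: float = model_core.DEFAULT_HORIZON,
                              size_cap: float = model_core.DEFAULT_SIZE_CAP,
                              band: float = model_core.DEFAULT_BAND) -> np.ndarray:
    """Pick N vectors from a feasible ensemble to start DE.

    Modes:

    * ``"random"`` — uniform subset without replacement;
    * ``"vmax"`` — greedy maximisation of the estimated log volume over the
      given axes (seeded with per-axis extreme vectors, grown greedily,
      then improved by single-swap hill climbing);
    * ``"smax+vmax"`` — at most one representative per unique prediction
      vector first (volume-greedy within that constraint), any shortfall
      filled volume-greedily.

    ``predictions`` may supply precomputed prediction vectors (one tuple
    per ensemble row) to avoid re-simulation in smax+vmax mode.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    m = ensemble.shape[0]
    if N > m:
        raise ValueError(f"cannot select {N} vectors from an ensemble of {m}")
    rng = np.random.default_rng(seed)
    mode = mode.lower()
    if mode == "random":
        idx = rng.choice(m, size=N, replace=False)
        return ensemble[np.sort(idx)]

    if model is not None:
        axes_idx = _axes_indices(model, volume_axes)
    elif volume_axes is None:
        axes_idx = np.arange(ensemble.shape[1])
    else:
        axes_idx = np.asarray([int(a) for a in volume_axes], dtype=int)

    if mode == "vmax":
        chosen = _greedy_vmax(ensemble, N, axes_idx)
        return ensemble[chosen]

    if mode in ("smax+vmax", "smax&vmax"):
        if predictions is None:
            if model is None:
                raise ValueError("smax+vmax needs a model or precomputed "
                                 "predictions")
            predictions = [predict_vector(truncate32(pv), model,
                                          prediction_strains, dt=dt,
                                          horizon=horizon, size_cap=size_cap,
                                          band=band)
                           for pv in ensemble]
        return ensemble[_smax_vmax(ensemble, N, axes_idx, list(predictions))]

    raise ValueError(f"unknown selection mode {mode!r}")


def _greedy_vmax(values: np.ndarray, N: int, axes_idx: np.ndarray,
                 candidates: Optional[Sequence[int]] = None,
                 start: Optional[list] = None) -> list:
    m = values.shape[0]
    pool = list(range(m)) if candidates is None else list(candidates)
    chosen: list = list(start or [])

    # seed with the vectors attaining each axis extreme (deduplicated),
    # largest-range axes first, until N slots are filled
    if not chosen:
        order = np.argsort(-(values[np.ix_(pool, axes_idx)].max(axis=0)
                             - values[np.ix_(pool, axes_idx)].min(axis=0)))
        for a in order:
            col = values[pool, axes_idx[a]]
            for pick in (pool[int(np.argmin(col))], pool[int(np.argmax(col))]):
                if pick not in chosen and len(chosen) < N:
                    chosen.append(pick)
            if len(chosen) >= N:
                break

    # grow greedily
    while len(chosen) < N:
        best, best_key = None, None
        for c in pool:
            if c in chosen:
                continue
            key = volume_key(values[chosen + [c]], axes_idx)
            if best_key is None or key > best_key:
                best, best_key = c, key
        if best is None:
            break
        chosen.append(best)

    # single-swap improvement passes (bounded)
    locked = set(start or [])
    for _ in range(3):
        improved = False
        current = volume_key(values[chosen], axes_idx)
        for pos in range(len(chosen)):
            if chosen[pos] in locked:
                continue
            for c in pool:
                if c in chosen:
                    continue
                trial = list(chosen)
                trial[pos] = c
                key = volume_key(values[trial], axes_idx)
                if key > current:
                    chosen = trial
                    current = key
                    improved = True
        if not improved:
            break
    return chosen


def _smax_vmax(values: np.ndarray, N: int, axes_idx: np.ndarray,
               predictions: list) -> list:
    buckets: dict = {}
    for row, pred in enumerate(predictions):
        buckets.setdefault(pred, []).append(row)
    # distinct prediction vectors first, larger buckets first for stability
    ordered = sorted(buckets.values(), key=lambda b: (-len(b), b[0]))
    chosen: list = []
    for bucket in ordered[:N]:
        best, best_key = bucket[0], None
        for c in bucket:
            key = volume_key(values[chosen + [c]], axes_idx)
            if best_key is None or key > best_key:
                best, best_key = c, key
        chosen.append(best)
    if len(chosen) < N:
        chosen = _greedy_vmax(values, N, axes_idx, start=chosen)
    return chosen
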