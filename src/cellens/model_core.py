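"""Simulation core for growth-division dynamical models.

A model is a deterministic ODE system over named species, one of which is a
distinguished cell-size variable ``V``.  Fixed-step explicit Euler integration
is used throughout (no adaptive stepping).  Division events are detected by a
trigger predicate evaluated on consecutive grid states; when the trigger
fires, a division map is applied to the state before the next Euler step so
that the simulation follows a single daughter cell whose size is a fixed
fraction ``f`` of the size at division.

A parameter vector bundles the kinetic parameters *and* the initial
conditions of the species, in that order, so its length is
``D = n_params + n_species``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "StrainSpec",
    "Trajectory",
    "Phenotype",
    "VIABLE",
    "INVIABLE",
    "MULTIPLY_PERIODIC",
    "DEFAULT_DT",
    "DEFAULT_HORIZON",
    "DEFAULT_SIZE_CAP",
    "DEFAULT_BAND",
    "simulate_strain",
    "wt_final_state",
    "classify_phenotype",
    "time_average_abundances",
]

#: Phenotype codes.
MULTIPLY_PERIODIC = 0
VIABLE = 1
INVIABLE = 2

DEFAULT_DT = 0.05
DEFAULT_HORIZON = 2000.0
DEFAULT_SIZE_CAP = 25.0
DEFAULT_BAND = 0.05


class AcyclicWildTypeError(RuntimeError):
    """Raised when a wild-type trajectory has no division to seed mutants."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a growth-division model.

    Parameters
    ----------
    name
        Identifier of the model.
    species
        Ordered unique species names; must contain `size_var`.
    params
        Ordered unique kinetic-parameter names.
    deriv
        Pure function ``deriv(state, params) -> dstate`` returning the time
        derivative of every species (sequences of floats, same order as
        `species`).
    trigger
        Predicate ``trigger(prev_state, new_state, params) -> bool`` that is
        True exactly when a division occurs on the step from ``prev_state``
        to ``new_state``.
    divide
        Division map ``divide(state, params) -> state`` applied right after
        the trigger fires; must strictly reduce the size variable.
    size_var
        Name of the cell-size species.
    modules
        Optional annotation hook mapping species to network-module labels.
    fast_integrator
        Optional drop-in replacement for the generic Euler loop with the
        same observable behaviour (used by synthetic fixtures for speed);
        signature ``(params, init, dt, n_steps, store_states) -> dict``.
    """

    name: str
    species: tuple
    params: tuple
    deriv: Callable
    trigger: Callable
    divide: Callable
    size_var: str = "V"
    modules: Mapping[str, str] = field(default_factory=dict)
    fast_integrator: Optional[Callable] = None

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        if len(set(self.params)) != len(self.params):
            raise ValueError("duplicate parameter names")
        if self.size_var not in self.species:
            raise ValueError(f"size variable {self.size_var!r} not a species")
        if set(self.species) & set(self.params):
            raise ValueError("species and parameter names overlap")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def dimension(self) -> int:
        """Length D of a parameter vector (kinetic parameters + initial conditions)."""
        return self.n_params + self.n_species

    @property
    def size_index(self) -> int:
        return self.species.index(self.size_var)

    def param_index(self, name: str) -> int:
        return self.params.index(name)

    def split(self, pv: np.ndarray):
        """Split a parameter vector into (kinetic params, initial conditions)."""
        pv = np.asarray(pv, dtype=float)
        if pv.shape != (self.dimension,):
            raise ValueError(
                f"parameter vector has length {pv.shape}, expected ({self.dimension},)"
            )
        return pv[: self.n_params], pv[self.n_params :]


@dataclass(frozen=True)
class StrainSpec:
    """A mutant strain: a set of parameter overrides applied to a background."""

    id: int
    label: str
    overrides: tuple = ()  # tuple of (parameter name, replacement value)

    @property
    def is_wild_type(self) -> bool:
        return len(self.overrides) == 0

    def apply(self, model: ModelSpec, pv: np.ndarray) -> np.ndarray:
        out = np.array(pv, dtype=float, copy=True)
        for name, value in self.overrides:
            out[model.param_index(name)] = value
        return out


WILD_TYPE = StrainSpec(id=0, label="WT", overrides=())


@dataclass
class Trajectory:
    """Result of one fixed-step Euler simulation of a single strain."""

    species: tuple
    dt: float
    n_steps: int
    division_times: np.ndarray
    division_sizes: np.ndarray
    max_size: float
    state_sums: np.ndarray  # per-species sum over all grid points
    n_points: int
    final_state: np.ndarray
    last_post_division_state: Optional[np.ndarray]
    blew_up: bool
    states: Optional[np.ndarray] = None  # (n_points, n_species) when stored

    @property
    def n_divisions(self) -> int:
        return len(self.division_times)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dt

    def to_frame(self):
        """Export the stored states as a delimited-table-ready data frame."""
        import pandas as pd

        if self.states is None:
            raise ValueError("trajectory was simulated without state storage")
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class Phenotype:
    """Discrete phenotype: 0 multiply periodic, 1 viable, 2 inviable."""

    code: int
    reason: str

    def __int__(self) -> int:
        return self.code


def _generic_euler(model: ModelSpec, params, init, dt: float, n_steps: int,
                   store_states: bool) -> dict:
    """Reference Euler loop; pure Python, works for any ModelSpec."""
    deriv = model.deriv
    trigger = model.trigger
    divide = model.divide
    size_i = model.size_index
    n_sp = model.n_species

    state = [float(v) for v in init]
    sums = [0.0] * n_sp
    for k in range(n_sp):
        sums[k] += state[k]
    max_size = state[size_i]
    div_times: list = []
    div_sizes: list = []
    post_div = None
    blew_up = False
    n_points = 1
    states = [tuple(state)] if store_states else None

    for step in range(n_steps):
        d = deriv(state, params)
        new = [state[k] + dt * d[k] for k in range(n_sp)]
        ok = True
        for v in new:
            if not math.isfinite(v):
                ok = False
                break
        if not ok:
            blew_up = True
            break
        size_here = new[size_i]
        if size_here > max_size:
            max_size = size_here
        if trigger(state, new, params):
            div_times.append((step + 1) * dt)
            div_sizes.append(size_here)
            new = list(divide(new, params))
            post_div = tuple(new)
        state = new
        n_points += 1
        for k in range(n_sp):
            sums[k] += state[k]
        if store_states:
            states.append(tuple(state))

    return {
        "division_times": np.asarray(div_times, dtype=float),
        "division_sizes": np.asarray(div_sizes, dtype=float),
        "max_size": max_size,
        "state_sums": np.asarray(sums, dtype=float),
        "n_points": n_points,
        "final_state": np.asarray(state, dtype=float),
        "last_post_division_state": (None if post_div is None
                                     else np.asarray(post_div, dtype=float)),
        "blew_up": blew_up,
        "states": states,
    }


def simulate_strain(model: ModelSpec, pv: np.ndarray,
                    strain: StrainSpec = WILD_TYPE,
                    dt: float = DEFAULT_DT,
                    horizon: float = DEFAULT_HORIZON,
                    init: Optional[Sequence[float]] = None,
                    store_states: bool = True) -> Trajectory:
    """Simulate one strain with fixed-step explicit Euler.

    Strain overrides are applied to ``pv`` before integration.  When ``init``
    is None the initial conditions stored in the parameter vector are used
    (the wild-type convention); mutants are typically seeded with
    :func:`wt_final_state` instead.

    Non-finite states abort the integration; the trajectory is returned up to
    the failure point with ``blew_up`` set, and downstream classification
    treats the size as exceeding any viability cap.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    params_full = strain.apply(model, pv)
    params, pv_init = model.split(params_full)
    if init is None:
        init = pv_init
    init = np.asarray(init, dtype=float)
    if init.shape != (model.n_species,):
        raise ValueError("initial state has wrong length")
    n_steps = int(round(horizon / dt))

    integ = model.fast_integrator or (
        lambda p, s0, h, n, store: _generic_euler(model, p, s0, h, n, store))
    # overflow on the way to a detected blow-up is expected, not an error
    with np.errstate(over="ignore", invalid="ignore"):
        raw = integ(params, init, dt, n_steps, store_states)

    states = raw.get("states") if store_states else None
    if states is not None:
        states = np.asarray(states, dtype=float)

    return Trajectory(
        species=model.species,
        dt=dt,
        n_steps=n_steps,
        division_times=raw["division_times"],
        division_sizes=raw["division_sizes"],
        max_size=float(raw["max_size"]),
        state_sums=raw["state_sums"],
        n_points=int(raw["n_points"]),
        final_state=raw["final_state"],
        last_post_division_state=raw["last_post_division_state"],
        blew_up=bool(raw["blew_up"]),
        states=states,
    )


def wt_final_state(model: ModelSpec, pv: np.ndarray,
                   dt: float = DEFAULT_DT,
                   horizon: float = DEFAULT_HORIZON) -> np.ndarray:
    """State right after the last division of the wild-type simulation.

    This state seeds the initial conditions of every mutant simulation.
    """
    traj = simulate_strain(model, pv, WILD_TYPE, dt=dt, horizon=horizon,
                           store_states=False)
    return wt_final_state_from(traj)


def wt_final_state_from(traj: Trajectory) -> np.ndarray:
    if traj.last_post_division_state is None:
        raise AcyclicWildTypeError("WT acyclic; cannot seed mutants")
    return traj.last_post_division_state


def classify_phenotype(traj: Trajectory,
                       size_cap: float = DEFAULT_SIZE_CAP,
                       band: float = DEFAULT_BAND) -> Phenotype:
    """Classify a trajectory into phenotype codes {0, 1, 2}.

    Rules, in precedence order:

    * size exceeds ``size_cap`` at any grid point (or numerical blow-up)
      -> inviable (2);
    * at least three divisions with the last division size within ``band``
      (relative to the last size) of *both* previous division sizes
      -> viable (1);
    * at least three divisions otherwise -> multiply periodic (0);
    * fewer than three divisions -> inviable (2), reason ``"arrest"``.
    """
    if traj.blew_up:
        return Phenotype(INVIABLE, "numerical blow-up")
    if traj.max_size > size_cap:
        return Phenotype(INVIABLE, f"size cap exceeded ({traj.max_size:.4g} > {size_cap:g})")
    sizes = traj.division_sizes
    if len(sizes) >= 3:
        s_last, s_prev1, s_prev2 = sizes[-1], sizes[-2], sizes[-3]
        if s_last > 0 and (abs(s_last - s_prev1) / s_last <= band
                           and abs(s_last - s_prev2) / s_last <= band):
            return Phenotype(VIABLE, "balanced divisions")
        return Phenotype(MULTIPLY_PERIODIC, "division sizes oscillate beyond band")
    return Phenotype(INVIABLE, "arrest")


def time_average_abundances(traj: Trajectory) -> dict:
    """Arithmetic mean of each species over all grid points of the horizon."""
    if traj.n_points < 1:
        raise ValueError("empty trajectory")
    means = traj.state_sums / traj.n_points
    return {name: float(means[i]) for i, name in enumerate(traj.species)}
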