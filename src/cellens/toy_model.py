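"""Synthetic growth-division fixture with a known feasible structure.

The toy network is a size-gated relaxation oscillator spanning three modules:

* START: an activator chain sensing cell size (``A1 .. An``), with a
  redundant basal synthesis input into ``A1``;
* S/G2/M: a relay chain (``B1 .. Bm``) driven by the last START species;
* EXIT: an inhibitor chain ending in a "divider" species ``E`` that starts
  high and is repressed by the last S/G2/M species.

Cell size ``V`` grows exponentially.  As ``V`` rises the cascade pushes the
divider down; when the divider crosses its threshold downward the cell
divides and the followed daughter retains a fraction ``f`` of the size.
Knockouts of chain synthesis rates produce arrest, size blow-up, or
unbalanced division patterns, so all three phenotype codes are reachable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .model_core import (
    ModelSpec,
    StrainSpec,
    WILD_TYPE,
    VIABLE,
    INVIABLE,
    simulate_strain,
    classify_phenotype,
)

__all__ = [
    "ToyConfig",
    "StrainPanel",
    "make_toy_model",
    "make_strain_panel",
    "make_reference_ensemble",
    "make_module_structured_features",
    "default_training_constraint",
    "DEFAULT_ELIMINABLE_RATES",
]

MODULE_START = "START"
MODULE_SG2M = "S/G2/M"
MODULE_EXIT = "EXIT"


@dataclass
class ToyConfig:
    """Configuration of the synthetic fixture.

    The screening step/horizon are deliberately coarser than the production
    defaults of :func:`cellens.model_core.simulate_strain`; the reference
    vector is calibrated to cycle under both settings.
    """

    n_start: int = 1
    n_sg2m: int = 1
    n_exit: int = 1
    growth_rate: float = 0.03
    division_threshold: float = 0.3
    daughter_fraction: float = 0.45
    basal_start_input: float = 0.02
    size_coupling: float = 0.1
    chain_synthesis: float = 0.2
    chain_degradation: float = 0.2
    divider_recovery: float = 0.1
    divider_inhibition: float = 0.4
    divider_total: float = 1.0
    dt: float = 0.1
    horizon: float = 240.0
    size_cap: float = 25.0
    band: float = 0.05
    seed: int = 0

    def validate(self):
        if min(self.n_start, self.n_sg2m, self.n_exit) < 1:
            raise ValueError("each module needs at least one species")
        if not (0 < self.daughter_fraction < 1):
            raise ValueError("daughter fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ToyConfig":
        return cls(**d)


@dataclass
class StrainPanel:
    """Training strains (with required phenotypes) plus prediction strains."""

    training: tuple  # tuple of (StrainSpec, required phenotype code)
    prediction: tuple  # tuple of StrainSpec
    eliminable_rates: tuple

    @property
    def prediction_ids(self) -> tuple:
        return tuple(s.id for s in self.prediction)


def _species_names(cfg: ToyConfig):
    start = [f"A{i+1}" for i in range(cfg.n_start)]
    sg2m = [f"B{i+1}" for i in range(cfg.n_sg2m)]
    exit_ = [f"E{i+1}" for i in range(cfg.n_exit)]
    return start, sg2m, exit_


def make_toy_model(cfg: Optional[ToyConfig] = None):
    """Build the toy ModelSpec and its reference parameter vector.

    Deterministic in ``cfg``; raises if the reference vector does not
    produce a viable wild type under the screening settings.
    """
    if cfg is None:
        cfg = ToyConfig()
    cfg.validate()
    start, sg2m, exit_, = _species_names(cfg)
    chain = start + sg2m + exit_
    species = tuple(["V"] + chain)
    modules = {"V": "--"}
    modules.update({s: MODULE_START for s in start})
    modules.update({s: MODULE_SG2M for s in sg2m})
    modules.update({s: MODULE_EXIT for s in exit_})

    # kinetic parameters: growth + basal input + per chain species (ks, kd)
    # + divider kinetics + threshold; the daughter fraction f stays fixed in
    # the division map (not an optimisable parameter).
    params = ["mu", "ks0_A1"]
    for s in chain[:-1]:
        params += [f"ks_{s}", f"kd_{s}"]
    divider = chain[-1]
    params += ["ks_E", "ki_E", "Etot", "theta"]
    params = tuple(params)

    n_chain = len(chain)
    n_relay = n_chain - 1  # species with ks/kd pairs (all but the divider)
    i_mu = 0
    i_basal = 1
    # index bookkeeping for the deriv closure
    ks_idx = [2 + 2 * k for k in range(n_relay)]
    kd_idx = [3 + 2 * k for k in range(n_relay)]
    i_kse = 2 + 2 * n_relay
    i_kie = i_kse + 1
    i_etot = i_kse + 2
    i_theta = i_kse + 3
    div_state_i = n_chain  # divider position within state (after V at 0)
    f = cfg.daughter_fraction

    def deriv(state, p):
        v = state[0]
        d = [p[i_mu] * v]
        # first chain species senses size plus a redundant basal input
        prev = v
        d.append(p[i_basal] + p[ks_idx[0]] * prev - p[kd_idx[0]] * state[1])
        for k in range(1, n_relay):
            d.append(p[ks_idx[k]] * state[k] - p[kd_idx[k]] * state[k + 1])
        # divider: recovers toward Etot, repressed by the last relay species
        e = state[div_state_i]
        b_last = state[div_state_i - 1]
        d.append(p[i_kse] * (p[i_etot] - e) - p[i_kie] * b_last * e)
        return d

    def trigger(prev_state, new_state, p):
        th = p[i_theta]
        return prev_state[div_state_i] >= th > new_state[div_state_i]

    def divide(state, p):
        out = list(state)
        out[0] = f * out[0]
        return out

    fast = _build_fast_integrator(n_chain, n_relay, ks_idx, kd_idx,
                                  i_mu, i_basal, i_kse, i_kie, i_etot,
                                  i_theta, div_state_i, f)

    model = ModelSpec(
        name="toy3mod",
        species=species,
        params=params,
        deriv=deriv,
        trigger=trigger,
        divide=divide,
        size_var="V",
        modules=modules,
        fast_integrator=fast,
    )

    reference = _reference_vector(model, cfg)

    traj = simulate_strain(model, reference, WILD_TYPE, dt=cfg.dt,
                           horizon=cfg.horizon, store_states=False)
    ph = classify_phenotype(traj, size_cap=cfg.size_cap, band=cfg.band)
    if ph.code != VIABLE or traj.n_divisions < 3:
        raise ValueError(
            f"reference vector not viable (code {ph.code}: {ph.reason}, "
            f"{traj.n_divisions} divisions)")
    return model, reference


def _reference_vector(model: ModelSpec, cfg: ToyConfig) -> np.ndarray:
    values = {}
    values["mu"] = cfg.growth_rate
    values["ks0_A1"] = cfg.basal_start_input
    start, sg2m, exit_ = _species_names(cfg)
    chain = start + sg2m + exit_
    for j, s in enumerate(chain[:-1]):
        values[f"ks_{s}"] = cfg.size_coupling if j == 0 else cfg.chain_synthesis
        values[f"kd_{s}"] = cfg.chain_degradation
    values["ks_E"] = cfg.divider_recovery
    values["ki_E"] = cfg.divider_inhibition
    values["Etot"] = cfg.divider_total
    values["theta"] = cfg.division_threshold
    params = np.array([values[p] for p in model.params], dtype=float)
    # initial conditions: mid-cycle state
    init = {"V": 0.6}
    for s in chain[:-1]:
        init[s] = 0.4
    init[chain[-1]] = 0.5
    ics = np.array([init[s] for s in model.species], dtype=float)
    return np.concatenate([params, ics])


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speed-up
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco


@_njit(cache=True)
def _toy_euler_kernel(p, init, dt, n_steps, store_states,
                      ks_idx, kd_idx, i_mu, i_basal, i_kse, i_kie,
                      i_etot, i_theta, div_i, f):  # pragma: no cover - jit
    n_relay = len(ks_idx)
    n_sp = len(init)
    mu = p[i_mu]
    basal = p[i_basal]
    kse = p[i_kse]
    kie = p[i_kie]
    etot = p[i_etot]
    theta = p[i_theta]

    state = init.copy()
    new = init.copy()
    sums = init.copy()
    max_size = state[0]
    div_times = np.empty(n_steps + 1, dtype=np.float64)
    div_sizes = np.empty(n_steps + 1, dtype=np.float64)
    n_div = 0
    post_div = np.zeros(n_sp, dtype=np.float64)
    has_post_div = False
    blew_up = False
    n_points = 1
    if store_states:
        states = np.empty((n_steps + 1, n_sp), dtype=np.float64)
        states[0] = state
    else:
        states = np.empty((1, n_sp), dtype=np.float64)

    for step in range(n_steps):
        v = state[0]
        new[0] = v + dt * (mu * v)
        new[1] = state[1] + dt * (basal + p[ks_idx[0]] * v
                                  - p[kd_idx[0]] * state[1])
        for k in range(1, n_relay):
            new[k + 1] = state[k + 1] + dt * (p[ks_idx[k]] * state[k]
                                              - p[kd_idx[k]] * state[k + 1])
        e = state[div_i]
        b_last = state[div_i - 1]
        new[div_i] = e + dt * (kse * (etot - e) - kie * b_last * e)

        ok = True
        for k in range(n_sp):
            if not np.isfinite(new[k]):
                ok = False
                break
        if not ok:
            blew_up = True
            break
        size_here = new[0]
        if size_here > max_size:
            max_size = size_here
        if e >= theta > new[div_i]:
            div_times[n_div] = (step + 1) * dt
            div_sizes[n_div] = size_here
            n_div += 1
            new[0] = f * new[0]
            post_div[:] = new
            has_post_div = True
        for k in range(n_sp):
            state[k] = new[k]
            sums[k] += new[k]
        n_points += 1
        if store_states:
            states[n_points - 1] = state

    return (div_times[:n_div].copy(), div_sizes[:n_div].copy(), max_size,
            sums, n_points, state, post_div, has_post_div, blew_up,
            states[:n_points].copy() if store_states else states)


def _build_fast_integrator(n_chain, n_relay, ks_idx, kd_idx, i_mu, i_basal,
                           i_kse, i_kie, i_etot, i_theta, div_i, f):
    """Compiled Euler loop for the toy network; same arithmetic and event
    handling as the generic loop in model_core, just without per-step
    callable dispatch."""
    ks_idx = np.asarray(ks_idx, dtype=np.int64)
    kd_idx = np.asarray(kd_idx, dtype=np.int64)

    def integrate(p, init, dt, n_steps, store_states):
        p = np.ascontiguousarray(p, dtype=np.float64)
        init = np.ascontiguousarray(init, dtype=np.float64)
        (div_times, div_sizes, max_size, sums, n_points, state, post_div,
         has_post_div, blew_up, states) = _toy_euler_kernel(
            p, init, float(dt), int(n_steps), bool(store_states),
            ks_idx, kd_idx, i_mu, i_basal, i_kse, i_kie, i_etot, i_theta,
            div_i, f)
        return {
            "division_times": div_times,
            "division_sizes": div_sizes,
            "max_size": float(max_size),
            "state_sums": sums,
            "n_points": int(n_points),
            "final_state": state,
            "last_post_division_state": post_div if has_post_div else None,
            "blew_up": bool(blew_up),
            "states": states if store_states else None,
        }

    return integrate


#: Rates whose one-by-one elimination defines the default prediction panel.
DEFAULT_ELIMINABLE_RATES = (
    "ks0_A1", "ks_A1", "kd_A1", "ks_B1", "kd_B1", "ks_E", "ki_E", "Etot", "mu",
)


def make_strain_panel(eliminable_rates: Sequence[str],
                      max_order: int = 3) -> StrainPanel:
    """All single, pair, and triple eliminations of the given rates.

    Prediction strains are every combination of the eliminable rates up to
    ``max_order``, each override setting the chosen rates to zero.  Strain
    ids are dense from 1; the wild type is excluded.
    """
    rates = list(eliminable_rates)
    if len(set(rates)) != len(rates):
        raise ValueError("duplicate rate names")
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2, or 3")
    strains = []
    next_id = 1
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(rates, order):
            strains.append(StrainSpec(
                id=next_id,
                label="+".join(f"{r}=0" for r in combo),
                overrides=tuple((r, 0.0) for r in combo),
            ))
            next_id += 1
    return StrainPanel(training=(), prediction=tuple(strains),
                       eliminable_rates=tuple(rates))


def default_training_constraint(model: ModelSpec):
    """The toy Training Set: strain/required-phenotype pairs used by FC1.

    The wild type must cycle; the basal START input is dispensable; the
    size-coupling input and the growth rate are essential.
    """
    from .explore import TrainingConstraint

    strains = [
        (WILD_TYPE, VIABLE),
        (StrainSpec(id=-1, label="ks0_A1=0", overrides=(("ks0_A1", 0.0),)), VIABLE),
        (StrainSpec(id=-2, label="ks_A1=0", overrides=(("ks_A1", 0.0),)), INVIABLE),
        (StrainSpec(id=-3, label="mu=0", overrides=(("mu", 0.0),)), INVIABLE),
        (StrainSpec(id=-4, label="ki_E=0", overrides=(("ki_E", 0.0),)), INVIABLE),
    ]
    return TrainingConstraint(strains=tuple(strains))


def make_reference_ensemble(model: ModelSpec, reference: np.ndarray,
                            n: int, jitter: float, seed: int,
                            constraint=None,
                            dt: Optional[float] = None,
                            horizon: Optional[float] = None,
                            size_cap: float = 25.0, band: float = 0.05,
                            outlier_fraction: float = 0.15,
                            outlier_scale: float = 3.0,
                            max_tries: int = 200000) -> np.ndarray:
    """Log-normal jitter around the reference, screened to FC1-feasible.

    The jitter is a two-component mixture: most candidates use sigma =
    ``jitter`` while a fraction ``outlier_fraction`` uses sigma =
    ``outlier_scale * jitter``.  The screened ensemble is therefore
    concentrated around the reference with a heavy tail of feasible
    outliers, which is the structure that makes biased initial-population
    selection for DE worthwhile.

    Returns an ``(n, D)`` array (fewer rows only if the retry budget runs
    out with at least one feasible vector found); deterministic in ``seed``.
    """
    from .explore import check_fc1

    if n < 2:
        raise ValueError("n must be at least 2")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if constraint is None:
        constraint = default_training_constraint(model)
    if dt is None:
        dt = 0.1
    if horizon is None:
        horizon = 240.0
    rng = np.random.default_rng(seed)
    reference = np.asarray(reference, dtype=float)
    out = []
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        if jitter == 0:
            cand = reference.copy()
        else:
            sigma = jitter * (outlier_scale
                              if rng.uniform() < outlier_fraction else 1.0)
            cand = reference * np.exp(rng.normal(0.0, sigma,
                                                 size=reference.shape))
        if check_fc1(cand, model, constraint, dt=dt, horizon=horizon,
                     size_cap=size_cap, band=band):
            out.append(cand)
    if not out:
        raise RuntimeError(
            f"no FC1-feasible vector found in {tries} tries "
            f"(jitter={jitter}, seed={seed})")
    return np.vstack(out)


def make_module_structured_features(n_records: int = 3000,
                                    effect_size: float = 1.0,
                                    seed: int = 0):
    """Synthetic abundance-statistic feature table with module labels.

    Each record mimics one relative-abundance summary (mean, std, CV of a
    ratio across an ensemble, plus a numeric mutant id).  The three feature
    distributions are shifted per module by ``effect_size`` standard
    deviations; ``effect_size=0`` makes labels exchangeable.

    Returns ``(records, annotation)`` where records is a DataFrame with
    columns ``mutant, num, den, mean, std, cv`` and annotation maps each
    numerator species to its module.
    """
    import pandas as pd

    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    modules = [MODULE_START, MODULE_SG2M, MODULE_EXIT]
    # three proteins per module so the annotation map is non-trivial
    species = {m: [f"{m.replace('/', '')}_p{k}" for k in range(3)]
               for m in modules}
    annotation = {sp: m for m in modules for sp in species[m]}
    shifts = {MODULE_START: (1.0, 0.5, 0.0),
              MODULE_SG2M: (0.0, 1.0, 0.5),
              MODULE_EXIT: (0.5, 0.0, 1.0)}

    labels = rng.choice(modules, size=n_records)
    rows = []
    all_species = [sp for m in modules for sp in species[m]]
    for lab in labels:
        sh = shifts[lab]
        mean = math.exp(rng.normal(effect_size * sh[0], 1.0))
        std = math.exp(rng.normal(effect_size * sh[1], 1.0))
        cv = abs(rng.normal(effect_size * sh[2], 1.0))
        num = species[lab][rng.integers(0, 3)]
        den = all_species[rng.integers(0, len(all_species))]
        mutant = int(rng.integers(1, 130))
        rows.append((mutant, num, den, mean, std, cv))
    records = pd.DataFrame(rows, columns=["mutant", "num", "den",
                                          "mean", "std", "cv"])
    return records, annotation
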