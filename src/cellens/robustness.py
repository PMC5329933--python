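"""Perturbation-grid robustness scoring of feasible parameter vectors.

Each critical parameter is scaled by +/-20/40/60/80% and also set to zero
(nine levels, one at a time).  For each (vector, parameter, strain, level)
the strain is re-simulated and the indicator records whether the strain's
pre-perturbation phenotype (simulated once per vector and cached) is
maintained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import model_core
from .model_core import (
    ModelSpec,
    StrainSpec,
    WILD_TYPE,
    classify_phenotype,
    simulate_strain,
)

__all__ = [
    "PerturbationGrid",
    "RobustnessTensor",
    "robustness_tensor",
    "r_hat",
    "r_breve",
    "r_tilde",
    "r_bar",
    "relative_robustness",
]

#: Multiplicative levels 1 +/- {0.2, 0.4, 0.6, 0.8}; the ninth level is an
#: absolute zero.  A -80% perturbation keeps the parameter positive (0.2x),
#: so set-to-zero is the only hard zero.
DEFAULT_FACTORS = (0.2, 0.4, 0.6, 0.8, 1.2, 1.4, 1.6, 1.8)


@dataclass(frozen=True)
class PerturbationGrid:
    """One-at-a-time perturbations of a critical-parameter set."""

    params: tuple
    factors: tuple = DEFAULT_FACTORS
    include_zero: bool = True

    def __post_init__(self):
        if len(set(self.params)) != len(self.params):
            raise ValueError("duplicate parameter names")

    @property
    def n_levels(self) -> int:
        return len(self.factors) + (1 if self.include_zero else 0)

    def level_value(self, nominal: float, level: int) -> float:
        """Perturbed value of a parameter at the given level index."""
        if level < len(self.factors):
            return nominal * self.factors[level]
        if self.include_zero and level == len(self.factors):
            return 0.0
        raise IndexError(f"level {level} out of range")

    def apply(self, model: ModelSpec, pv: np.ndarray, param: str,
              level: int) -> np.ndarray:
        out = np.array(pv, dtype=float, copy=True)
        j = model.param_index(param)
        out[j] = self.level_value(out[j], level)
        return out


@dataclass
class RobustnessTensor:
    """Indicator R[i, j, k, l] over vectors, parameters, strains, levels."""

    values: np.ndarray  # uint8, shape (m, n_params, n_strains, n_levels)
    params: tuple
    strain_ids: tuple
    baseline: Optional[np.ndarray] = None  # (m, n_strains) phenotype codes

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("robustness tensor must be 4-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("tensor entries must be 0 or 1")

    def to_frame(self):
        """Long-format export (vector_id, param, strain, level, maintained)."""
        import pandas as pd

        m, np_, ns, nl = self.values.shape
        idx = np.indices((m, np_, ns, nl)).reshape(4, -1)
        return pd.DataFrame({
            "vector_id": idx[0],
            "param": [self.params[j] for j in idx[1]],
            "strain": [self.strain_ids[k] for k in idx[2]],
            "level": idx[3],
            "maintained": self.values.reshape(-1),
        })


def robustness_tensor(ensemble_values: np.ndarray, model: ModelSpec,
                      grid: PerturbationGrid,
                      strains: Sequence[StrainSpec],
                      dt: float = model_core.DEFAULT_DT,
                      horizon: float = model_core.DEFAULT_HORIZON,
                      size_cap: float = model_core.DEFAULT_SIZE_CAP,
                      band: float = model_core.DEFAULT_BAND) -> RobustnessTensor:
    """Simulate the whole perturbation protocol for every ensemble vector.

    Phenotype "maintained" means equality with the same strain's phenotype
    under the unperturbed vector; simulation failures count as lost.
    Mutant simulations are seeded from the perturbed vector's own wild-type
    final state, recomputed per perturbation.
    """
    values = np.asarray(ensemble_values, dtype=float)
    if values.ndim != 2:
        raise ValueError("ensemble must be 2-D")
    m = values.shape[0]
    n_par, n_str, n_lev = len(grid.params), len(strains), grid.n_levels
    R = np.zeros((m, n_par, n_str, n_lev), dtype=np.uint8)
    baseline = np.zeros((m, n_str), dtype=np.int8)

    def phenotypes(pv) -> list:
        wt_traj = simulate_strain(model, pv, WILD_TYPE, dt=dt,
                                  horizon=horizon, store_states=False)
        seed = wt_traj.last_post_division_state
        codes = []
        for strain in strains:
            if strain.is_wild_type:
                codes.append(classify_phenotype(wt_traj, size_cap, band).code)
            elif seed is None:
                codes.append(model_core.INVIABLE)
            else:
                traj = simulate_strain(model, pv, strain, dt=dt,
                                       horizon=horizon, init=seed,
                                       store_states=False)
                codes.append(classify_phenotype(traj, size_cap, band).code)
        return codes

    for i in range(m):
        baseline[i] = phenotypes(values[i])
        for j, param in enumerate(grid.params):
            for l in range(n_lev):
                perturbed = grid.apply(model, values[i], param, l)
                codes = phenotypes(perturbed)
                for k in range(n_str):
                    R[i, j, k, l] = 1 if codes[k] == baseline[i, k] else 0
    return RobustnessTensor(values=R, params=tuple(grid.params),
                            strain_ids=tuple(s.id for s in strains),
                            baseline=baseline)


def _vals(tensor) -> np.ndarray:
    return tensor.values if isinstance(tensor, RobustnessTensor) \
        else np.asarray(tensor)


def r_hat(tensor, i: int) -> int:
    """Robustness score of vector i: sum of R over parameters, strains, levels."""
    return int(_vals(tensor)[i].sum())


def r_breve(tensor) -> int:
    """Highest per-vector robustness score within the ensemble."""
    v = _vals(tensor)
    return int(v.reshape(v.shape[0], -1).sum(axis=1).max())


def r_tilde(tensor, i: int, j: int, k: int) -> int:
    """Per-(vector, parameter, strain) score: sum of R over levels."""
    return int(_vals(tensor)[i, j, k].sum())


def r_bar(tensor, j: int, k: int) -> int:
    """Maximum over vectors of the per-(parameter, strain) score."""
    return int(_vals(tensor)[:, j, k].sum(axis=1).max())


def r_hat_all(tensor) -> np.ndarray:
    v = _vals(tensor)
    return v.reshape(v.shape[0], -1).sum(axis=1)


def r_bar_all(tensor) -> np.ndarray:
    """R-bar for every (parameter, strain) pair, shape (n_params, n_strains)."""
    return _vals(tensor).sum(axis=3).max(axis=0)


def relative_robustness(tensor_a, tensor_b) -> np.ndarray:
    """Sign of (R-bar_b - R-bar_a) per (parameter, strain) pair.

    -1 where ensemble b is less robust than a, +1 where more, 0 on ties.
    """
    a, b = r_bar_all(tensor_a), r_bar_all(tensor_b)
    if a.shape != b.shape:
        raise ValueError("tensors cover different (parameter, strain) grids")
    return np.sign(b.astype(int) - a.astype(int)).astype(int)
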