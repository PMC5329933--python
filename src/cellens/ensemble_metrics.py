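"""Prediction matrices, prediction range, sampling efficiencies, and
ensemble-volume diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import model_core
from .model_core import (
    INVIABLE,
    ModelSpec,
    StrainSpec,
    WILD_TYPE,
    classify_phenotype,
    simulate_strain,
)

__all__ = [
    "Ensemble",
    "PredictionMatrix",
    "predict_vector",
    "prediction_matrix",
    "prediction_range",
    "sampling_efficiency",
    "feasibility_efficiency",
    "estimated_log_volume",
    "volume_key",
    "parameter_range_ratios",
]


@dataclass
class Ensemble:
    """An (m, n) matrix of feasible parameter vectors with named columns."""

    values: np.ndarray
    param_names: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("ensemble must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ensemble contains non-finite entries")
        if self.values.shape[1] != len(self.param_names):
            raise ValueError("column count does not match parameter names")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.param_names))


@dataclass
class PredictionMatrix:
    """An (m, l) integer matrix of phenotype codes; columns follow the panel."""

    values: np.ndarray
    strain_ids: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("prediction matrix must be 2-D")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("phenotype codes must be in {0, 1, 2}")
        if self.values.shape[1] != len(self.strain_ids):
            raise ValueError("column count does not match strain ids")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values,
                            columns=[str(s) for s in self.strain_ids])


def predict_vector(pv: np.ndarray, model: ModelSpec,
                   strains: Sequence[StrainSpec],
                   dt: float = model_core.DEFAULT_DT,
                   horizon: float = model_core.DEFAULT_HORIZON,
                   size_cap: float = model_core.DEFAULT_SIZE_CAP,
                   band: float = model_core.DEFAULT_BAND) -> tuple:
    """Phenotype codes of `strains` under one vector, WT-seeded.

    The wild type is simulated once from the vector's own initial
    conditions; every mutant starts from the state right after the last WT
    division.  An acyclic wild type (or any simulation failure) makes every
    dependent strain inviable.
    """
    wt_traj = simulate_strain(model, pv, WILD_TYPE, dt=dt, horizon=horizon,
                              store_states=False)
    wt_seed = wt_traj.last_post_division_state
    codes = []
    for strain in strains:
        if strain.is_wild_type:
            codes.append(classify_phenotype(wt_traj, size_cap, band).code)
        elif wt_seed is None:
            codes.append(INVIABLE)  # cannot seed from an acyclic wild type
        else:
            traj = simulate_strain(model, pv, strain, dt=dt, horizon=horizon,
                                   init=wt_seed, store_states=False)
            codes.append(classify_phenotype(traj, size_cap, band).code)
    return tuple(codes)


def prediction_matrix(ensemble: Ensemble, model: ModelSpec,
                      strains: Sequence[StrainSpec],
                      dt: float = model_core.DEFAULT_DT,
                      horizon: float = model_core.DEFAULT_HORIZON,
                      size_cap: float = model_core.DEFAULT_SIZE_CAP,
                      band: float = model_core.DEFAULT_BAND) -> PredictionMatrix:
    """Entry (i, j) is the phenotype of strain j under ensemble vector i."""
    rows = [predict_vector(pv, model, strains, dt=dt, horizon=horizon,
                           size_cap=size_cap, band=band)
            for pv in ensemble.values]
    return PredictionMatrix(values=np.asarray(rows, dtype=np.int8),
                            strain_ids=tuple(s.id for s in strains))


def prediction_range(P: PredictionMatrix) -> int:
    """S(P): number of distinct rows of the prediction matrix."""
    values = P.values if isinstance(P, PredictionMatrix) else np.asarray(P)
    if values.size == 0 or values.shape[0] == 0:
        raise ValueError("prediction matrix is empty")
    return len({tuple(int(v) for v in row) for row in values})


def sampling_efficiency(S: int, n_tot: int) -> float:
    """e_S = S / n_tot, the unique-prediction yield per sample."""
    if n_tot <= 0:
        raise ValueError("n_tot must be positive")
    return S / n_tot


def feasibility_efficiency(n_fc1: int, n_tot: int) -> float:
    """e_FC1 = n_FC1 / n_tot, the feasible-vector yield per sample."""
    if n_tot <= 0:
        raise ValueError("n_tot must be positive")
    return n_fc1 / n_tot


def _resolve_axes(param_names: Sequence[str], axes) -> np.ndarray:
    if axes is None:
        return np.arange(len(param_names))
    idx = []
    names = list(param_names)
    for a in axes:
        idx.append(names.index(a) if isinstance(a, str) else int(a))
    return np.asarray(idx, dtype=int)


def estimated_log_volume(ensemble, axes=None,
                         param_names: Optional[Sequence[str]] = None) -> float:
    """Log of the axis-aligned bounding-box volume over the chosen axes.

    Sum over axes of ``log(max - min)`` across ensemble members; ``-inf``
    when any axis is degenerate.  All volume comparisons (FC2, biased
    initial-population selection) happen on this log scale.
    """
    if isinstance(ensemble, Ensemble):
        values = ensemble.values
        names = ensemble.param_names
    else:
        values = np.asarray(ensemble, dtype=float)
        names = param_names if param_names is not None else \
            tuple(range(values.shape[1]))
    if values.shape[0] < 2:
        raise ValueError("at least two vectors are required")
    idx = _resolve_axes(names, axes)
    ranges = values[:, idx].max(axis=0) - values[:, idx].min(axis=0)
    if np.any(ranges <= 0):
        return float("-inf")
    return float(np.sum(np.log(ranges)))


def volume_key(values: np.ndarray, axes_idx: np.ndarray):
    """Comparison key for greedy volume maximisation that stays informative
    when some axes are still degenerate: (#non-degenerate axes, sum of log
    ranges over those axes).  Larger is better, compared lexicographically.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        return (0, float("-inf"))
    ranges = values[:, axes_idx].max(axis=0) - values[:, axes_idx].min(axis=0)
    pos = ranges > 0
    if not pos.any():
        return (0, float("-inf"))
    return (int(pos.sum()), float(np.sum(np.log(ranges[pos]))))


def parameter_range_ratios(ensemble: Ensemble) -> dict:
    """Per-parameter max/min ratio across the ensemble.

    Axes containing non-positive values are excluded with a warning.
    """
    out = {}
    for j, name in enumerate(ensemble.param_names):
        col = ensemble.values[:, j]
        if np.any(col <= 0):
            warnings.warn(
                f"parameter {name!r} has non-positive values; "
                "excluded from range ratios")
            continue
        out[name] = float(col.max() / col.min())
    return out
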