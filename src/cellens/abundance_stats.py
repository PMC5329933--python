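"""Relative-abundance variability statistics across feasible ensembles.

For every consistently viable strain and every ordered species pair (a, b),
the ratio of time-averaged abundances a/b is computed under each ensemble
vector; the spread of that ratio across the ensemble is summarised by its
coefficient of variation (sample standard deviation / mean).  Sums of CVs
give per-mutant and per-protein variability scores, which are ranked,
bucketed into high/low categories, and aggregated per biological process.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import model_core
from .ensemble_metrics import Ensemble, PredictionMatrix
from .model_core import (
    ModelSpec,
    StrainSpec,
    VIABLE,
    WILD_TYPE,
    simulate_strain,
    time_average_abundances,
)

__all__ = [
    "consistently_viable_mutants",
    "relative_abundance_table",
    "mutant_variability",
    "protein_variability_scores",
    "ranking_orientation_correlation",
    "process_variability",
]


def consistently_viable_mutants(prediction_matrices: Sequence[PredictionMatrix]):
    """Strain ids predicted viable by every vector of every matrix."""
    if not prediction_matrices:
        raise ValueError("no prediction matrices given")
    ids = prediction_matrices[0].strain_ids
    for P in prediction_matrices[1:]:
        if P.strain_ids != ids:
            raise ValueError("prediction matrices cover different panels")
    viable = np.ones(len(ids), dtype=bool)
    for P in prediction_matrices:
        viable &= (P.values == VIABLE).all(axis=0)
    return {ids[k] for k in np.nonzero(viable)[0]}


def relative_abundance_table(ensemble: Ensemble, model: ModelSpec,
                             strains: Sequence[StrainSpec],
                             include_self_ratios: bool = False,
                             dt: float = model_core.DEFAULT_DT,
                             horizon: float = model_core.DEFAULT_HORIZON,
                             drop_nonfinite: bool = True) -> pd.DataFrame:
    """Mean/std/CV of every ordered-pair abundance ratio per strain.

    Mutants are seeded from each vector's wild-type final state; the wild
    type itself may be included in ``strains``.  Standard deviations use the
    sample (n-1) convention.  Records whose CV is non-finite (zero or
    undefined mean, or an undefined ratio under any vector) are dropped by
    default.

    Returns a DataFrame with columns
    ``mutant, num, den, mean, std, cv, n_vectors``.
    """
    species = model.species
    m = ensemble.m
    # abundances[v][s] = dict species -> time average, for vector v strain s
    abundances = np.full((m, len(strains), len(species)), np.nan)
    for v, pv in enumerate(ensemble.values):
        wt_traj = simulate_strain(model, pv, WILD_TYPE, dt=dt,
                                  horizon=horizon, store_states=False)
        seed = wt_traj.last_post_division_state
        for s, strain in enumerate(strains):
            if strain.is_wild_type:
                traj = wt_traj
            elif seed is None:
                continue  # leaves NaN; the record is dropped downstream
            else:
                traj = simulate_strain(model, pv, strain, dt=dt,
                                       horizon=horizon, init=seed,
                                       store_states=False)
            means = time_average_abundances(traj)
            abundances[v, s] = [means[name] for name in species]

    rows = []
    pairs = itertools.product(range(len(species)), repeat=2) \
        if include_self_ratios else itertools.permutations(range(len(species)), 2)
    pairs = list(pairs)
    for s, strain in enumerate(strains):
        block = abundances[:, s, :]
        for a, b in pairs:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = block[:, a] / block[:, b]
            if not np.all(np.isfinite(ratios)):
                if drop_nonfinite:
                    continue
                ratios = ratios[np.isfinite(ratios)]
                if len(ratios) < 2:
                    continue
            mean = float(np.mean(ratios))
            std = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
            cv = std / mean if mean != 0 else float("nan")
            if drop_nonfinite and not np.isfinite(cv):
                continue
            rows.append((strain.id, species[a], species[b],
                         mean, std, cv, len(ratios)))
    return pd.DataFrame(rows, columns=["mutant", "num", "den",
                                       "mean", "std", "cv", "n_vectors"])


def mutant_variability(records: pd.DataFrame) -> pd.DataFrame:
    """Per-mutant sum of finite CVs, ranked in descending order."""
    if records.empty:
        raise ValueError("no abundance records")
    finite = records[np.isfinite(records["cv"])]
    sums = finite.groupby("mutant")["cv"].sum().sort_values(ascending=False)
    out = sums.reset_index().rename(columns={"cv": "variability"})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def protein_variability_scores(records: pd.DataFrame,
                               orientation: str = "numerator") -> pd.DataFrame:
    """Per-protein summed CV under the chosen orientation.

    ``orientation`` picks which side of the ratio attributes the CV to a
    protein.  Ranks are descending by score (ties broken by species name);
    percentile = 100 * (n - rank) / (n - 1); category is "high" in the top
    half of the ranking and "low" in the bottom half.
    """
    if records.empty:
        raise ValueError("no abundance records")
    col = {"numerator": "num", "denominator": "den"}.get(orientation)
    if col is None:
        raise ValueError("orientation must be 'numerator' or 'denominator'")
    finite = records[np.isfinite(records["cv"])]
    sums = finite.groupby(col)["cv"].sum()
    df = sums.reset_index().rename(columns={col: "protein",
                                            "cv": "variability"})
    df = df.sort_values(["variability", "protein"],
                        ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    if n > 1:
        df["percentile"] = 100.0 * (n - df["rank"]) / (n - 1)
    else:
        df["percentile"] = 100.0
    top = n - n // 2  # the bottom half (floor) is "low"
    df["category"] = np.where(df["rank"] <= top, "high", "low")
    return df


def ranking_orientation_correlation(report_num: pd.DataFrame,
                                    report_den: pd.DataFrame) -> float:
    """Pearson correlation between the two orientation rank vectors."""
    a = report_num.set_index("protein")["rank"]
    b = report_den.set_index("protein")["rank"]
    if set(a.index) != set(b.index):
        raise ValueError("reports cover different protein sets")
    b = b.reindex(a.index)
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero-variance ranks")
    return float(np.corrcoef(a.to_numpy(float), b.to_numpy(float))[0, 1])


def process_variability(report: pd.DataFrame,
                        annotation: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Mean +/- sample std of member-protein scores per biological process.

    ``annotation`` maps protein -> iterable of process names.  Singleton
    processes get std 0; processes without any protein present in the
    report are excluded with a warning.  Ranked descending by mean.
    """
    scores = report.set_index("protein")["variability"]
    per_process: dict = {}
    for protein, processes in annotation.items():
        if protein not in scores.index:
            raise ValueError(f"annotated protein {protein!r} missing from report")
        for proc in processes:
            per_process.setdefault(proc, []).append(float(scores[protein]))
    rows = []
    for proc, vals in per_process.items():
        if not vals:
            warnings.warn(f"process {proc!r} has no member proteins; excluded")
            continue
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append((proc, mean, std, len(vals)))
    out = pd.DataFrame(rows, columns=["process", "mean", "std", "n_proteins"])
    out = out.sort_values(["mean", "process"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
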