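"""Random-forest prediction of a regulator's network module from
relative-abundance statistics.

The forest is built tree by tree: each tree trains on a bootstrap sample
(with replacement, same size as the data) and the rows left out of a tree's
bootstrap are its out-of-bag (OOB) rows.  Each row is scored by the vote
fractions of the trees that never saw it, and one-vs-rest ROC AUCs are
computed per module from those OOB vote fractions (midrank tie handling,
equivalent to trapezoidal integration of the ROC curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FEATURE_COLUMNS",
    "AUCReport",
    "build_feature_table",
    "train_eval_once",
    "repeated_eval",
    "auc_from_scores",
    "combined_report",
]

#: The four model inputs: summary statistics of one relative abundance plus
#: the numeric id of the mutant that generated it.
FEATURE_COLUMNS = ("mean", "std", "cv", "mutant")


@dataclass
class AUCReport:
    """Per-module AUC summary over repeated runs."""

    per_module: pd.DataFrame  # columns: module, auc_mean, auc_std, z, p_value
    n_runs: int
    n_trees: int
    permuted: bool

    def __str__(self) -> str:
        return self.per_module.to_string(index=False)


def build_feature_table(records: pd.DataFrame,
                        annotation: Mapping[str, str],
                        reference: str = "numerator") -> pd.DataFrame:
    """One feature row per abundance record, labelled by the module of the
    reference species.  Rows whose reference species has no module
    annotation are dropped; non-finite feature rows are rejected."""
    col = {"numerator": "num", "denominator": "den"}.get(reference)
    if col is None:
        raise ValueError("reference must be 'numerator' or 'denominator'")
    labels = records[col].map(annotation)
    rows = records.loc[labels.notna(),
                       ["mutant", "num", "den", "mean", "std", "cv"]].copy()
    rows["label"] = labels[labels.notna()]
    feats = rows[list(FEATURE_COLUMNS)].to_numpy(float)
    if not np.all(np.isfinite(feats)):
        raise ValueError("feature rows contain non-finite values")
    if rows.empty:
        raise ValueError("no annotated records; feature table is empty")
    return rows.reset_index(drop=True)


def auc_from_scores(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest AUC of `scores` for the boolean `positive` mask.

    Mann-Whitney / midrank formulation: identical to trapezoidal ROC
    integration with tied scores contributing at half weight.
    """
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative samples")
    ranks = rankdata(scores)  # average (mid) ranks
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def train_eval_once(rows: pd.DataFrame, n_trees: int = 100,
                    seed: int = 0,
                    labels: Optional[np.ndarray] = None) -> dict:
    """Train one forest and return the per-module OOB one-vs-rest AUCs.

    ``labels`` may override the label column (used for permutation runs).
    A module with fewer than two OOB rows gets a NaN AUC.
    """
    X = rows[list(FEATURE_COLUMNS)].to_numpy(float)
    y = np.asarray(labels if labels is not None else rows["label"])
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two modules to classify")
    n = len(y)
    rng = np.random.default_rng(seed)
    class_index = {c: k for k, c in enumerate(classes)}
    y_idx = np.fromiter((class_index[v] for v in y), dtype=int, count=n)

    votes = np.zeros((n, len(classes)))
    oob_counts = np.zeros(n, dtype=int)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y_idx[boot])
        if not oob.any():
            continue
        pred = tree.predict(X[oob])
        votes[np.nonzero(oob)[0], pred] += 1
        oob_counts[oob] += 1

    scored = oob_counts > 0
    frac = np.zeros_like(votes)
    frac[scored] = votes[scored] / oob_counts[scored, None]

    aucs = {}
    for c, k in class_index.items():
        mask = scored
        pos = (y_idx == k) & mask
        neg = (y_idx != k) & mask
        if pos.sum() < 2 or neg.sum() == 0:
            aucs[c] = float("nan")
            continue
        aucs[c] = auc_from_scores(frac[mask, k], (y_idx == k)[mask])
    return aucs


def repeated_eval(rows: pd.DataFrame, n_runs: int = 100, n_trees: int = 100,
                  permute: bool = False, seed: int = 0) -> AUCReport:
    """Mean +/- std AUC over repeated forest runs, with a one-sided Z-test
    of the mean AUC against the chance level 0.5.

    With ``permute`` the labels are reshuffled independently before every
    run.  The standard error is the std of the per-run AUCs divided by
    sqrt(n_runs); the alternative hypothesis is AUC > 0.5.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    rng = np.random.default_rng(seed)
    base_labels = rows["label"].to_numpy()
    per_run: dict = {}
    for _ in range(n_runs):
        labels = rng.permutation(base_labels) if permute else base_labels
        run_seed = int(rng.integers(0, 2**31 - 1))
        aucs = train_eval_once(rows, n_trees=n_trees, seed=run_seed,
                               labels=labels)
        for module, value in aucs.items():
            per_run.setdefault(module, []).append(value)

    out = []
    for module in sorted(per_run):
        vals = np.asarray(per_run[module], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if std == 0.0:
            z = 0.0 if mean == 0.5 else math.copysign(math.inf, mean - 0.5)
        else:
            z = (mean - 0.5) / (std / math.sqrt(len(vals)))
        p = float(norm.sf(z))
        out.append((module, mean, std, z, p))
    frame = pd.DataFrame(out, columns=["module", "auc_mean", "auc_std",
                                       "z", "p_value"])
    return AUCReport(per_module=frame, n_runs=n_runs, n_trees=n_trees,
                     permuted=permute)


def combined_report(true_report: AUCReport,
                    permuted_report: AUCReport) -> pd.DataFrame:
    """Side-by-side table: positive class, mean +/- std AUC and p-value of
    the true-label model next to the randomized-label counterpart."""
    a = true_report.per_module.rename(columns={
        "auc_mean": "auc_mean", "auc_std": "auc_std", "p_value": "p_value"})
    b = permuted_report.per_module.rename(columns={
        "auc_mean": "auc_mean_randomized",
        "auc_std": "auc_std_randomized",
        "p_value": "p_value_randomized"})
    cols = ["module", "auc_mean", "auc_std", "p_value"]
    out = a[cols].merge(
        b[["module", "auc_mean_randomized", "auc_std_randomized",
           "p_value_randomized"]], on="module")
    return out
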