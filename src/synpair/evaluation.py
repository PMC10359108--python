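"""Leakage-aware cross-validation, regression metrics and hyperparameter search.

Two split strategies serve the transductive imputation setting:

* ``leave_triple_out`` deals unique (drug pair, CCL) triples into folds, so
  a sample and its order-swap mirror always share a fold;
* ``leave_pair_out`` deals unique unordered drug pairs into folds, so a drug
  pair in the test fold is never seen during training (in any CCL or order).

Regression quality is summarized by RMSE, Spearman and Pearson correlation;
classification quality by AUROC after binarizing synergy scores at a
threshold grid (scores in the closed band ``[-t, +t]`` are discarded as
low-confidence).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from .data import (
    DrugSignatureSet,
    SynergyRecord,
    TripleSample,
    ValidationError,
    samples_to_arrays,
)
from .model import SynergyRegressor
from .nn import TrainingDiverged

__all__ = [
    "FoldAssignment",
    "MetricReport",
    "split_leave_triple_out",
    "split_leave_pair_out",
    "regression_metrics",
    "binarize_scores",
    "auroc",
    "cross_validate",
    "default_hyperparameter_grid",
    "enumerate_grid",
    "grid_search",
    "signature_correlation_vs_synergy",
]


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """A partition of sample indices into k folds by grouping unit."""

    strategy: str
    k: int
    assignment: dict[int, int]
    seed: int

    def fold_of(self, sample_id: int) -> int:
        return self.assignment[sample_id]

    def test_indices(self, fold: int) -> np.ndarray:
        return np.array(sorted(i for i, f in self.assignment.items() if f == fold), dtype=int)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.array(sorted(i for i, f in self.assignment.items() if f != fold), dtype=int)

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.assignment)
        return pd.DataFrame({"sample_id": ids, "fold": [self.assignment[i] for i in ids]})


def _deal_groups(
    samples: Sequence[TripleSample],
    group_of: Mapping[int, tuple],
    k: int,
    seed: int,
    strategy: str,
) -> FoldAssignment:
    groups = sorted(set(group_of.values()))
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > len(groups):
        raise ValidationError(f"k={k} exceeds the {len(groups)} available grouping units")
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    fold_of_group = {g: i % k for i, g in enumerate(order)}
    assignment = {i: fold_of_group[group_of[i]] for i in range(len(samples))}
    return FoldAssignment(strategy=strategy, k=k, assignment=assignment, seed=seed)


def split_leave_triple_out(
    samples: Sequence[TripleSample], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Deal unique (pair, CCL) triples into k folds; mirrors follow their triple."""
    group_of = {i: (s.pair_key, s.ccl_id) for i, s in enumerate(samples)}
    return _deal_groups(samples, group_of, k, seed, "leave_triple_out")


def split_leave_pair_out(
    samples: Sequence[TripleSample], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Deal unique unordered drug pairs into k folds; all of a pair's samples follow."""
    group_of = {i: s.pair_key for i, s in enumerate(samples)}
    return _deal_groups(samples, group_of, k, seed, "leave_pair_out")


_SPLITTERS = {
    "leave_triple_out": split_leave_triple_out,
    "leave_pair_out": split_leave_pair_out,
}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """RMSE, Spearman and Pearson correlation (average ranks on ties)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length non-empty vectors")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant input; correlations undefined", RuntimeWarning, stacklevel=2)
        return {"rmse": rmse, "scc": float("nan"), "pcc": float("nan")}
    pcc = float(stats.pearsonr(y_true, y_pred).statistic)
    scc = float(stats.spearmanr(y_true, y_pred).statistic)
    return {"rmse": rmse, "scc": scc, "pcc": pcc}


def binarize_scores(scores: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Binarize synergy scores at threshold ``t``.

    Scores strictly above ``+t`` are synergistic (label 1), strictly below
    ``-t`` antagonistic (label 0); the closed band ``[-t, +t]`` is discarded
    (at ``t = 0`` only exact zeros are dropped). Returns ``(labels,
    retained_indices)``.
    """
    if t < 0:
        raise ValidationError("threshold must be non-negative")
    scores = np.asarray(scores, dtype=float)
    positive = scores > t
    negative = scores < -t
    retained = np.flatnonzero(positive | negative)
    labels = positive[retained].astype(int)
    return labels, retained


def auroc(labels: np.ndarray, predicted_scores: np.ndarray) -> float:
    """AUROC of continuous predictions against binary labels (1 = synergistic)."""
    labels = np.asarray(labels)
    predicted_scores = np.asarray(predicted_scores, dtype=float)
    if labels.shape != predicted_scores.shape:
        raise ValidationError("labels and scores must have equal lengths")
    if labels.size == 0 or len(np.unique(labels)) < 2:
        warnings.warn("one class absent; AUROC undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(roc_auc_score(labels, predicted_scores))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Per-fold metrics with mean/std aggregation."""

    per_fold: pd.DataFrame
    strategy: str
    thresholds: tuple[float, ...] = (0, 1, 5, 10, 20)

    def mean(self) -> pd.Series:
        return self.per_fold.mean(numeric_only=True)

    def std(self) -> pd.Series:
        return self.per_fold.std(numeric_only=True, ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean(), "std": self.std()})

    def to_json(self) -> dict:
        return {
            "strategy": self.strategy,
            "thresholds": list(self.thresholds),
            "per_fold": self.per_fold.to_dict(orient="records"),
            "mean": self.mean().to_dict(),
            "std": self.std().to_dict(),
        }


def cross_validate(
    samples: Sequence[TripleSample],
    estimator,
    strategy: str = "leave_triple_out",
    k: int = 5,
    seed: int = 0,
    thresholds: Sequence[float] = (0, 1, 5, 10, 20),
    fold_assignment: FoldAssignment | None = None,
) -> MetricReport:
    """k-fold cross-validation of any sklearn-style regressor on triple samples.

    A fresh clone of ``estimator`` is fitted per fold. Metrics are computed
    on the synergy task (first output column when the estimator is
    multitask). Passing an explicit ``fold_assignment`` lets several model
    variants share identical test memberships.
    """
    if fold_assignment is None:
        if strategy not in _SPLITTERS:
            raise ValidationError(f"unknown strategy {strategy!r}; options: {sorted(_SPLITTERS)}")
        fold_assignment = _SPLITTERS[strategy](samples, k=k, seed=seed)
    X, Y, _ = samples_to_arrays(samples)
    rows = []
    for fold in range(fold_assignment.k):
        tr = fold_assignment.train_indices(fold)
        te = fold_assignment.test_indices(fold)
        est = clone(estimator)
        est.fit(X[tr], Y[tr])
        pred = np.asarray(est.predict(X[te]), dtype=float)
        pred_syn = pred[:, 0] if pred.ndim == 2 else pred
        true_syn = Y[te, 0]
        row: dict[str, float] = {"fold": fold, **regression_metrics(true_syn, pred_syn)}
        for t in thresholds:
            labels, retained = binarize_scores(true_syn, t)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row[f"auroc_t{t:g}"] = auroc(labels, pred_syn[retained])
        rows.append(row)
    return MetricReport(
        per_fold=pd.DataFrame(rows),
        strategy=fold_assignment.strategy,
        thresholds=tuple(thresholds),
    )


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------


def default_hyperparameter_grid() -> dict[str, list]:
    """The 576-combination tuning grid.

    Axes: learning rate (0.01, 0.001, 0.0001) x optimizer (adam, adamax) x
    input activation (linear, relu) x batch size (64, 128) x dropout
    (on/off) x 12 width/depth presets (width scale 0.5/1/2, encoder depth
    2/3, predictor depth 2/3).
    """
    architectures = [
        {"width_scale": ws, "encoder_depth": ed, "predictor_depth": pd_}
        for ws in (0.5, 1.0, 2.0)
        for ed in (2, 3)
        for pd_ in (2, 3)
    ]
    return {
        "learning_rate": [0.01, 0.001, 0.0001],
        "optimizer": ["adam", "adamax"],
        "input_activation": ["linear", "relu"],
        "batch_size": [64, 128],
        "dropout": [True, False],
        "architecture": architectures,
    }


def enumerate_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """Cartesian product of grid axes, as flat estimator-parameter dicts."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValidationError("grid must enumerate at least one option per axis")
    keys = list(grid)
    combos = []
    for values in itertools.product(*(grid[k] for k in keys)):
        combo: dict = {}
        for key, value in zip(keys, values):
            if key == "architecture":
                combo.update(value)
            elif key == "dropout":
                if value:
                    combo.update({"encoder_dropout": 0.2, "predictor_dropout": 0.5})
                else:
                    combo.update({"encoder_dropout": 0.0, "predictor_dropout": 0.0})
            else:
                combo[key] = value
        combos.append(combo)
    return combos


def grid_search(
    samples: Sequence[TripleSample],
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    base_estimator: SynergyRegressor | None = None,
    holdout_fraction: float = 0.2,
    strategy: str = "leave_pair_out",
    metric: str = "pcc",
    full_cv: bool = False,
    k: int = 5,
    subsample: int | None = None,
    max_combos: int | None = None,
) -> pd.DataFrame:
    """Evaluate every grid combination and rank the converged ones.

    By default each combination is scored on a single grouped held-out
    split (``holdout_fraction`` of grouping units); ``full_cv=True`` runs
    k-fold cross-validation per combination instead. Combinations whose
    training diverges (non-finite loss) are flagged ``converged=False`` and
    excluded from the ranking.
    """
    grid = grid or default_hyperparameter_grid()
    combos = enumerate_grid(grid)
    if max_combos is not None:
        combos = combos[:max_combos]
    samples = list(samples)
    rng = np.random.default_rng(seed)
    if subsample is not None and subsample < len(samples):
        keep = rng.choice(len(samples), size=subsample, replace=False)
        samples = [samples[i] for i in sorted(keep)]
    if base_estimator is None:
        # modest tuning budget per combination; override via base_estimator
        base_estimator = SynergyRegressor(
            drug_dim=samples[0].drug_dim, max_epochs=30, patience=5
        )

    X, Y, _ = samples_to_arrays(samples)
    k_holdout = max(2, int(round(1.0 / holdout_fraction)))
    fold = _SPLITTERS[strategy](samples, k=k_holdout, seed=seed)
    tr, te = fold.train_indices(0), fold.test_indices(0)

    rows = []
    for i, combo in enumerate(combos):
        est = clone(base_estimator)
        est.set_params(random_state=seed, **combo)
        converged = True
        score = float("nan")
        try:
            if full_cv:
                report = cross_validate(samples, est, strategy=strategy, k=k, seed=seed)
                score = float(report.mean()[metric])
            else:
                est.fit(X[tr], Y[tr])
                pred = np.asarray(est.predict(X[te]), dtype=float)
                pred_syn = pred[:, 0] if pred.ndim == 2 else pred
                score = float(regression_metrics(Y[te, 0], pred_syn)[metric])
        except TrainingDiverged:
            converged = False
        rows.append({"combo_id": i, **combo, "converged": converged, metric: score})
    table = pd.DataFrame(rows)
    ranked = table[table["converged"]].sort_values(metric, ascending=False)
    table["rank"] = pd.Series(
        {idx: r + 1 for r, idx in enumerate(ranked.index)}, dtype="Int64"
    )
    return table.sort_values(["rank"], na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# signature correlation vs synergy
# ---------------------------------------------------------------------------


def signature_correlation_vs_synergy(
    sigs: DrugSignatureSet, records: Sequence[SynergyRecord], ccl_id: str
) -> dict[str, float]:
    """Correlation between drug-signature similarity and synergy.

    For every record, computes the Pearson correlation between the two
    drugs' consensus signatures in ``ccl_id``; then correlates those
    per-triple values with the synergy scores (Pearson and Spearman).
    """
    if len(records) < 3:
        raise ValidationError("need at least 3 triples for a meaningful correlation")
    sims, scores = [], []
    for rec in records:
        s1 = sigs.consensus(rec.drug1_id, ccl_id)
        s2 = sigs.consensus(rec.drug2_id, ccl_id)
        sims.append(float(stats.pearsonr(s1, s2).statistic))
        scores.append(rec.score)
    sims_arr = np.array(sims)
    scores_arr = np.array(scores)
    return {
        "pcc": float(stats.pearsonr(sims_arr, scores_arr).statistic),
        "scc": float(stats.spearmanr(sims_arr, scores_arr).statistic),
    }
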