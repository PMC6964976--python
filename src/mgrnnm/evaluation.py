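"""Cross-validation protocols and ranking metrics.

Three cross-validation settings mirror the standard DTI evaluation
protocols: CVS1 masks random drug-target pairs, CVS2 masks whole drug rows
(novel drugs), CVS3 masks whole target columns (novel targets).  Each
setting runs k-fold CV over several runs; per fold the interaction-derived
similarities are recomputed from the training matrix only (no label
leakage), graphs rebuilt, the model refit, and AUPR/AUC computed on the
held-out entries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import DTIDataset
from .model import MGRNNMParams, mgrnnm_fit, predict
from .nnm import MaskedProblem
from .similarity import combined_graph

__all__ = [
    "SETTINGS",
    "FoldPlan",
    "MetricReport",
    "make_folds",
    "aupr",
    "auc",
    "training_problem",
    "cross_validate",
    "grid_search",
]

logger = logging.getLogger(__name__)

SETTINGS = ("CVS1", "CVS2", "CVS3")


@dataclass(frozen=True)
class FoldPlan:
    """Test-index partition for every run of k-fold cross-validation.

    folds[run] is a list of k test-index arrays: flat pair indices for
    CVS1, drug row indices for CVS2, target column indices for CVS3.
    """

    setting: str
    k_folds: int
    n_runs: int
    seeds: tuple[int, ...]
    folds: tuple[tuple[np.ndarray, ...], ...]
    n_drugs: int
    n_targets: int


def make_folds(
    n_drugs: int,
    n_targets: int,
    setting: str = "CVS1",
    k_folds: int = 10,
    n_runs: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Partition pairs (CVS1), drugs (CVS2) or targets (CVS3) into k
    disjoint test folds for each run, deterministically from the seed."""
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; choose one of {SETTINGS}")
    if setting == "CVS1":
        n_units = n_drugs * n_targets
    elif setting == "CVS2":
        n_units = n_drugs
    else:
        n_units = n_targets
    if k_folds > n_units:
        raise ValueError(
            f"{setting} with k_folds={k_folds} needs at least {k_folds} "
            f"units, have {n_units}"
        )
    ss = np.random.SeedSequence(seed)
    run_seeds = tuple(int(s) for s in ss.generate_state(n_runs))
    runs = []
    for rs in run_seeds:
        rng = np.random.default_rng(rs)
        perm = rng.permutation(n_units)
        runs.append(tuple(np.sort(f) for f in np.array_split(perm, k_folds)))
    return FoldPlan(
        setting=setting,
        k_folds=k_folds,
        n_runs=n_runs,
        seeds=run_seeds,
        folds=tuple(runs),
        n_drugs=n_drugs,
        n_targets=n_targets,
    )


def fold_mask(plan: FoldPlan, run: int, fold: int) -> np.ndarray:
    """Training mask for one fold: 1 on training entries (observed, whether
    interacting or not), 0 on test entries / rows / columns."""
    A = np.ones((plan.n_drugs, plan.n_targets))
    test = plan.folds[run][fold]
    if plan.setting == "CVS1":
        A.flat[test] = 0.0
    elif plan.setting == "CVS2":
        A[test, :] = 0.0
    else:
        A[:, test] = 0.0
    return A


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the non-interpolated precision-recall step curve."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR is undefined without positive labels")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties count 1/2)."""
    labels = np.asarray(labels)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("AUC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class MetricReport:
    """Per-fold metrics with their aggregate, for one dataset/setting/params."""

    setting: str
    dataset_label: str
    params: MGRNNMParams
    table: pd.DataFrame        # columns: run, fold, aupr, auc
    skipped: int = 0

    @property
    def aupr_mean(self) -> float:
        return float(self.table["aupr"].mean())

    @property
    def aupr_std(self) -> float:
        return float(self.table["aupr"].std(ddof=1))

    @property
    def auc_mean(self) -> float:
        return float(self.table["auc"].mean())

    @property
    def auc_std(self) -> float:
        return float(self.table["auc"].std(ddof=1))

    def summary(self) -> dict:
        return {
            "setting": self.setting,
            "dataset": self.dataset_label,
            "aupr_mean": self.aupr_mean,
            "aupr_std": self.aupr_std,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "n_folds_used": int(len(self.table)),
            "n_folds_skipped": int(self.skipped),
        }


def training_problem(
    ds: DTIDataset,
    A: np.ndarray,
    params: MGRNNMParams,
    similarity_from_full: bool = False,
):
    """Build the masked problem and both side graphs for a training mask.

    By default the interaction-derived similarities are computed from the
    training matrix only (test entries zeroed); similarity_from_full
    reproduces the leakier variant computed once from the full matrix.
    """
    M = ds.interactions * A
    source = ds.interactions if similarity_from_full else M
    Ld = combined_graph(
        source, ds.chem_similarity, "drug",
        weights=params.weights, p=params.p,
        normalized=params.normalized_laplacian,
    )
    Lt = combined_graph(
        source, ds.seq_similarity, "target",
        weights=params.weights, p=params.p,
        normalized=params.normalized_laplacian,
    )
    return MaskedProblem(observed=M, mask=A), Ld, Lt


def cross_validate(
    ds: DTIDataset,
    params: MGRNNMParams,
    plan: FoldPlan,
    dataset_label: str = "dataset",
    similarity_from_full: bool = False,
) -> MetricReport:
    """Run the full CV protocol: per fold, rebuild similarities and graphs
    from training data, fit, and score the held-out entries.

    Folds whose test set has no positive label (or, for AUC, no negative)
    are skipped with a warning -- unavoidable on very small networks.
    """
    if (ds.n_drugs, ds.n_targets) != (plan.n_drugs, plan.n_targets):
        raise ValueError("fold plan shape does not match the dataset")
    rows = []
    skipped = 0
    for run in range(plan.n_runs):
        for fold in range(plan.k_folds):
            A = fold_mask(plan, run, fold)
            test = A.ravel() == 0.0
            labels = ds.interactions.ravel()[test]
            if labels.sum() == 0 or labels.sum() == labels.size:
                skipped += 1
                logger.warning(
                    "skipping %s run %d fold %d: single-class test labels",
                    plan.setting, run, fold,
                )
                continue
            problem, Ld, Lt = training_problem(
                ds, A, params, similarity_from_full=similarity_from_full
            )
            state = mgrnnm_fit(problem, Ld, Lt, params)
            scores = predict(state).ravel()[test]
            rows.append(
                {"run": run, "fold": fold,
                 "aupr": aupr(scores, labels), "auc": auc(scores, labels)}
            )
    table = pd.DataFrame(rows, columns=["run", "fold", "aupr", "auc"])
    return MetricReport(
        setting=plan.setting,
        dataset_label=dataset_label,
        params=params,
        table=table,
        skipped=skipped,
    )


def grid_search(
    ds: DTIDataset,
    plan: FoldPlan,
    grid: dict[str, list],
    base_params: MGRNNMParams | None = None,
    dataset_label: str = "dataset",
) -> tuple[MGRNNMParams, pd.DataFrame]:
    """Exhaustive hyperparameter search selecting the grid point with the
    best mean validation AUPR.

    Each grid point is evaluated by cross-validation over ``plan`` on the
    data it is given; for an unbiased outer estimate, pass the training
    portion only and keep a separate held-out evaluation.  Ties break
    deterministically by grid enumeration order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    base = base_params or MGRNNMParams()
    keys = list(grid)
    rows = []
    best_params, best_aupr = None, -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = replace(base, **dict(zip(keys, combo)))
        report = cross_validate(ds, params, plan, dataset_label=dataset_label)
        row = dict(zip(keys, combo))
        row.update(setting=plan.setting, aupr_mean=report.aupr_mean,
                   auc_mean=report.auc_mean)
        rows.append(row)
        if report.aupr_mean > best_aupr:
            best_aupr, best_params = report.aupr_mean, params
    return best_params, pd.DataFrame(rows)
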