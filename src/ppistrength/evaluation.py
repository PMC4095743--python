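"""Cross-validated evaluation protocol.

The protocol is threefold outer cross-validation over the protein pairs.
Within each outer-training split, the Laplacian kernel parameter sigma is
selected by fivefold inner cross-validation over a grid, separately for
every value of the SVR regularisation constant C. The APM domain-pair score
table is always rebuilt from the outer-training pairs only, and test pairs
are restricted to those whose every domain pair received a score from the
training split (the coverage filter), so that the regression models and the
APM baseline are scored on the same pairs.

Default grids: sigma in {0.01, 0.02, ..., 0.1} and C in {1, 2, 5}; the RVM
on the one-dimensional APM-score feature instead uses
sigma in {3.0, 3.1, ..., 9.0}, a scale matched to the small distances of
that feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import apm_scores, coverage_filter, predict_strength
from .data_model import PairDataset, PairRecord
from .features import feature_matrix
from .regression import KernelSpec, rvm_fit, svr_fit

__all__ = [
    "DEFAULT_SIGMA_GRID",
    "RVM_APM_SIGMA_GRID",
    "DEFAULT_C_GRID",
    "CVPlan",
    "FoldResult",
    "EvaluationReport",
    "rmse",
    "make_cv_plan",
    "select_sigma",
    "run_protocol",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_GRID: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(1, 11))
RVM_APM_SIGMA_GRID: tuple[float, ...] = tuple(round(3.0 + 0.1 * i, 1) for i in range(61))
DEFAULT_C_GRID: tuple[float, ...] = (1.0, 2.0, 5.0)
DEFAULT_EPSILON = 0.1


def rmse(predicted, observed) -> float:
    """Root mean square error between two equal-length vectors."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    if predicted.size == 0:
        raise ValueError("RMSE of an empty vector is undefined")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


@dataclass
class CVPlan:
    """Fold assignments and hyperparameter grids for one protocol run.

    ``outer_folds`` partitions the pair indices into three test folds;
    ``inner_folds[f]`` partitions ``range(len(outer training set of f))``
    (positions within the concatenated outer-training index list) into five
    validation folds.
    """

    outer_folds: list[np.ndarray]
    inner_folds: list[list[np.ndarray]]
    seed: int
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    C_grid: tuple[float, ...] = DEFAULT_C_GRID

    def __post_init__(self) -> None:
        for grid in (self.sigma_grid, self.C_grid):
            if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError("grids must be non-empty and strictly increasing")

    def outer_train_indices(self, fold: int) -> np.ndarray:
        return np.concatenate(
            [f for i, f in enumerate(self.outer_folds) if i != fold]
        )


def make_cv_plan(
    n: int,
    seed: int,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    n_outer: int = 3,
    n_inner: int = 5,
) -> CVPlan:
    """Random fold assignment, reproducible under ``seed``.

    Outer folds have sizes differing by at most one, and likewise the inner
    folds within each outer-training set. Needs n >= n_outer * n_inner so no
    inner fold is empty.
    """
    if n < n_outer * n_inner:
        raise ValueError(f"need at least {n_outer * n_inner} pairs, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    outer = [np.sort(f) for f in np.array_split(perm, n_outer)]
    inner: list[list[np.ndarray]] = []
    for fold in range(n_outer):
        m = n - len(outer[fold])
        inner_perm = rng.permutation(m)
        inner.append([np.sort(f) for f in np.array_split(inner_perm, n_inner)])
    return CVPlan(outer, inner, seed, tuple(sigma_grid), tuple(C_grid))


def _fit_model(model_kind: str, X, y, sigma: float, C: float | None, epsilon: float):
    kernel = KernelSpec(sigma=sigma)
    if model_kind == "svr":
        return svr_fit(X, y, C=C, epsilon=epsilon, kernel=kernel)
    if model_kind == "rvm":
        return rvm_fit(X, y, kernel=kernel)
    raise ValueError(f"unknown model kind {model_kind!r}")


def select_sigma(
    X_train: np.ndarray,
    y_train: np.ndarray,
    model_kind: str,
    C: float | None,
    inner_folds: list[np.ndarray],
    sigma_grid: tuple[float, ...],
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Pick the grid sigma minimising mean inner-validation RMSE.

    Ties go to the smallest sigma. Grid values for which training fails on
    any inner fold (for example RVM degeneracy at small sigma) are skipped
    with a logged reason; if every value fails, an error is raised.
    """
    if len(sigma_grid) == 0:
        raise ValueError("empty sigma grid")
    best_sigma = None
    best_score = np.inf
    for sigma in sigma_grid:
        fold_rmses = []
        try:
            for val_idx in inner_folds:
                mask = np.zeros(len(y_train), dtype=bool)
                mask[val_idx] = True
                model = _fit_model(
                    model_kind, X_train[~mask], y_train[~mask], sigma, C, epsilon
                )
                fold_rmses.append(rmse(model.predict(X_train[mask]), y_train[mask]))
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.info("sigma=%g skipped: %s", sigma, exc)
            continue
        score = float(np.mean(fold_rmses))
        if score < best_score - 1e-12:
            best_score = score
            best_sigma = sigma
    if best_sigma is None:
        raise RuntimeError("training failed for every sigma in the grid")
    return best_sigma


@dataclass
class FoldResult:
    """Metrics for one (outer fold, C) cell of the protocol.

    ``C`` is None for the RVM (which has no regularisation constant) and for
    the APM baseline; ``test_predictions`` holds one (pair_key, observed,
    predicted) triple per coverage-kept test pair so that the reported RMSEs
    can be recomputed from the dump.
    """

    fold: int
    C: float | None
    sigma: float | None
    train_rmse: float
    test_rmse: float
    n_kept: int
    n_dropped: int
    test_rmse_unfiltered: float | None = None
    n_vectors: int | None = None  # support / relevance vector count
    test_predictions: list[tuple[tuple[str, str], float, float]] = field(
        default_factory=list
    )


@dataclass
class EvaluationReport:
    """All per-fold results of one protocol run plus the plan that produced them."""

    mapping: str
    model_kind: str
    results: list[FoldResult]
    plan: CVPlan

    def mean_train_rmse(self, C: float | None = None) -> float:
        return float(np.mean([r.train_rmse for r in self._cells(C)]))

    def mean_test_rmse(self, C: float | None = None) -> float:
        return float(np.mean([r.test_rmse for r in self._cells(C)]))

    def _cells(self, C) -> list[FoldResult]:
        cells = [r for r in self.results if C is None or r.C == C]
        if not cells:
            raise ValueError(f"no results for C={C}")
        return cells

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": r.fold,
                "C": r.C,
                "sigma": r.sigma,
                "train_rmse": r.train_rmse,
                "test_rmse": r.test_rmse,
                "test_rmse_unfiltered": r.test_rmse_unfiltered,
                "n_kept": r.n_kept,
                "n_dropped": r.n_dropped,
                "n_vectors": r.n_vectors,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _build_features(pairs, dataset, mapping, k, table):
    return feature_matrix(
        pairs,
        dataset.proteins,
        mapping,
        domain_universe=dataset.domain_universe,
        k=k,
        table=table,
    ).vectors


def run_protocol(
    dataset: PairDataset,
    mapping: str,
    model_kind: str,
    plan: CVPlan | None = None,
    *,
    k: int = 1,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    distinct_domains: bool = False,
    clip: bool = False,
) -> EvaluationReport:
    """Run the full threefold protocol for one (mapping, model) combination.

    ``mapping`` is one of {"dn", "spd", "apm"}; ``model_kind`` one of
    {"svr", "rvm", "apm_baseline"}. Per outer fold: the APM table is built
    from the training pairs only, sigma is selected by inner fivefold CV,
    the model is refit on the full outer-training set, and RMSE is reported
    on the training pairs and on the coverage-filtered test pairs (plus,
    for the DN/SPD mappings, on the unfiltered test pairs, labelled as
    such). For ``apm_baseline`` the combined table score is the prediction
    directly and ``mapping`` is ignored.
    """
    mapping = mapping.lower()
    model_kind = model_kind.lower()
    if model_kind not in ("svr", "rvm", "apm_baseline"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    if mapping not in ("dn", "spd", "apm"):
        raise ValueError(f"unknown mapping {mapping!r}")
    if plan is None:
        sigma_grid = (
            RVM_APM_SIGMA_GRID
            if (model_kind == "rvm" and mapping == "apm")
            else DEFAULT_SIGMA_GRID
        )
        plan = make_cv_plan(len(dataset.pairs), seed, sigma_grid=sigma_grid)
    results: list[FoldResult] = []
    for fold, test_idx in enumerate(plan.outer_folds):
        train_idx = plan.outer_train_indices(fold)
        train_pairs = [dataset.pairs[i] for i in train_idx]
        test_pairs = [dataset.pairs[i] for i in test_idx]
        y_train = np.array([p.strength for p in train_pairs])
        table = apm_scores(dataset.subset(train_idx), distinct_domains=distinct_domains)
        kept, dropped = coverage_filter(test_pairs, table, dataset.proteins)
        if not kept:
            raise RuntimeError(f"fold {fold}: no test pair passes the coverage filter")
        y_kept = np.array([p.strength for p in kept])

        if model_kind == "apm_baseline":
            pred_train = np.array(
                [predict_strength(p, table, dataset.proteins) for p in train_pairs]
            )
            pred_kept = np.array(
                [predict_strength(p, table, dataset.proteins) for p in kept]
            )
            results.append(
                FoldResult(
                    fold=fold,
                    C=None,
                    sigma=None,
                    train_rmse=rmse(pred_train, y_train),
                    test_rmse=rmse(pred_kept, y_kept),
                    n_kept=len(kept),
                    n_dropped=len(dropped),
                    test_predictions=[
                        (p.key, p.strength, float(v)) for p, v in zip(kept, pred_kept)
                    ],
                )
            )
            continue

        X_train = _build_features(train_pairs, dataset, mapping, k, table)
        X_kept = _build_features(kept, dataset, mapping, k, table)
        if mapping == "apm":
            X_test_all, y_test_all = None, None
        else:
            X_test_all = _build_features(test_pairs, dataset, mapping, k, table)
            y_test_all = np.array([p.strength for p in test_pairs])

        C_values: tuple[float | None, ...] = (
            plan.C_grid if model_kind == "svr" else (None,)
        )
        for C in C_values:
            sigma = select_sigma(
                X_train,
                y_train,
                model_kind,
                C,
                plan.inner_folds[fold],
                plan.sigma_grid,
                epsilon,
            )
            model = _fit_model(model_kind, X_train, y_train, sigma, C, epsilon)
            pred_train = model.predict(X_train, clip=clip)
            pred_kept = model.predict(X_kept, clip=clip)
            unfiltered = (
                rmse(model.predict(X_test_all, clip=clip), y_test_all)
                if X_test_all is not None
                else None
            )
            n_vec = model.n_support if model_kind == "svr" else model.n_relevance
            results.append(
                FoldResult(
                    fold=fold,
                    C=C,
                    sigma=sigma,
                    train_rmse=rmse(pred_train, y_train),
                    test_rmse=rmse(pred_kept, y_kept),
                    n_kept=len(kept),
                    n_dropped=len(dropped),
                    test_rmse_unfiltered=unfiltered,
                    n_vectors=n_vec,
                    test_predictions=[
                        (p.key, p.strength, float(v)) for p, v in zip(kept, pred_kept)
                    ],
                )
            )
    return EvaluationReport(mapping, model_kind, results, plan)
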