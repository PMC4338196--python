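"""Fisher linear discriminant diagnostic indices and exhaustive panel search.

A two-class Fisher discriminant on marker log2 signals defines the
diagnostic index::

    index(x) = w . x + b,    w = S_w^{-1} (mu_cancer - mu_control)

with S_w the pooled within-class covariance (denominator n0 + n1 - 2) and
the intercept b = -w . (mu_cancer + mu_control) / 2, placing the cut-point
0 midway between the projected class means (equal priors).  A sample with
index strictly above the cutoff is classified to the cancer side.

``combination_search`` fits and evaluates every non-empty subset of a
marker shortlist (all 2^k - 1 panels) on the training cohort and validates
each on the independent test cohort, reporting per-size accuracy maxima
with ties.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .performance import ConfusionCounts, confusion_metrics, roc_auc
from .types import DiscriminantModel, ExpressionMatrix

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """Raised when a discriminant cannot be fitted (no class separation or
    singular within-class covariance without the ridge fallback)."""


def fit_fisher_lda(
    X: np.ndarray,
    labels: np.ndarray,
    marker_ids: list[str] | None = None,
    ridge: float | None = 1e-6,
    comparison: str = "",
) -> DiscriminantModel:
    """Fit a two-class Fisher linear discriminant.

    Parameters
    ----------
    X
        samples x markers matrix of log2 signals.
    labels
        Binary labels; 1 = cancer side.
    ridge
        If the pooled within-class covariance is singular, add
        ``ridge * mean(diag(S_w)) * I``; ``None`` raises instead.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    if X.ndim == 1:
        X = X[:, None]
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples")
    X1, X0 = X[labels == 1], X[labels == 0]
    mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
    if np.allclose(mu1, mu0):
        raise DegenerateModelError("identical class means: no direction to learn")

    S1 = (X1 - mu1).T @ (X1 - mu1)
    S0 = (X0 - mu0).T @ (X0 - mu0)
    Sw = (S1 + S0) / (n0 + n1 - 2)
    try:
        w = np.linalg.solve(Sw, mu1 - mu0)
    except np.linalg.LinAlgError:
        if ridge is None:
            raise DegenerateModelError(
                "singular within-class covariance; enable the ridge fallback"
            ) from None
        lam = ridge * float(np.trace(Sw)) / Sw.shape[0]
        if lam <= 0:
            lam = ridge
        w = np.linalg.solve(Sw + lam * np.eye(Sw.shape[0]), mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(X.shape[1])]
    return DiscriminantModel(
        marker_ids=list(marker_ids), weights=w, intercept=b, training_comparison=comparison
    )


def apply_index(
    model: DiscriminantModel,
    sample_values,
    cutoff: float = 0.0,
) -> tuple[float, bool]:
    """Diagnostic index and classification of one sample.

    ``sample_values`` maps marker ID -> log2 value (mapping or pandas
    Series).  Classified cancer iff the score strictly exceeds the cutoff;
    a score exactly at the cutoff falls on the non-cancer side (logged).
    """
    try:
        x = np.array([float(sample_values[m]) for m in model.marker_ids])
    except KeyError as exc:
        raise KeyError(f"sample is missing marker {exc.args[0]!r}") from None
    score = float(model.weights @ x + model.intercept)
    if score == cutoff:
        logger.warning("index exactly at cutoff %.3g; classified non-cancer", cutoff)
    return score, score > cutoff


def index_scores(model: DiscriminantModel, matrix: ExpressionMatrix) -> pd.Series:
    """Diagnostic index for every sample of a log2 expression matrix."""
    matrix.require_scale("log2", "diagnostic index")
    missing = [m for m in model.marker_ids if m not in matrix.values.index]
    if missing:
        raise KeyError(f"matrix is missing markers: {missing}")
    X = matrix.values.loc[model.marker_ids].to_numpy().T
    return pd.Series(X @ model.weights + model.intercept, index=matrix.sample_ids)


def enumerate_combinations(marker_ids: list[str], max_k: int = 20) -> list[tuple[str, ...]]:
    """All 2^k - 1 non-empty marker subsets, ordered by size then by the
    shortlist order within each size."""
    k = len(marker_ids)
    if k < 1:
        raise ValueError("shortlist must contain at least one marker")
    if k > max_k:
        raise ValueError(
            f"shortlist of {k} markers would enumerate {2**k - 1} subsets; "
            f"raise max_k explicitly to override"
        )
    subsets: list[tuple[str, ...]] = []
    for size in range(1, k + 1):
        subsets.extend(itertools.combinations(marker_ids, size))
    return subsets


@dataclass
class CombinationResult:
    """One marker panel with its fitted model and cohort performance."""

    model: DiscriminantModel
    n_markers: int
    train_metrics: ConfusionCounts
    test_metrics: ConfusionCounts
    test_auc: float

    @property
    def marker_ids(self) -> list[str]:
        return self.model.marker_ids


def _evaluate(
    model: DiscriminantModel,
    matrix: ExpressionMatrix,
    labels: pd.Series,
    cutoff: float,
) -> tuple[ConfusionCounts, pd.Series]:
    scores = index_scores(model, matrix)
    preds = (scores > cutoff).astype(int)
    aligned = labels.loc[scores.index]
    return confusion_metrics(preds.to_numpy(), aligned.to_numpy()), scores


def combination_search(
    train: ExpressionMatrix,
    train_labels: pd.Series,
    test: ExpressionMatrix,
    test_labels: pd.Series,
    shortlist: list[str],
    config: PipelineConfig | None = None,
) -> tuple[list[CombinationResult], dict[int, list[CombinationResult]], CombinationResult]:
    """Exhaustive diagnostic-panel search over a marker shortlist.

    Fits a Fisher discriminant on the training cohort for every non-empty
    subset, evaluates sensitivity/specificity/accuracy on both cohorts and
    AUC on the test cohort.  Returns ``(all_results, best_per_size, best)``
    where ``best_per_size[k]`` lists every size-k panel attaining the
    maximal test accuracy for that size, and ``best`` is the single best
    panel under the tie-break (highest test accuracy, fewest markers,
    highest test AUC, enumeration order).
    """
    config = config or PipelineConfig()
    train.require_scale("log2", "panel search")
    test.require_scale("log2", "panel search")
    results: list[CombinationResult] = []
    y_tr = train_labels.astype(int)
    y_te = test_labels.astype(int)
    X_full = train.values.loc[shortlist, :].to_numpy().T
    y_arr = y_tr.loc[train.sample_ids].to_numpy()
    pos = {m: i for i, m in enumerate(shortlist)}

    for subset in enumerate_combinations(shortlist):
        cols = [pos[m] for m in subset]
        try:
            model = fit_fisher_lda(
                X_full[:, cols], y_arr, marker_ids=list(subset), ridge=config.lda_ridge
            )
        except DegenerateModelError as exc:
            logger.warning("skipping panel %s: %s", subset, exc)
            continue
        train_cm, _ = _evaluate(model, train, y_tr, config.index_cutoff)
        test_cm, test_scores = _evaluate(model, test, y_te, config.index_cutoff)
        curve = roc_auc(test_scores.to_numpy(), y_te.loc[test_scores.index].to_numpy())
        results.append(
            CombinationResult(
                model=model,
                n_markers=len(subset),
                train_metrics=train_cm,
                test_metrics=test_cm,
                test_auc=curve.auc,
            )
        )

    best_per_size: dict[int, list[CombinationResult]] = {}
    for size in sorted({r.n_markers for r in results}):
        of_size = [r for r in results if r.n_markers == size]
        top = max(r.test_metrics.accuracy for r in of_size)
        best_per_size[size] = [r for r in of_size if r.test_metrics.accuracy == top]

    best = max(
        enumerate(results),
        key=lambda ir: (
            ir[1].test_metrics.accuracy,
            -ir[1].n_markers,
            ir[1].test_auc,
            -ir[0],
        ),
    )[1]
    return results, best_per_size, best


def best_per_size_table(best_per_size: dict[int, list[CombinationResult]]) -> pd.DataFrame:
    """Flatten the per-size maxima (with ties) into a report DataFrame."""
    rows = []
    for size in sorted(best_per_size):
        for r in best_per_size[size]:
            rows.append(
                {
                    "n_markers": size,
                    "markers": ";".join(r.marker_ids),
                    "test_accuracy": r.test_metrics.accuracy,
                    "test_sensitivity": r.test_metrics.sensitivity,
                    "test_specificity": r.test_metrics.specificity,
                    "test_auc": r.test_auc,
                }
            )
    return pd.DataFrame(rows)
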