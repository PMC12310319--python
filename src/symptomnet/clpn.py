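"""Cross-lagged panel network (CLPN) estimation.

Ten separate l1-penalised logistic regressions link the Wave-1 symptom
vector to each Wave-2 symptom.  The penalty is chosen per outcome by
k-fold cross-validation on the binomial deviance, with the
one-standard-error rule by default: lambda_1SE is the largest penalty
whose mean CV deviance is within one standard error of the minimum,
giving the sparser of the near-optimal models.  Reported edge weights
are the raw log-odds coefficients at the selected penalty; the diagonal
of the coefficient matrix holds the autoregressive effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_seed_sequence, seed_record
from ._solver import lambda_grid, lasso_logistic_path, predict_logliks
from .data import BinarySymptomMatrix, CrossLaggedNetwork

__all__ = [
    "CVLassoResult",
    "one_se_index",
    "cv_lasso_logistic",
    "CrossLaggedModel",
    "CLPNResults",
    "fit_clpn",
]


@dataclass
class CVLassoResult:
    """Cross-validated penalised logistic fit for one outcome."""

    lambdas: np.ndarray        # descending grid
    mean_deviance: np.ndarray  # mean held-out deviance per lambda
    se_deviance: np.ndarray    # SE over folds per lambda
    idx_min: int
    idx_1se: int
    coefs_path: np.ndarray     # full-data path (n_lambda, p)
    intercepts_path: np.ndarray
    fold_ids: np.ndarray
    seed: int | None

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[self.idx_min])

    @property
    def lambda_1se(self) -> float:
        return float(self.lambdas[self.idx_1se])

    def coefs_at(self, rule: str = "1se") -> tuple[np.ndarray, float]:
        idx = self.idx_1se if rule == "1se" else self.idx_min
        return self.coefs_path[idx], float(self.intercepts_path[idx])


def one_se_index(mean_dev: np.ndarray, se_dev: np.ndarray) -> tuple[int, int]:
    """(idx_min, idx_1se) for a descending-lambda CV curve.

    idx_min minimises the mean CV deviance (ties toward larger lambda);
    idx_1se is the smallest index — i.e. the largest lambda — whose mean
    deviance is within one SE (taken at the minimum) of the minimum.
    """
    idx_min = int(np.argmin(mean_dev))
    thresh = mean_dev[idx_min] + se_dev[idx_min]
    return idx_min, int(np.flatnonzero(mean_dev <= thresh)[0])


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by outcome; sizes differ by <= 1."""
    n = y.shape[0]
    folds = np.empty(n, dtype=np.int64)
    offset = 0
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size  # keeps overall fold sizes within 1
    return folds


def cv_lasso_logistic(
    y,
    X,
    k_folds: int = 10,
    seed=None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    stratify: bool = True,
    standardize: bool = False,
    max_refolds: int = 10,
) -> CVLassoResult:
    """k-fold cross-validated LASSO logistic regression.

    The lambda grid is computed once on the full data.  Fold deviance
    is the mean per-observation binomial deviance on the held-out fold;
    its SE is the SD of the k fold deviances divided by sqrt(k).  A
    fold whose training outcome is constant triggers a refold with a
    spawned sub-seed (logged via warning).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    n = y.shape[0]
    if n < k_folds:
        raise ValueError("need n >= k_folds")
    if y.min() == y.max():
        raise ValueError("outcome is constant")

    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale

    ss = as_seed_sequence(seed)
    lambdas = lambda_grid(X, y, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)

    folds = None
    for attempt in range(max_refolds):
        rng = np.random.default_rng(ss.spawn(1)[0] if attempt else ss)
        cand = (
            _stratified_folds(y, k_folds, rng)
            if stratify
            else rng.permutation(n) % k_folds
        )
        ok = all(
            y[cand != f].min() != y[cand != f].max() for f in range(k_folds)
        )
        if ok:
            folds = cand
            break
        warnings.warn(
            f"fold assignment produced a constant training outcome; refolding "
            f"(attempt {attempt + 1})",
            RuntimeWarning,
            stacklevel=2,
        )
    if folds is None:
        raise ValueError("could not build folds with non-constant training outcomes")

    fold_dev = np.empty((k_folds, n_lambda))
    for f in range(k_folds):
        tr, te = folds != f, folds == f
        coefs, intercepts, _ = lasso_logistic_path(X[tr], y[tr], lambdas)
        fold_dev[f] = predict_logliks(X[te], y[te], coefs, intercepts)
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(k_folds)

    idx_min, idx_1se = one_se_index(mean_dev, se_dev)

    coefs, intercepts, _ = lasso_logistic_path(X, y, lambdas)
    if standardize:
        intercepts = intercepts - coefs @ (mean / scale)
        coefs = coefs / scale[None, :]
    return CVLassoResult(
        lambdas=lambdas,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        idx_min=idx_min,
        idx_1se=idx_1se,
        coefs_path=coefs,
        intercepts_path=intercepts,
        fold_ids=folds,
        seed=seed_record(seed),
    )


class CrossLaggedModel:
    """CLPN model: Wave-1 items predict each Wave-2 item.

    Parameters
    ----------
    w1, w2 : BinarySymptomMatrix with matched subjects (row-aligned).
    k_folds : CV folds (default 10), stratified by outcome prevalence.
    rule : "1se" (default) or "min" penalty choice.
    standardize : standardise predictors before penalisation (off by
        default; binary predictors).
    """

    def __init__(
        self,
        w1: BinarySymptomMatrix,
        w2: BinarySymptomMatrix,
        k_folds: int = 10,
        rule: str = "1se",
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        stratify: bool = True,
        standardize: bool = False,
    ):
        if w1.values.shape != w2.values.shape:
            raise ValueError("waves must have matched subjects (same shape)")
        if w1.item_labels != w2.item_labels:
            raise ValueError("waves must share item labels")
        if rule not in ("1se", "min"):
            raise ValueError("rule must be '1se' or 'min'")
        self.w1, self.w2 = w1, w2
        self.k_folds = k_folds
        self.rule = rule
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.stratify = stratify
        self.standardize = standardize

    def fit(self, seed=None) -> "CLPNResults":
        p = self.w1.p
        X = self.w1.values.astype(np.float64)
        B = np.zeros((p, p))
        intercepts = np.zeros(p)
        lambda_info: dict[str, dict] = {}
        cv_results: list[CVLassoResult | None] = [None] * p
        ss = as_seed_sequence(seed)
        outcome_seeds = ss.spawn(p)

        for j in range(p):
            y = self.w2.values[:, j].astype(np.float64)
            label = self.w1.item_labels[j]
            if y.min() == y.max():
                warnings.warn(
                    f"Wave-2 outcome {label!r} is constant; zero column",
                    RuntimeWarning,
                    stacklevel=2,
                )
                intercepts[j] = 30.0 if y[0] == 1 else -30.0
                lambda_info[label] = {"lambda_min": None, "lambda_1se": None}
                continue
            cv = cv_lasso_logistic(
                y,
                X,
                k_folds=self.k_folds,
                seed=outcome_seeds[j],
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                stratify=self.stratify,
                standardize=self.standardize,
            )
            cv_results[j] = cv
            coefs, b0 = cv.coefs_at(self.rule)
            B[:, j] = coefs
            intercepts[j] = b0
            lambda_info[label] = {
                "lambda_min": cv.lambda_min,
                "lambda_1se": cv.lambda_1se,
            }

        net = CrossLaggedNetwork(
            coefficients=B,
            intercepts=intercepts,
            item_labels=self.w1.item_labels,
            lambda_info=lambda_info,
            fold_seed=seed_record(seed),
        )
        return CLPNResults(self, net, cv_results)


@dataclass
class CLPNResults:
    """Fitted cross-lagged network with per-outcome CV diagnostics."""

    model: CrossLaggedModel
    network: CrossLaggedNetwork
    cv_results: list = field(repr=False, default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        return self.network.coefficients

    @property
    def autoregressive(self) -> np.ndarray:
        return self.network.autoregressive

    def edge_frame(self) -> pd.DataFrame:
        labels = self.network.item_labels
        p = self.network.p
        rows = []
        for i in range(p):
            for j in range(p):
                w = self.network.coefficients[i, j]
                rows.append(
                    {
                        "from": labels[i],
                        "to": labels[j],
                        "weight": w,
                        "autoregressive": i == j,
                    }
                )
        return pd.DataFrame(rows)

    def centrality(self) -> pd.DataFrame:
        from .centrality import out_in_ei

        return out_in_ei(self.network)

    def summary(self) -> str:
        ef = self.edge_frame()
        cross = ef[~ef.autoregressive & (ef.weight != 0)]
        auto = ef[ef.autoregressive]
        lines = [
            "Cross-lagged panel network (per-outcome CV LASSO logistic)",
            f"  nodes: {self.network.p}   rule: {self.model.rule}   "
            f"folds: {self.model.k_folds}   seed: {self.network.fold_seed}",
            f"  nonzero cross-lagged edges: {len(cross)} / "
            f"{self.network.p * (self.network.p - 1)}",
            "  autoregressive effects:",
        ]
        for _, r in auto.reindex(
            auto.weight.abs().sort_values(ascending=False).index
        ).head(3).iterrows():
            lines.append(f"    {r['from']}: {r.weight:+.3f}")
        lines.append("  strongest cross-lagged effects:")
        for _, r in cross.reindex(
            cross.weight.abs().sort_values(ascending=False).index
        ).head(5).iterrows():
            lines.append(f"    {r['from']}  ->  {r['to']}: {r.weight:+.3f}")
        return "\n".join(lines)


def fit_clpn(
    w1: BinarySymptomMatrix,
    w2: BinarySymptomMatrix,
    seed=None,
    **kwargs,
) -> CrossLaggedNetwork:
    """One-call CLPN estimator returning the directed network."""
    return CrossLaggedModel(w1, w2, **kwargs).fit(seed=seed).network
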