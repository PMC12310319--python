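"""Cross-sectional Ising network estimation (eLasso).

Each node is regressed on all other nodes with l1-penalised logistic
regression along a descending lambda path; per node, the Extended
Bayesian Information Criterion

    EBIC = -2 loglik + k log n + 2 gamma k log p_candidates

selects the penalty (gamma = 0.5 by default, trading sparsity against
fit).  The asymmetric nodewise slopes are then symmetrised: under the
AND rule an edge survives only if both directed coefficients are
nonzero, and its weight is their average; the OR rule keeps edges with
at least one nonzero coefficient (the missing one counted as zero).
Selected intercepts become the node thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import lambda_grid, lasso_logistic_path
from .data import BinarySymptomMatrix, IsingNetwork

__all__ = [
    "LassoPathFit",
    "ebic",
    "nodewise_lasso_path",
    "IsingModel",
    "IsingResults",
    "fit_ising",
    "global_strength",
]


def ebic(loglik: float, k_active: int, n: int, p_candidates: int, gamma: float) -> float:
    """Extended BIC; gamma = 0 reduces to the ordinary BIC."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    penalty = 2.0 * gamma * k_active * np.log(p_candidates) if k_active else 0.0
    return -2.0 * loglik + k_active * np.log(n) + penalty


@dataclass
class LassoPathFit:
    """One nodewise regularisation path with EBIC model selection."""

    lambdas: np.ndarray          # descending grid
    coefs: np.ndarray            # (n_lambda, p_predictors)
    intercepts: np.ndarray
    logliks: np.ndarray
    ebics: np.ndarray
    selected: int                # index into the grid (argmin EBIC)
    gamma: float

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected])

    @property
    def selected_coefs(self) -> np.ndarray:
        return self.coefs[self.selected]

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])


def nodewise_lasso_path(
    y,
    X,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    gamma: float = 0.5,
    standardize: bool = False,
    tol: float = 1e-7,
) -> LassoPathFit:
    """Penalised logistic path for one node, with per-lambda EBIC.

    ``y`` is the node's 0/1 vector, ``X`` the remaining nodes.  The
    intercept is unpenalised.  EBIC ties break toward larger lambda
    (the sparser model).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    n, p_pred = X.shape
    scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    lambdas = lambda_grid(X, y, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    coefs, intercepts, logliks = lasso_logistic_path(X, y, lambdas, tol=tol)
    if standardize:
        # report on the original predictor scale
        intercepts = intercepts - coefs @ (mean / scale)
        coefs = coefs / scale[None, :]
    k = (coefs != 0).sum(axis=1)
    ebics = np.array(
        [ebic(logliks[i], int(k[i]), n, p_pred, gamma) for i in range(len(lambdas))]
    )
    selected = int(np.argmin(ebics))  # argmin returns first (largest lambda) on ties
    return LassoPathFit(lambdas, coefs, intercepts, logliks, ebics, selected, gamma)


class IsingModel:
    """Nodewise-logistic-LASSO Ising model of a binary symptom matrix.

    Parameters
    ----------
    data : BinarySymptomMatrix or array-like / DataFrame of 0/1 values.
    gamma : EBIC hyperparameter (default 0.5).
    rule : "and" (default) or "or" edge symmetrisation rule.
    n_lambda, lambda_min_ratio : penalty-grid geometry.
    standardize : z-score predictors before penalisation (off by
        default: with binary predictors the raw coefficients are
        log-odds per endorsement).
    """

    def __init__(
        self,
        data,
        gamma: float = 0.5,
        rule: str = "and",
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        standardize: bool = False,
        tol: float = 1e-7,
    ):
        if isinstance(data, BinarySymptomMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = BinarySymptomMatrix(
                data.to_numpy(), tuple(map(str, data.columns))
            )
        else:
            arr = np.asarray(data)
            self.data = BinarySymptomMatrix(
                arr, tuple(f"V{i+1}" for i in range(arr.shape[1]))
            )
        if rule not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")
        if self.data.n <= self.data.p:
            raise ValueError("estimation requires n > p rows")
        self.gamma = gamma
        self.rule = rule
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.tol = tol

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IsingModel":
        return cls(df, **kwargs)

    def fit(self) -> "IsingResults":
        m = self.data
        p = m.p
        vals = m.values.astype(np.float64)
        beta = np.zeros((p, p))  # beta[j, i]: slope of predictor i for node j
        thresholds = np.zeros(p)
        node_fits: list[LassoPathFit | None] = [None] * p
        constant_nodes: list[int] = []

        for j in range(p):
            y = vals[:, j]
            if y.min() == y.max():
                constant_nodes.append(j)
                warnings.warn(
                    f"node {m.item_labels[j]!r} is constant; isolated with "
                    "zero edges",
                    RuntimeWarning,
                    stacklevel=2,
                )
                # threshold at +/- inf is truncated to a large log-odds
                thresholds[j] = 30.0 if y[0] == 1 else -30.0
                continue
            others = [i for i in range(p) if i != j]
            fit = nodewise_lasso_path(
                y,
                vals[:, others],
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                gamma=self.gamma,
                standardize=self.standardize,
                tol=self.tol,
            )
            node_fits[j] = fit
            beta[j, others] = fit.selected_coefs
            thresholds[j] = fit.selected_intercept

        W = np.zeros((p, p))
        iu, ju = np.triu_indices(p, k=1)
        for i, j in zip(iu, ju):
            bij, bji = beta[j, i], beta[i, j]
            if self.rule == "and":
                w = 0.5 * (bij + bji) if (bij != 0 and bji != 0) else 0.0
            else:
                w = 0.5 * (bij + bji) if (bij != 0 or bji != 0) else 0.0
            W[i, j] = W[j, i] = w

        net = IsingNetwork(
            weights=W,
            thresholds=thresholds,
            item_labels=m.item_labels,
            estimation_meta={
                "gamma": self.gamma,
                "rule": self.rule,
                "n": m.n,
                "n_lambda": self.n_lambda,
                "lambda_min_ratio": self.lambda_min_ratio,
                "standardize": self.standardize,
                "selected_lambda": [
                    f.selected_lambda if f is not None else None for f in node_fits
                ],
                "constant_nodes": constant_nodes,
            },
        )
        return IsingResults(self, net, node_fits, constant_nodes)


@dataclass
class IsingResults:
    """Fitted Ising network plus per-node selection diagnostics."""

    model: IsingModel
    network: IsingNetwork
    node_fits: list = field(repr=False, default_factory=list)
    constant_nodes: list = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return self.network.weights

    @property
    def thresholds(self) -> np.ndarray:
        return self.network.thresholds

    @property
    def global_strength(self) -> float:
        return global_strength(self.network)

    def edge_frame(self) -> pd.DataFrame:
        """Long-format table of the 45 unique edges."""
        labels = self.network.item_labels
        iu, ju = np.triu_indices(self.network.p, k=1)
        return pd.DataFrame(
            {
                "node1": [labels[i] for i in iu],
                "node2": [labels[j] for j in ju],
                "weight": self.network.weights[iu, ju],
            }
        )

    def centrality(self, metrics=("strength", "expected_influence")) -> pd.DataFrame:
        from .centrality import centrality_table

        return centrality_table(self.network, metrics=metrics)

    def summary(self) -> str:
        net = self.network
        ef = self.edge_frame()
        nz = ef[ef.weight != 0]
        lines = [
            "Ising network (nodewise logistic LASSO, EBIC selection)",
            f"  nodes: {net.p}   n: {net.estimation_meta.get('n')}   "
            f"gamma: {net.estimation_meta.get('gamma')}   "
            f"rule: {net.estimation_meta.get('rule').upper()}",
            f"  nonzero edges: {len(nz)} / {len(ef)}   "
            f"global strength: {self.global_strength:.3f}",
            "",
            "  strongest edges:",
        ]
        top = nz.reindex(nz.weight.abs().sort_values(ascending=False).index).head(5)
        for _, r in top.iterrows():
            lines.append(f"    {r.node1}  --  {r.node2}: {r.weight:+.3f}")
        if self.constant_nodes:
            lines.append(f"  constant nodes isolated: {self.constant_nodes}")
        return "\n".join(lines)


def fit_ising(
    m: BinarySymptomMatrix,
    gamma: float = 0.5,
    rule: str = "and",
    **kwargs,
) -> IsingNetwork:
    """One-call estimator: returns the IsingNetwork (use IsingModel for
    diagnostics and summaries)."""
    return IsingModel(m, gamma=gamma, rule=rule, **kwargs).fit().network


def global_strength(net: IsingNetwork) -> float:
    """Sum of absolute edge weights over the unique (i < j) edges."""
    return float(np.abs(net.edge_vector()).sum())
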