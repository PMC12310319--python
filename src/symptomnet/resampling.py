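"""Bootstrap accuracy and case-dropping stability machinery.

Three procedures, all fully seeded through a SeedSequence hierarchy so
replicates are independent and results do not depend on execution
order:

* nonparametric bootstrap of edge weights (95% CIs and pairwise
  edge-difference tests),
* nonparametric bootstrap of node centrality (pairwise node-difference
  tests),
* case-dropping bootstrap and the correlation-stability (CS)
  coefficient: the largest proportion of cases that can be dropped
  such that, with the requested confidence, the correlation between
  subset and full-sample centrality stays above the threshold
  (conventionally 0.7); CS >= 0.25 is interpretable, CS >= 0.5
  preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_seed_sequence, seed_record

from .centrality import strength
from .data import BinarySymptomMatrix, IsingNetwork

__all__ = [
    "BootstrapEdgeResult",
    "BootstrapCentralityResult",
    "CaseDropResult",
    "bootstrap_edges",
    "bootstrap_centrality_diff",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


def _strength_raw(net: IsingNetwork) -> np.ndarray:
    return strength(net)["raw"].to_numpy()


def _resample_networks(m, estimator, B, seed, replace=True, sizes=None):
    """Common replicate loop; returns list of networks + warning count."""
    ss = as_seed_sequence(seed)
    child = ss.spawn(B)
    nets = []
    n_warn = 0
    for b in range(B):
        rng = np.random.default_rng(child[b])
        if replace:
            idx = rng.integers(0, m.n, size=m.n)
        else:
            idx = rng.choice(m.n, size=sizes, replace=False)
        sub = BinarySymptomMatrix(m.values[idx], m.item_labels, m.wave_tag)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            nets.append(estimator(sub))
        n_warn += sum(issubclass(w.category, RuntimeWarning) for w in caught)
    return nets, n_warn


@dataclass
class BootstrapEdgeResult:
    """Edge-weight bootstrap: observed weights, CIs, difference tests."""

    observed: IsingNetwork
    boot_edges: np.ndarray          # (B, n_edges) upper-triangle weights
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    boot_mean: np.ndarray
    edge_diff_significant: np.ndarray  # (n_edges, n_edges) bool, symmetric
    n_degenerate_replicates: int
    seed: int | None
    alpha: float = 0.05

    @property
    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.observed.p, k=1)


def bootstrap_edges(
    m: BinarySymptomMatrix,
    estimator,
    B: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> BootstrapEdgeResult:
    """Nonparametric bootstrap of the edge weights.

    Rows are resampled with replacement B times and the network
    re-estimated.  CIs are the empirical alpha/2 and 1 - alpha/2
    quantiles.  Two edges differ significantly when the bootstrap CI
    of their difference excludes zero.  Degenerate replicates (a
    constant column isolates a node inside the estimator) are counted,
    never dropped.
    """
    observed = estimator(m)
    iu = np.triu_indices(observed.p, k=1)
    nets, n_warn = _resample_networks(m, estimator, B, seed)
    boot = np.stack([net.weights[iu] for net in nets])  # (B, n_edges)

    lo = np.quantile(boot, alpha / 2, axis=0)
    hi = np.quantile(boot, 1 - alpha / 2, axis=0)

    n_edges = boot.shape[1]
    sig = np.zeros((n_edges, n_edges), dtype=bool)
    for a in range(n_edges):
        diff = boot[:, a : a + 1] - boot[:, a + 1 :]
        dlo = np.quantile(diff, alpha / 2, axis=0)
        dhi = np.quantile(diff, 1 - alpha / 2, axis=0)
        s = (dlo > 0) | (dhi < 0)
        sig[a, a + 1 :] = s
        sig[a + 1 :, a] = s

    return BootstrapEdgeResult(
        observed=observed,
        boot_edges=boot,
        ci_lower=lo,
        ci_upper=hi,
        boot_mean=boot.mean(axis=0),
        edge_diff_significant=sig,
        n_degenerate_replicates=n_warn,
        seed=seed_record(seed),
        alpha=alpha,
    )


@dataclass
class BootstrapCentralityResult:
    """Centrality bootstrap with pairwise node-difference tests."""

    observed: np.ndarray            # (p,) raw centrality
    boot_values: np.ndarray         # (B, p)
    node_diff_significant: np.ndarray  # (p, p) bool, symmetric
    n_degenerate_replicates: int
    seed: int | None
    alpha: float = 0.05


def bootstrap_centrality_diff(
    m: BinarySymptomMatrix,
    estimator,
    B: int = 1000,
    seed=None,
    centrality_fn=_strength_raw,
    alpha: float = 0.05,
) -> BootstrapCentralityResult:
    """Bootstrap pairwise differences in node centrality (same CI
    contract as the edge-difference test)."""
    observed = centrality_fn(estimator(m))
    nets, n_warn = _resample_networks(m, estimator, B, seed)
    boot = np.stack([centrality_fn(net) for net in nets])  # (B, p)

    p = boot.shape[1]
    sig = np.zeros((p, p), dtype=bool)
    for a in range(p):
        diff = boot[:, a : a + 1] - boot[:, a + 1 :]
        dlo = np.quantile(diff, alpha / 2, axis=0)
        dhi = np.quantile(diff, 1 - alpha / 2, axis=0)
        s = (dlo > 0) | (dhi < 0)
        sig[a, a + 1 :] = s
        sig[a + 1 :, a] = s

    return BootstrapCentralityResult(
        observed=observed,
        boot_values=boot,
        node_diff_significant=sig,
        n_degenerate_replicates=n_warn,
        seed=seed_record(seed),
        alpha=alpha,
    )


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap output and the CS coefficient."""

    grid: np.ndarray                     # drop proportions actually used
    correlations: dict = field(repr=False, default_factory=dict)  # q -> (B,)
    cs: float = 0.0
    threshold_r: float = 0.7
    confidence: float = 0.95
    method: str = "pearson"
    skipped: list = field(default_factory=list)
    seed: int | None = None

    def proportion_above(self, q: float) -> float:
        r = self.correlations[q]
        return float(np.mean(r >= self.threshold_r))


def cs_coefficient(
    m: BinarySymptomMatrix,
    estimator,
    centrality_fn=_strength_raw,
    grid=DEFAULT_DROP_GRID,
    B: int = 1000,
    threshold_r: float = 0.7,
    confidence: float = 0.95,
    method: str = "pearson",
    seed=None,
) -> CaseDropResult:
    """Case-dropping bootstrap CS coefficient for a centrality metric.

    For each drop proportion q, B subsamples of size n(1-q) are drawn
    without replacement, the network re-estimated, and the subset
    centrality correlated with the full-sample centrality.
    CS = max{q : fraction of subsamples with r >= threshold_r is at
    least ``confidence``}; 0.0 if no grid point qualifies.
    """
    from scipy.stats import spearmanr

    full = centrality_fn(estimator(m))
    grid = np.asarray(sorted(grid), dtype=np.float64)
    if np.any(grid <= 0) or np.any(grid > 0.75):
        raise ValueError("drop proportions must lie in (0, 0.75]")

    ss = as_seed_sequence(seed)
    q_seeds = ss.spawn(len(grid))
    correlations: dict[float, np.ndarray] = {}
    skipped: list[float] = []
    used: list[float] = []
    for q, q_seed in zip(grid, q_seeds):
        size = int(round(m.n * (1.0 - q)))
        if size <= m.p:
            warnings.warn(
                f"drop proportion {q} leaves only {size} rows; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            skipped.append(float(q))
            continue
        nets, _ = _resample_networks(
            m, estimator, B, q_seed, replace=False, sizes=size
        )
        rs = np.empty(B)
        for b, net in enumerate(nets):
            sub = centrality_fn(net)
            if np.std(sub) == 0 or np.std(full) == 0:
                rs[b] = 0.0
            elif method == "pearson":
                rs[b] = np.corrcoef(full, sub)[0, 1]
            else:
                rs[b] = spearmanr(full, sub).statistic
        correlations[float(q)] = rs
        used.append(float(q))

    cs = 0.0
    for q in used:
        if np.mean(correlations[q] >= threshold_r) >= confidence:
            cs = max(cs, q)
    return CaseDropResult(
        grid=np.asarray(used),
        correlations=correlations,
        cs=cs,
        threshold_r=threshold_r,
        confidence=confidence,
        method=method,
        skipped=skipped,
        seed=seed_record(seed),
    )
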