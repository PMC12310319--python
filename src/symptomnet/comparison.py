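"""Replicability and invariance testing between two networks.

Replicability of two estimated networks over the same node set is
summarised by the phi correlation of their edge-presence indicators and
the Spearman correlation of their edge weights.  Invariance is tested
by permutation on the raw data: the maximum absolute edge-weight
difference M and the global-strength difference dS are recomputed on
label-permuted data to form the null distribution, with the add-one
p-value convention p = (1 + #{perm >= obs}) / (1 + n_perm).

For a two-wave comparison on the same subjects the waves are dependent;
the paired mode therefore swaps each subject's two rows with
probability 1/2 (a within-subject exchangeability null).  The unpaired
mode pools and reshuffles rows, the standard independent-groups test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import as_seed_sequence, seed_record
from scipy.stats import spearmanr

from .data import BinarySymptomMatrix, IsingNetwork
from .ising import fit_ising, global_strength

__all__ = ["ComparisonResult", "edge_replicability", "invariance_test"]


@dataclass
class ComparisonResult:
    """Invariance statistics between two networks."""

    M: float                 # max |e1 - e2| over unique edges
    p_M: float
    S1: float                # global strength, network 1
    S2: float
    delta_S: float           # |S1 - S2|
    p_S: float
    phi: float               # edge-presence phi correlation (nan if undefined)
    rho: float               # edge-weight Spearman correlation
    n_permutations: int
    paired: bool
    seed: int | None
    n_failed_permutations: int = 0


def _phi_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two binary vectors (2x2 phi)."""
    if a.min() == a.max() or b.min() == b.max():
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def edge_replicability(net1: IsingNetwork, net2: IsingNetwork) -> tuple[float, float]:
    """(phi, rho) over the unique edges of two same-labelled networks.

    phi correlates the binary presence indicators (nonzero weight after
    estimation, no epsilon); rho is the Spearman correlation of the
    edge weights.  phi is NaN when either network has all edges present
    or all absent.
    """
    if net1.item_labels != net2.item_labels:
        raise ValueError("networks must share the same node set and order")
    e1, e2 = net1.edge_vector(), net2.edge_vector()
    phi = _phi_binary((e1 != 0).astype(float), (e2 != 0).astype(float))
    if np.all(e1 == e1[0]) or np.all(e2 == e2[0]):
        rho = float("nan")
    else:
        rho = float(spearmanr(e1, e2).statistic)
    return phi, rho


def _stats(net1: IsingNetwork, net2: IsingNetwork) -> tuple[float, float]:
    M = float(np.max(np.abs(net1.edge_vector() - net2.edge_vector())))
    dS = abs(global_strength(net1) - global_strength(net2))
    return M, dS


def invariance_test(
    data1: BinarySymptomMatrix,
    data2: BinarySymptomMatrix,
    estimator=fit_ising,
    n_perm: int = 1000,
    paired: bool = False,
    seed=None,
) -> ComparisonResult:
    """Permutation test of network invariance between two datasets.

    Tests the maximum edge-weight difference M and the global-strength
    difference dS.  ``paired`` requires equal n with row alignment and
    permutes by swapping each subject's two rows with probability 0.5;
    unpaired permutes pooled group labels.  A replicate whose
    estimation fails is re-drawn once, then counted as a failure and
    excluded.
    """
    if data1.item_labels != data2.item_labels:
        raise ValueError("datasets must share the same item set")
    if paired and data1.n != data2.n:
        raise ValueError("paired comparison requires equal n")

    net1, net2 = estimator(data1), estimator(data2)
    M_obs, dS_obs = _stats(net1, net2)
    phi, rho = edge_replicability(net1, net2)

    ss = as_seed_sequence(seed)
    child = iter(ss.spawn(2 * n_perm + 4))
    pooled = np.vstack([data1.values, data2.values])
    n1 = data1.n

    count_M = 0
    count_S = 0
    n_failed = 0
    done = 0
    while done < n_perm:
        stat = None
        for _attempt in range(2):  # one redraw on failure
            rng = np.random.default_rng(next(child))
            if paired:
                swap = rng.random(n1) < 0.5
                v1 = np.where(swap[:, None], data2.values, data1.values)
                v2 = np.where(swap[:, None], data1.values, data2.values)
            else:
                order = rng.permutation(pooled.shape[0])
                v1, v2 = pooled[order[:n1]], pooled[order[n1:]]
            try:
                pn1 = estimator(BinarySymptomMatrix(v1, data1.item_labels, "perm1"))
                pn2 = estimator(BinarySymptomMatrix(v2, data1.item_labels, "perm2"))
                stat = _stats(pn1, pn2)
                break
            except Exception:
                continue
        done += 1
        if stat is None:
            n_failed += 1
            continue
        # >= with a small tolerance so identical-data permutations
        # (all stats exactly 0) count as extreme
        if stat[0] >= M_obs - 1e-12:
            count_M += 1
        if stat[1] >= dS_obs - 1e-12:
            count_S += 1
    if n_failed:
        warnings.warn(
            f"{n_failed} of {n_perm} permutation replicates failed estimation",
            RuntimeWarning,
            stacklevel=2,
        )

    n_eff = n_perm - n_failed
    p_M = (1 + count_M) / (1 + n_eff)
    p_S = (1 + count_S) / (1 + n_eff)
    return ComparisonResult(
        M=M_obs,
        p_M=float(p_M),
        S1=global_strength(net1),
        S2=global_strength(net2),
        delta_S=dS_obs,
        p_S=float(p_S),
        phi=phi,
        rho=rho,
        n_permutations=n_perm,
        paired=paired,
        seed=seed_record(seed),
        n_failed_permutations=n_failed,
    )
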