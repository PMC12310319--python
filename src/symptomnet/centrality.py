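"""Node centrality for undirected Ising and directed cross-lagged networks.

Raw values are reported alongside z-standardised values (population SD,
divisor n), which is the scale on which centrality is usually compared
across nodes.  Closeness and betweenness are exploratory only: they are
unstable in cross-sectional symptom networks and are flagged as such in
the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CrossLaggedNetwork, IsingNetwork

__all__ = [
    "standardize_values",
    "strength",
    "expected_influence",
    "out_in_ei",
    "closeness_betweenness",
    "centrality_table",
]


def standardize_values(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """z-scores with population SD; degenerate (SD = 0) becomes all
    zeros with a flag."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()  # ddof=0
    if sd == 0:
        return np.zeros_like(values), True
    return (values - values.mean()) / sd, False


def _table(labels, metric: str, raw: np.ndarray, exploratory: bool = False) -> pd.DataFrame:
    z, degenerate = standardize_values(raw)
    df = pd.DataFrame(
        {"node": list(labels), "metric": metric, "raw": raw, "z": z}
    )
    df.attrs["degenerate"] = degenerate
    df.attrs["exploratory"] = exploratory
    return df


def strength(net: IsingNetwork) -> pd.DataFrame:
    """Strength: sum of absolute incident edge weights."""
    raw = np.abs(net.weights).sum(axis=1)
    return _table(net.item_labels, "strength", raw)


def expected_influence(net: IsingNetwork) -> pd.DataFrame:
    """One-step expected influence: signed sum of incident edge weights."""
    raw = net.weights.sum(axis=1)
    return _table(net.item_labels, "expected_influence", raw)


def out_in_ei(net: CrossLaggedNetwork, include_loops: bool = False) -> pd.DataFrame:
    """Out- and in-expected influence of a directed network.

    out-EI_i = sum_j B_ij, in-EI_j = sum_i B_ij, excluding the
    autoregressive diagonal by default (out-EI indexes how strongly a
    Wave-1 symptom prospectively predicts the *other* symptoms).
    """
    B = net.coefficients
    if include_loops:
        out_raw = B.sum(axis=1)
        in_raw = B.sum(axis=0)
    else:
        d = np.diag(B)
        out_raw = B.sum(axis=1) - d
        in_raw = B.sum(axis=0) - d
    out_df = _table(net.item_labels, "out_ei", out_raw)
    in_df = _table(net.item_labels, "in_ei", in_raw)
    df = pd.concat([out_df, in_df], ignore_index=True)
    df.attrs["include_loops"] = include_loops
    df.attrs["degenerate"] = out_df.attrs["degenerate"] or in_df.attrs["degenerate"]
    df.attrs["exploratory"] = False
    return df


def closeness_betweenness(net: IsingNetwork) -> pd.DataFrame:
    """Exploratory closeness and betweenness on distances 1/|w|.

    Closeness is 1 / (sum of shortest-path distances to all other
    nodes); on disconnected graphs the harmonic variant (mean of
    inverse distances, unreachable = 0) is used and flagged.
    Betweenness is the standard shortest-path betweenness (normalised).
    """
    import networkx as nx

    p = net.p
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0:
                g.add_edge(i, j, distance=1.0 / abs(w))

    connected = p > 0 and nx.is_connected(g)
    closeness = np.zeros(p)
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    for i in range(p):
        if connected:
            total = sum(lengths[i][j] for j in range(p) if j != i)
            closeness[i] = 1.0 / total if total > 0 else 0.0
        else:
            # harmonic closeness, unreachable nodes contribute 0
            closeness[i] = sum(
                1.0 / d for j, d in lengths[i].items() if j != i and d > 0
            ) / max(p - 1, 1)

    betw = nx.betweenness_centrality(g, weight="distance", normalized=True)
    betweenness = np.array([betw[i] for i in range(p)])

    df_c = _table(net.item_labels, "closeness", closeness, exploratory=True)
    df_b = _table(net.item_labels, "betweenness", betweenness, exploratory=True)
    df = pd.concat([df_c, df_b], ignore_index=True)
    df.attrs["exploratory"] = True
    df.attrs["harmonic_closeness"] = not connected
    df.attrs["degenerate"] = df_c.attrs["degenerate"] or df_b.attrs["degenerate"]
    return df


def centrality_table(
    net: IsingNetwork,
    metrics=("strength", "expected_influence"),
) -> pd.DataFrame:
    """Stacked centrality table for an undirected network."""
    parts = []
    for metric in metrics:
        if metric == "strength":
            parts.append(strength(net))
        elif metric == "expected_influence":
            parts.append(expected_influence(net))
        elif metric in ("closeness", "betweenness"):
            cb = closeness_betweenness(net)
            parts.append(cb[cb.metric == metric].reset_index(drop=True))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return pd.concat(parts, ignore_index=True)
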