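"""Network serialization: CSV adjacency matrix + JSON metadata sidecar.

Floats are written with 17 significant digits so the round trip is exact
for double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CrossLaggedNetwork, IsingNetwork

__all__ = ["write_network", "read_network"]

_FLOAT_FMT = "%.17g"


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    return base.with_suffix(".csv"), base.with_suffix(".json")


def write_network(path, net: IsingNetwork | CrossLaggedNetwork) -> tuple[Path, Path]:
    """Write ``net`` as <path>.csv (adjacency, labelled) + <path>.json."""
    csv_path, json_path = _paths(path)
    labels = list(net.item_labels)
    if isinstance(net, IsingNetwork):
        mat, vec = net.weights, net.thresholds
        meta = {
            "kind": "ising",
            "item_labels": labels,
            "thresholds": [float(v) for v in vec],
            "estimation_meta": net.estimation_meta,
        }
    elif isinstance(net, CrossLaggedNetwork):
        mat, vec = net.coefficients, net.intercepts
        meta = {
            "kind": "clpn",
            "item_labels": labels,
            "intercepts": [float(v) for v in vec],
            "lambda_info": net.lambda_info,
            "fold_seed": net.fold_seed,
        }
    else:
        raise TypeError(f"unsupported network type: {type(net).__name__}")
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        csv_path, float_format=_FLOAT_FMT
    )
    json_path.write_text(json.dumps(meta, indent=2, default=float))
    return csv_path, json_path


def read_network(path) -> IsingNetwork | CrossLaggedNetwork:
    """Read a network written by :func:`write_network`."""
    csv_path, json_path = _paths(path)
    meta = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path, index_col=0, float_precision="round_trip")
    labels = meta["item_labels"]
    if list(df.index) != labels or list(df.columns) != labels:
        raise ValueError("adjacency labels do not match JSON metadata")
    mat = df.to_numpy(dtype=np.float64)
    if meta["kind"] == "ising":
        return IsingNetwork(
            weights=mat,
            thresholds=np.asarray(meta["thresholds"], dtype=np.float64),
            item_labels=tuple(labels),
            estimation_meta=meta.get("estimation_meta", {}),
        )
    if meta["kind"] == "clpn":
        return CrossLaggedNetwork(
            coefficients=mat,
            intercepts=np.asarray(meta["intercepts"], dtype=np.float64),
            item_labels=tuple(labels),
            lambda_info=meta.get("lambda_info", {}),
            fold_seed=meta.get("fold_seed"),
        )
    raise ValueError(f"unknown network kind: {meta['kind']!r}")
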