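"""Domain containers and CESD-10 recoding.

The CESD-10 asks how often each of ten depressive symptoms was felt in
the past week, on a 0-3 Likert scale (0 = rarely ... 3 = most of the
time).  Two positively worded items ("felt hopeful", "felt happy") are
reverse-coded before analysis; every item is then binarised as
0 = rarely vs 1 = at least sometimes, which is the coding the Ising and
cross-lagged network estimators in this package operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CESD10_RAW_LABELS",
    "CESD10_BINARY_LABELS",
    "POSITIVE_ITEMS",
    "SymptomPanel",
    "BinarySymptomMatrix",
    "IsingNetwork",
    "CrossLaggedNetwork",
    "IngestReport",
    "recode_cesd",
    "read_panel_csv",
]

#: CESD-10 item wording as administered (D5/D8 positively worded).
CESD10_RAW_LABELS = (
    "D1: bothered by things",
    "D2: had trouble keeping in mind",
    "D3: felt depressed",
    "D4: everything an effort",
    "D5: felt hopeful",
    "D6: felt fear",
    "D7: sleep was restless",
    "D8: felt happy",
    "D9: felt lonely",
    "D10: could not get going",
)

#: Item wording after reverse coding (negated forms for the two
#: positively worded items).
CESD10_BINARY_LABELS = (
    "D1: bothered by things",
    "D2: had trouble keeping in mind",
    "D3: felt depressed",
    "D4: everything an effort",
    "D5: hopelessness",
    "D6: felt fear",
    "D7: sleep was restless",
    "D8: lack of happiness",
    "D9: felt lonely",
    "D10: could not get going",
)

#: 0-based indices of the reverse-scored (positively worded) items.
POSITIVE_ITEMS = frozenset({4, 7})

_NEGATED = {
    "D5: felt hopeful": "D5: hopelessness",
    "D8: felt happy": "D8: lack of happiness",
}


@dataclass
class IngestReport:
    """Completeness accounting for a CSV ingest."""

    n_read: int
    n_kept: int
    n_dropped: int


@dataclass
class SymptomPanel:
    """Two waves of raw 0-3 Likert responses for the same subjects.

    Rows of ``wave1_raw`` and ``wave2_raw`` are aligned: row i of both
    matrices belongs to ``subject_ids[i]``.
    """

    subject_ids: np.ndarray
    wave1_raw: np.ndarray
    wave2_raw: np.ndarray
    item_labels: tuple = CESD10_RAW_LABELS
    positive_items: frozenset = POSITIVE_ITEMS

    def __post_init__(self):
        self.wave1_raw = np.asarray(self.wave1_raw, dtype=np.int64)
        self.wave2_raw = np.asarray(self.wave2_raw, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        self.item_labels = tuple(self.item_labels)
        if self.wave1_raw.shape != self.wave2_raw.shape:
            raise ValueError("wave matrices must have identical shape")
        if self.wave1_raw.shape[0] != self.subject_ids.shape[0]:
            raise ValueError("subject_ids and wave matrices are not aligned")
        if self.wave1_raw.shape[1] != len(self.item_labels):
            raise ValueError("item_labels does not match column count")
        for name, mat in (("wave1", self.wave1_raw), ("wave2", self.wave2_raw)):
            bad = (mat < 0) | (mat > 3)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"{name} value out of range {{0,1,2,3}} at row {r} "
                    f"(subject {self.subject_ids[r]!r}), "
                    f"column {c} ({self.item_labels[c]!r})"
                )

    @property
    def n(self) -> int:
        return self.wave1_raw.shape[0]

    @property
    def p(self) -> int:
        return self.wave1_raw.shape[1]


@dataclass
class BinarySymptomMatrix:
    """n x p 0/1 endorsement matrix for one wave."""

    values: np.ndarray
    item_labels: tuple = CESD10_BINARY_LABELS
    wave_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        self.item_labels = tuple(self.item_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be 0/1")
        if self.values.shape[1] != len(self.item_labels):
            raise ValueError("item_labels does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_labels))


@dataclass
class IsingNetwork:
    """Undirected Ising network: symmetric signed edge weights plus
    per-node thresholds (tau) on the {0,1} state coding."""

    weights: np.ndarray
    thresholds: np.ndarray
    item_labels: tuple = CESD10_BINARY_LABELS
    estimation_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.item_labels = tuple(self.item_labels)
        p = self.weights.shape[0]
        if self.weights.shape != (p, p):
            raise ValueError("weights must be square")
        if self.thresholds.shape != (p,):
            raise ValueError("thresholds length must match weights")
        if len(self.item_labels) != p:
            raise ValueError("item_labels does not match weights")
        if not np.isfinite(self.weights).all() or not np.isfinite(self.thresholds).all():
            raise ValueError("non-finite network parameters")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("weights must have zero diagonal")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle edge weights in row-major (i < j) order."""
        iu = np.triu_indices(self.p, k=1)
        return self.weights[iu]


@dataclass
class CrossLaggedNetwork:
    """Directed two-wave network: ``coefficients[i, j]`` is the
    log-odds effect of Wave-1 item i on Wave-2 item j; the diagonal
    holds the autoregressive effects."""

    coefficients: np.ndarray
    intercepts: np.ndarray
    item_labels: tuple = CESD10_BINARY_LABELS
    lambda_info: dict = field(default_factory=dict)
    fold_seed: int | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        self.item_labels = tuple(self.item_labels)
        p = self.coefficients.shape[0]
        if self.coefficients.shape != (p, p):
            raise ValueError("coefficients must be square")
        if self.intercepts.shape != (p,):
            raise ValueError("intercepts length must match coefficients")
        if len(self.item_labels) != p:
            raise ValueError("item_labels does not match coefficients")
        if not (
            np.isfinite(self.coefficients).all() and np.isfinite(self.intercepts).all()
        ):
            raise ValueError("non-finite network parameters")

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]

    @property
    def autoregressive(self) -> np.ndarray:
        return np.diag(self.coefficients).copy()


def recode_cesd(panel: SymptomPanel) -> tuple[BinarySymptomMatrix, BinarySymptomMatrix]:
    """Reverse-code the positively worded items and binarise everything.

    Non-positive items: 0 stays 0, any endorsement (1-3) becomes 1.
    Positive items are reversed (3 - r) first, so they become 1 exactly
    when the raw response is <= 2; their labels are renamed to the
    negated wording ("hopelessness", "lack of happiness").
    """
    pos = np.zeros(panel.p, dtype=bool)
    pos[list(panel.positive_items)] = True

    def _binarise(raw: np.ndarray) -> np.ndarray:
        out = (raw >= 1).astype(np.int64)
        out[:, pos] = (raw[:, pos] <= 2).astype(np.int64)
        return out

    labels = tuple(_NEGATED.get(lbl, lbl) for lbl in panel.item_labels)
    w1 = BinarySymptomMatrix(_binarise(panel.wave1_raw), labels, wave_tag="wave1")
    w2 = BinarySymptomMatrix(_binarise(panel.wave2_raw), labels, wave_tag="wave2")
    return w1, w2


def read_panel_csv(path, config: dict) -> tuple[SymptomPanel, IngestReport]:
    """Read a wide two-wave panel CSV into a complete-case SymptomPanel.

    ``config`` keys:

    id_column : str
        Subject identifier column (must be unique).
    wave1_columns, wave2_columns : list of p column names
        Item columns in D1..D10 order for each wave.
    item_labels : optional list of p labels (default CESD-10 wording).
    positive_items : optional iterable of 0-based reverse-scored indices.

    Any cell that is missing or outside {0,1,2,3} marks the row as
    incomplete; incomplete rows are dropped and counted.  Rows are
    ordered by subject id.
    """
    try:
        df = pd.read_csv(path, dtype={config["id_column"]: str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    id_col = config["id_column"]
    w1_cols = list(config["wave1_columns"])
    w2_cols = list(config["wave2_columns"])
    if len(w1_cols) != len(w2_cols):
        raise ValueError("wave1_columns and wave2_columns differ in length")
    missing = [c for c in [id_col, *w1_cols, *w2_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"mapped columns not found in CSV: {missing}")
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate subject id: {dup!r}")

    n_read = len(df)
    item_cols = w1_cols + w2_cols
    vals = df[item_cols].apply(pd.to_numeric, errors="coerce")
    ok = vals.notna().all(axis=1) & vals.isin([0, 1, 2, 3]).all(axis=1)
    kept = df.loc[ok].sort_values(id_col, kind="mergesort")
    vals = vals.loc[kept.index]

    labels = tuple(config.get("item_labels", CESD10_RAW_LABELS[: len(w1_cols)]))
    positive = frozenset(config.get("positive_items", POSITIVE_ITEMS))
    panel = SymptomPanel(
        subject_ids=kept[id_col].to_numpy(),
        wave1_raw=vals[w1_cols].to_numpy(dtype=np.int64),
        wave2_raw=vals[w2_cols].to_numpy(dtype=np.int64),
        item_labels=labels,
        positive_items=positive,
    )
    return panel, IngestReport(n_read=n_read, n_kept=len(kept), n_dropped=n_read - len(kept))
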