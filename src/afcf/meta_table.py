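"""The meta-level feature table: base-classifier votes, continuous scores,
ECG features and expert rhythm labels, one row per ECG record.

This is the substrate of the stacking pipeline: the outputs of the base
AFib detectors are treated as *features* for a meta-level learner.  Three
CSV shapes are supported, matching the shapes a study of this kind
publishes as supplementary data:

* labels file:       ``record_id,label``
* votes file:        ``record_id,<alg1>,...,<algk>`` (categorical calls
  and/or continuous scores, sniffed per column)
* predictions file:  ``record_id,p_afib,predicted_label``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RhythmLabel", "parse_label", "fuse_cinc_labels",
    "MetaTable", "EncodingMap", "encode_votes", "decode_votes",
    "read_labels", "read_votes", "read_predictions", "write_predictions",
    "join_tables",
]


class RhythmLabel(Enum):
    """Closed three-symbol rhythm vocabulary with canonical spellings."""

    AFIB = "AFib"
    NON_AFIB = "non-AFib"
    NOISY = "noisy"

    def __str__(self) -> str:
        return self.value


_LABEL_ALIASES = {
    "afib": RhythmLabel.AFIB,
    "af": RhythmLabel.AFIB,
    "atrial fibrillation": RhythmLabel.AFIB,
    "non-afib": RhythmLabel.NON_AFIB,
    "nonafib": RhythmLabel.NON_AFIB,
    "non_afib": RhythmLabel.NON_AFIB,
    "non afib": RhythmLabel.NON_AFIB,
    "noisy": RhythmLabel.NOISY,
    "noise": RhythmLabel.NOISY,
    "unreadable": RhythmLabel.NOISY,
}


def parse_label(text: str) -> RhythmLabel:
    """Case-insensitive tolerant parse to the canonical vocabulary.

    Single-letter codes ("A", "N") and composites ("N+O", "~") are
    rejected as too ambiguous.
    """
    key = str(text).strip().lower()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise ValueError(f"unrecognized rhythm label {text!r}")


_CINC_MAP = {
    "normal": RhythmLabel.NON_AFIB,
    "other": RhythmLabel.NON_AFIB,
    "afib": RhythmLabel.AFIB,
    "noisy": RhythmLabel.NOISY,
}


def fuse_cinc_labels(symbol: str) -> RhythmLabel:
    """Collapse the 4-symbol CinC vocabulary {Normal, Other, AFib, Noisy}
    to the binary-plus-noisy vocabulary: Normal and Other both become
    non-AFib."""
    key = str(symbol).strip().lower()
    if key not in _CINC_MAP:
        raise ValueError(
            f"unknown CinC rhythm symbol {symbol!r}; "
            "expected one of Normal/Other/AFib/Noisy"
        )
    return _CINC_MAP[key]


# --------------------------------------------------------------------------
# MetaTable

CATEGORICAL = "categorical"
SCORE = "score"        # continuous, constrained to [0, 1]
NUMERIC = "numeric"    # continuous, unconstrained (ECG features)


@dataclass
class MetaTable:
    """Rectangular records x meta-features table with optional labels.

    ``data`` is indexed by unique record_id; ``kinds`` maps each column to
    'categorical' (RhythmLabel votes), 'score' ([0,1] continuous) or
    'numeric'.  ``labels`` is an aligned Series of RhythmLabel or None.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    labels: pd.Series | None = None

    def __post_init__(self):
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate record_id(s): {dup}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate column names in meta table")
        unknown = set(self.data.columns) - set(self.kinds)
        if unknown:
            raise ValueError(f"columns without a declared kind: {sorted(unknown)}")
        for col, kind in self.kinds.items():
            vals = self.data[col]
            if kind == CATEGORICAL:
                bad = [v for v in vals if not isinstance(v, RhythmLabel)]
                if bad:
                    raise ValueError(
                        f"column {col!r}: non-RhythmLabel values {bad[:3]}"
                    )
            elif kind == SCORE:
                arr = vals.to_numpy(dtype=float)
                if np.any(np.isnan(arr)):
                    raise ValueError(f"column {col!r}: missing score values")
                if arr.size and (arr.min() < 0 or arr.max() > 1):
                    raise ValueError(f"column {col!r}: scores outside [0, 1]")
        if self.labels is not None:
            if not self.labels.index.equals(idx):
                raise ValueError("labels index does not match record_ids")

    @property
    def record_ids(self) -> list[str]:
        return [str(r) for r in self.data.index]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, features: list[str]) -> "MetaTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"meta table lacks feature column(s): {missing}")
        return MetaTable(
            self.data[features].copy(),
            {f: self.kinds[f] for f in features},
            self.labels,
        )

    def drop_noisy(self) -> "MetaTable":
        """Remove records labeled noisy, leaving binary AFib/non-AFib labels."""
        if self.labels is None:
            raise ValueError("table has no labels")
        keep = self.labels != RhythmLabel.NOISY
        if not keep.any():
            raise ValueError("no records left after removing noisy labels")
        return MetaTable(
            self.data.loc[keep].copy(), dict(self.kinds), self.labels.loc[keep]
        )

    def binary_y(self) -> np.ndarray:
        """Label vector with AFib = 1; raises if noisy labels remain."""
        if self.labels is None:
            raise ValueError("table has no labels")
        if (self.labels == RhythmLabel.NOISY).any():
            raise ValueError("noisy labels present; call drop_noisy() first")
        return (self.labels == RhythmLabel.AFIB).to_numpy(dtype=int)


# --------------------------------------------------------------------------
# Vote encoding

@dataclass(frozen=True)
class EncodingMap:
    """Deterministic column layout of the encoded design matrix.

    Each categorical vote column expands to the indicator pair
    (is_AFib, is_noisy) — AFib=(1,0), non-AFib=(0,0), noisy=(0,1) — so a
    single-feature split can isolate either class signal.  Continuous
    columns pass through unchanged.
    """

    columns: tuple[str, ...]            # encoded column names, in order
    source: tuple[str, ...]             # source feature per encoded column
    feature_slices: dict[str, list[int]] = field(hash=False)


def encode_votes(table: MetaTable) -> tuple[np.ndarray, EncodingMap]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    sources: list[str] = []
    slices: dict[str, list[int]] = {}
    for feat in table.feature_names:
        kind = table.kinds[feat]
        vals = table.data[feat]
        start = len(names)
        if kind == CATEGORICAL:
            is_af = np.array([v == RhythmLabel.AFIB for v in vals], dtype=float)
            is_noisy = np.array([v == RhythmLabel.NOISY for v in vals], dtype=float)
            cols += [is_af, is_noisy]
            names += [f"{feat}=AFib", f"{feat}=noisy"]
            sources += [feat, feat]
        else:
            arr = vals.to_numpy(dtype=float)
            nan_rows = np.flatnonzero(np.isnan(arr))
            if nan_rows.size:
                rid = table.data.index[nan_rows[0]]
                raise ValueError(
                    f"missing value in column {feat!r} at record {rid!r} "
                    f"({nan_rows.size} missing total); no silent imputation"
                )
            cols.append(arr)
            names.append(feat)
            sources.append(feat)
        slices[feat] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return X, EncodingMap(tuple(names), tuple(sources), slices)


def decode_votes(X: np.ndarray, emap: EncodingMap,
                 kinds: dict[str, str]) -> dict[str, list]:
    """Inverse of encode_votes (used for round-trip checks)."""
    out: dict[str, list] = {}
    for feat, idx in emap.feature_slices.items():
        if kinds[feat] == CATEGORICAL:
            af, noisy = X[:, idx[0]], X[:, idx[1]]
            vals = []
            for a, z in zip(af, noisy):
                if a == 1 and z == 0:
                    vals.append(RhythmLabel.AFIB)
                elif a == 0 and z == 1:
                    vals.append(RhythmLabel.NOISY)
                elif a == 0 and z == 0:
                    vals.append(RhythmLabel.NON_AFIB)
                else:
                    raise ValueError(f"invalid indicator pair ({a}, {z})")
            out[feat] = vals
        else:
            out[feat] = list(X[:, idx[0]])
    return out


# --------------------------------------------------------------------------
# CSV I/O

def _read_indexed_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "record_id":
        logger.warning(
            "%s: first column named %r, mapping by position to record_id",
            path, df.columns[0],
        )
        df = df.rename(columns={df.columns[0]: "record_id"})
    df["record_id"] = df["record_id"].astype(str)
    if df["record_id"].duplicated().any():
        dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
        raise ValueError(f"{path}: duplicate record_id {dup!r}")
    return df.set_index("record_id")


def read_labels(path) -> pd.Series:
    """Labels file ``record_id,label`` -> Series of RhythmLabel."""
    df = _read_indexed_csv(path)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: labels file must have exactly 2 columns")
    col = df.columns[0]
    if col != "label":
        logger.warning("%s: label column named %r, mapping by position", path, col)
    return df[col].map(parse_label)


def read_votes(path) -> MetaTable:
    """Votes/scores file -> unlabeled MetaTable, sniffing each column.

    A column whose values all parse as floats is continuous (a 'score' if
    within [0,1], else 'numeric'); otherwise it must hold rhythm labels.
    """
    df = _read_indexed_csv(path)
    kinds: dict[str, str] = {}
    data = {}
    for col in df.columns:
        vals = df[col]
        try:
            arr = vals.to_numpy(dtype=float)
        except (TypeError, ValueError):
            arr = None
        if arr is not None and not np.any(np.isnan(arr)):
            if arr.min() >= 0 and arr.max() <= 1:
                kinds[col] = SCORE
            else:
                kinds[col] = NUMERIC
            data[col] = arr
        else:
            data[col] = [parse_label(v) for v in vals]
            kinds[col] = CATEGORICAL
    return MetaTable(pd.DataFrame(data, index=df.index), kinds)


def read_predictions(path) -> pd.DataFrame:
    """Predictions file ``record_id,p_afib,predicted_label``."""
    df = _read_indexed_csv(path)
    if "p_afib" not in df.columns:
        logger.warning("%s: no 'p_afib' column, mapping first column by position",
                       path)
        df = df.rename(columns={df.columns[0]: "p_afib"})
    p = df["p_afib"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        bad = df.index[np.flatnonzero((p < 0) | (p > 1))[0]]
        raise ValueError(f"{path}: p_afib outside [0,1] at record {bad!r}")
    if "predicted_label" in df.columns:
        df["predicted_label"] = df["predicted_label"].map(parse_label)
    return df


def write_predictions(path, record_ids, p_afib, predicted_labels) -> None:
    pd.DataFrame(
        {
            "record_id": [str(r) for r in record_ids],
            "p_afib": np.asarray(p_afib, dtype=float),
            "predicted_label": [str(l) for l in predicted_labels],
        }
    ).to_csv(path, index=False)


def join_tables(votes: MetaTable, labels: pd.Series,
                strict: bool = True) -> MetaTable:
    """Attach labels to a votes table on record_id.

    strict: any record present in only one input is an error.  lenient:
    such records are dropped with a logged count.
    """
    v_ids = set(votes.data.index)
    l_ids = set(labels.index)
    only_v, only_l = v_ids - l_ids, l_ids - v_ids
    if only_v or only_l:
        if strict:
            raise ValueError(
                f"record_id mismatch: {len(only_v)} only in votes "
                f"(e.g. {sorted(only_v)[:3]}), {len(only_l)} only in labels "
                f"(e.g. {sorted(only_l)[:3]})"
            )
        logger.warning(
            "lenient join: dropping %d vote-only and %d label-only records",
            len(only_v), len(only_l),
        )
    common = votes.data.index.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no records in common between votes and labels")
    return MetaTable(
        votes.data.loc[common].copy(), dict(votes.kinds), labels.loc[common]
    )
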