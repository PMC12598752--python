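"""Reading, cleaning, normalizing, and padding CF-MS elution matrices.

A co-fractionation MS experiment quantifies each protein across a series of
chromatographic fractions; interacting proteins co-elute and therefore show
correlated intensity profiles.  This module turns raw tabular elution data
into the fixed-shape, row-normalized matrices the downstream classifier
consumes: missing intensities are imputed to zero, proteins never observed
are dropped, each surviving profile is scaled to sum to one, and profiles are
zero-padded on the right to a common length so experiments with different
fraction counts can be modelled together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ElutionMatrix",
    "load_elution",
    "preprocess",
    "pad_profiles",
    "write_elution",
    "ElutionPreprocessor",
]

#: row-sum tolerance for the "normalized" contract
ROW_SUM_TOL = 1e-9


@dataclass
class ElutionMatrix:
    """Proteins x fractions intensity matrix.

    Attributes
    ----------
    protein_ids : list of str
        Row identifiers, unique, in row order.
    values : ndarray of shape (n_proteins, n_columns)
        Non-negative intensities.  NaN marks a missing measurement prior to
        :func:`preprocess`; afterwards no NaN remains.
    original_fractions : int
        Number of measured fractions (columns before any padding).
    normalized : bool
        True once every row sums to 1 over the measured fractions.
    padded_to : int or None
        Total column count after zero-padding, or None if unpadded.
    """

    protein_ids: list[str]
    values: np.ndarray
    original_fractions: int
    normalized: bool = False
    padded_to: int | None = None
    dropped_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elution values must be a 2-D matrix")
        if len(self.protein_ids) != self.values.shape[0]:
            raise ValueError("protein_ids length does not match row count")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids in elution matrix")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]


def load_elution(path) -> ElutionMatrix:
    """Read a tabular elution matrix (TSV or CSV by extension).

    First column holds protein ids; remaining columns are numeric
    intensities, with blank cells parsed as missing (NaN).  Duplicate protein
    ids and non-numeric cells are rejected with informative errors.
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no fraction columns found")
    ids = [str(i) for i in df.index]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValueError(f"{path}: duplicate protein ids: {dup}")
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            text = str(raw).strip()
            if text == "" or text.upper() in {"NA", "NAN"}:
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {text!r} at row {ids[i]!r}, "
                    f"column {col!r}"
                ) from None
    return ElutionMatrix(ids, values, original_fractions=values.shape[1])


def preprocess(E: ElutionMatrix) -> ElutionMatrix:
    """Impute missing to zero, drop all-zero rows, sum-normalize each row.

    Idempotent: reapplying to an already-normalized matrix returns an equal
    matrix.  Raises if no protein survives the all-zero filter.
    """
    if E.padded_to is not None:
        raise ValueError("preprocess must run before padding")
    if E.normalized:
        return E
    values = np.nan_to_num(E.values, nan=0.0)
    if np.any(values < 0):
        raise ValueError("negative intensities in elution matrix")
    sums = values.sum(axis=1)
    keep = sums > 0
    if not np.any(keep):
        raise ValueError("all profiles are zero after imputation")
    dropped = [pid for pid, k in zip(E.protein_ids, keep) if not k]
    values = values[keep] / sums[keep, None]
    return ElutionMatrix(
        [pid for pid, k in zip(E.protein_ids, keep) if k],
        values,
        original_fractions=E.original_fractions,
        normalized=True,
        dropped_ids=list(E.dropped_ids) + dropped,
    )


def pad_profiles(E: ElutionMatrix, target_len: int = 200) -> ElutionMatrix:
    """Zero-pad every profile on the right to ``target_len`` columns.

    Padding is only applied after normalization, so the appended zeros never
    dilute the unit row sums; profiles longer than the target are an error
    (never truncated).
    """
    if not E.normalized:
        raise ValueError("pad_profiles requires a normalized matrix")
    if E.original_fractions > target_len:
        raise ValueError(
            f"profiles have {E.original_fractions} fractions, more than the "
            f"target length {target_len}; refusing to truncate"
        )
    if E.n_columns == target_len:
        return replace(E, padded_to=target_len)
    pad = np.zeros((E.n_proteins, target_len - E.n_columns))
    return replace(
        E,
        values=np.hstack([E.values, pad]),
        padded_to=target_len,
    )


def write_elution(E: ElutionMatrix, path) -> None:
    """Round-trip writer (TSV/CSV by extension); NaN written as blank."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.DataFrame(
        E.values,
        index=E.protein_ids,
        columns=[f"F{i + 1}" for i in range(E.n_columns)],
    )
    df.index.name = "protein_id"
    df.to_csv(path, sep=sep, na_rep="")


class ElutionPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`preprocess` + :func:`pad_profiles`.

    Parameters
    ----------
    target_len : int, default 200
        Common profile length after right zero-padding.
    """

    def __init__(self, target_len: int = 200):
        self.target_len = target_len

    def fit(self, X: ElutionMatrix, y=None):
        self.n_features_in_ = X.n_columns
        return self

    def transform(self, X: ElutionMatrix) -> ElutionMatrix:
        out = preprocess(X) if not X.normalized else X
        return pad_profiles(out, self.target_len)
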