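"""Chaos game representation (FCGR) encoding of protein sequences.

Each protein sequence is mapped to a trajectory in the plane by iterated
contraction toward the vertex of its next residue, and the trajectory is
binned on a square grid to give a fixed-length frequency vector.  The 20
canonical amino acids sit, in alphabetical order, at evenly spaced vertices
of the unit circle starting at angle 0 (counterclockwise).  With resolution
16 the flattened frequency matrix has length 256; the default contraction
factor 0.863271 spreads the attractors so that distinct suffixes land in
distinct grid cells.

Frequency matrices are normalized per protein by the maximum bin count, so
every vector lies in [0, 1] regardless of sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AMINO_ACIDS",
    "VERTICES",
    "cgr_trajectory",
    "fcgr_encode",
    "FCGRMatrix",
    "FCGREncoder",
    "read_fasta",
]

DEFAULT_RESOLUTION = 16
DEFAULT_SCALE = 0.863271

#: canonical amino acids, alphabetical; index = vertex index on the unit circle
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_angles = 2.0 * np.pi * np.arange(20) / 20.0
#: vertex coordinates, shape (20, 2)
VERTICES = np.column_stack([np.cos(_angles), np.sin(_angles)])


def _clean(sequence: str) -> np.ndarray:
    """Indices of canonical residues; non-canonical symbols are dropped."""
    return np.array(
        [_AA_INDEX[ch] for ch in sequence.upper() if ch in _AA_INDEX],
        dtype=np.intp,
    )


def cgr_trajectory(
    sequence: str, scale: float = DEFAULT_SCALE, protein_id: str | None = None
) -> np.ndarray:
    """Chaos-game trajectory of a protein sequence.

    Starting from the origin, each residue moves the point a fraction
    ``scale`` of the way toward that residue's vertex::

        p_k = p_{k-1} + scale * (V(res_k) - p_{k-1})

    Returns an array of shape (n_retained_residues, 2).  Residues outside
    the 20-letter canonical alphabet are dropped first; an empty result is
    an error naming the protein.
    """
    idx = _clean(sequence)
    if idx.size == 0:
        name = protein_id or "<unnamed>"
        raise ValueError(f"sequence of protein {name!r} is empty after "
                         "removing non-canonical residues")
    points = np.empty((idx.size, 2))
    p = np.zeros(2)
    for k, i in enumerate(idx):
        p = p + scale * (VERTICES[i] - p)
        points[k] = p
    return points


def fcgr_encode(
    sequence: str,
    resolution: int = DEFAULT_RESOLUTION,
    scale: float = DEFAULT_SCALE,
    protein_id: str | None = None,
) -> np.ndarray:
    """Flattened frequency-matrix CGR vector of length ``resolution ** 2``.

    Trajectory points are histogrammed on a resolution x resolution grid
    over [-1, 1]^2 (half-open cells, last cell closed), flattened row-major,
    and divided by the maximum bin count so values lie in [0, 1].
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    points = cgr_trajectory(sequence, scale, protein_id=protein_id)
    # np.histogram2d uses half-open bins with the last edge closed, which is
    # exactly the cell convention documented above.
    counts, _, _ = np.histogram2d(
        points[:, 0],
        points[:, 1],
        bins=resolution,
        range=[[-1.0, 1.0], [-1.0, 1.0]],
    )
    flat = counts.ravel()
    return flat / flat.max()


@dataclass
class FCGRMatrix:
    """Stacked FCGR vectors for an ordered protein list."""

    protein_ids: list[str]
    vectors: np.ndarray
    resolution: int = DEFAULT_RESOLUTION
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.protein_ids) != self.vectors.shape[0]:
            raise ValueError("protein_ids length does not match row count")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids in FCGR matrix")
        if self.vectors.shape[1] != self.resolution**2:
            raise ValueError("vector length does not equal resolution**2")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.vectors, index=self.protein_ids).to_csv(path, sep="\t")


def _strip_db_prefix(identifier: str) -> str:
    # UniProt-style headers like "sp|P12345|NAME_HUMAN" -> accession
    if "|" in identifier:
        parts = identifier.split("|")
        if len(parts) >= 2 and parts[0] in {"sp", "tr"}:
            return parts[1]
    return identifier


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by identifier, stripping sp|...|/tr|...| prefixes."""
    return {
        _strip_db_prefix(rec.id): str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


class FCGREncoder(BaseEstimator, TransformerMixin):
    """Transformer from protein sequences to an :class:`FCGRMatrix`.

    Accepts a mapping ``protein_id -> sequence`` (fit stores the id order)
    and produces the stacked, per-protein max-normalized FCGR vectors.
    """

    def __init__(
        self, resolution: int = DEFAULT_RESOLUTION, scale: float = DEFAULT_SCALE
    ):
        self.resolution = resolution
        self.scale = scale

    def fit(self, X: dict[str, str], y=None):
        self.protein_ids_ = list(X)
        return self

    def transform(self, X: dict[str, str]) -> FCGRMatrix:
        ids = list(X)
        vectors = np.stack(
            [
                fcgr_encode(X[pid], self.resolution, self.scale, protein_id=pid)
                for pid in ids
            ]
        )
        return FCGRMatrix(ids, vectors, self.resolution, self.scale)
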