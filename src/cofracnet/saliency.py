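"""Gradient-based input attribution for predicted interactions.

For one scored pair, the saliency profile is the absolute gradient of the
predicted interaction score with respect to the assembled input rows of the
two proteins, averaged over the two — one non-negative value per input
position (200 CF-MS columns followed by 256 sequence columns).  Pairs are
categorized by whether the mean saliency over the un-padded CF-MS region
exceeds the sequence-region mean by more than a margin (default 0.1), and
per-category profiles are superimposed and min-max normalized to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import PairScoringNetwork

__all__ = ["SaliencyProfile", "saliency_map", "categorize", "aggregate"]

CATEGORY_CFMS_GT = "CFMS_gt_SEQ"
CATEGORY_CFMS_LT = "CFMS_lt_SEQ"
CATEGORY_CFMS_SIM = "CFMS_sim_SEQ"


@dataclass
class SaliencyProfile:
    """Per-position attribution for one protein pair."""

    values: np.ndarray
    seq_offset: int = 200
    n_measured_fractions: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("saliency profile must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency profile contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("saliency profile must be non-negative")
        if self.n_measured_fractions is None:
            self.n_measured_fractions = self.seq_offset

    @property
    def cfms_values(self) -> np.ndarray:
        """Un-padded CF-MS region (padded positions are constant zero input)."""
        return self.values[: self.n_measured_fractions]

    @property
    def seq_values(self) -> np.ndarray:
        return self.values[self.seq_offset:]


def saliency_map(
    network: PairScoringNetwork,
    X_static: np.ndarray,
    pair: tuple[int, int],
    n_measured_fractions: int | None = None,
) -> SaliencyProfile:
    """Absolute score gradient w.r.t. the two input rows, averaged."""
    if not network.fitted_:
        raise ValueError("network must be trained before computing saliency")
    gi, gj = network.input_gradient(X_static, pair)
    values = 0.5 * (np.abs(gi) + np.abs(gj))
    return SaliencyProfile(
        values,
        seq_offset=network.seq_offset,
        n_measured_fractions=n_measured_fractions,
    )


def categorize(profile: SaliencyProfile, margin: float = 0.1) -> str:
    """Label a pair by which input region dominates its saliency.

    The profile is first min-max normalized to [0, 1] so the margin is a
    scale-free fraction of the map's dynamic range; the difference of mean
    intensities (un-padded CF-MS minus sequence) must then strictly exceed
    +margin / fall strictly below -margin to leave the "similar" band.
    """
    v = profile.values
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        v = (v - lo) / (hi - lo)
    norm = SaliencyProfile(
        v,
        seq_offset=profile.seq_offset,
        n_measured_fractions=profile.n_measured_fractions,
    )
    diff = float(norm.cfms_values.mean() - norm.seq_values.mean())
    if diff > margin:
        return CATEGORY_CFMS_GT
    if diff < -margin:
        return CATEGORY_CFMS_LT
    return CATEGORY_CFMS_SIM


def aggregate(profiles: list[SaliencyProfile]) -> np.ndarray:
    """Superimpose profiles and min-max normalize the sum to [0, 1]."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    total = np.sum([p.values for p in profiles], axis=0)
    lo, hi = total.min(), total.max()
    if hi == lo:
        warnings.warn("constant aggregated saliency; returning zeros")
        return np.zeros_like(total)
    return (total - lo) / (hi - lo)
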