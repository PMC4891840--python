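"""Pairwise Tanimoto analysis and sphere-exclusion diverse-subset selection.

Compound sets are diversity-reduced before profiling to avoid
chemotype bias: a seed-shuffled leader (sphere-exclusion) pass retains
a molecule only if its Tanimoto similarity to every already-retained
molecule is below the threshold (default 0.65). The selection is
non-deterministic across visit orders, so the order is driven by an
explicit seed; the same seed always reproduces the same subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import Fingerprint

BIN_WIDTH = 0.025
DEFAULT_THRESHOLD = 0.65


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a ∧ b| / |a ∨ b|; defined as 1.0 when both vectors are empty."""
    if a.bits.shape != b.bits.shape:
        raise ValueError("fingerprint length mismatch")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


def _similarity_matrix(fingerprints: list[Fingerprint]) -> np.ndarray:
    """Dense pairwise Tanimoto matrix (float64, diagonal 1)."""
    stack = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)
    inter = stack @ stack.T
    pops = stack.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    return sims


@dataclass
class SimilarityDistribution:
    """Histogram of all pairwise Tanimoto similarities of a set."""

    edges: np.ndarray          # bin edges, width 0.025 over [0, 1]
    counts: np.ndarray
    n_pairs: int
    peak: float                # left edge of the modal bin after smoothing

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_low": self.edges[:-1], "bin_high": self.edges[1:], "count": self.counts,
        })


def pairwise_distribution(fingerprints: list[Fingerprint], smooth_window: int = 3) -> SimilarityDistribution:
    """All-pairs Tanimoto histogram with a moving-average-smoothed peak.

    Bin width 0.025 over [0, 1]; the peak is the left edge of the bin
    maximizing the ``smooth_window``-bin moving average of the counts
    (ties go to the lowest bin). Requires at least two fingerprints.
    """
    n = len(fingerprints)
    if n < 2:
        raise ValueError("pairwise distribution needs at least two fingerprints")
    sims = _similarity_matrix(fingerprints)
    iu = np.triu_indices(n, k=1)
    values = sims[iu]
    edges = np.round(np.arange(0.0, 1.0 + BIN_WIDTH / 2, BIN_WIDTH), 10)
    counts, _ = np.histogram(values, bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    # modal bin of the smoothed counts; ties resolved by raw count, then
    # by the lower bin
    best = np.flatnonzero(smoothed == smoothed.max())
    peak_bin = int(best[np.argmax(counts[best])])
    peak = float(edges[peak_bin])
    return SimilarityDistribution(edges=edges, counts=counts, n_pairs=len(values), peak=peak)


def diverse_subset(
    fingerprints: list[Fingerprint],
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> list[int]:
    """Sphere-exclusion (leader) diverse-subset selection.

    Molecules are visited in a seed-shuffled order and retained only if
    their similarity to every already-retained molecule is strictly
    below ``threshold``. The result (sorted original indices) therefore
    satisfies: (a) no retained pair is similar at or above the
    threshold and (b) every excluded molecule is within the threshold
    of some retained one.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n = len(fingerprints)
    if n == 0:
        return []
    sims = _similarity_matrix(fingerprints)
    order = np.random.default_rng(seed).permutation(n)
    retained: list[int] = []
    for idx in order:
        if all(sims[idx, kept] < threshold for kept in retained):
            retained.append(int(idx))
    return sorted(retained)
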