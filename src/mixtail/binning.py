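"""Dynamic histogram binning for chi-square goodness-of-fit testing.

A chi-square goodness-of-fit test on a histogram is only trustworthy when
every bin holds a minimum number of observations (the classical rule of
thumb is five).  This module builds equal-width histograms whose initial
bin count follows the Mann-Wald rule,

    b = round(1.88 * n**(2/5)),

and then merges sparse bins — starting at the two ends of the range and
moving inward — until every remaining bin holds at least five
observations.  Bin membership is half-open ``[lo, hi)`` with the last bin
closed (numpy's convention); chi-square values downstream depend on this
choice, so it is fixed and documented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "BinningError",
    "DegenerateDistributionError",
    "TooFewSamplesError",
    "SingleBinError",
    "mann_wald_bins",
    "build_histogram",
    "merge_sparse_bins",
    "dynamic_histogram",
    "MIN_BIN_COUNT",
    "MIN_SAMPLES",
]

#: minimum observations per bin required for a valid chi-square test
MIN_BIN_COUNT = 5
#: minimum sample size for which a two-bin compliant histogram can exist
MIN_SAMPLES = 10


class BinningError(ValueError):
    """Base class for histogram-construction failures."""


class DegenerateDistributionError(BinningError):
    """All observations identical — no histogram can be built."""


class TooFewSamplesError(BinningError):
    """Fewer than :data:`MIN_SAMPLES` finite observations."""


class SingleBinError(BinningError):
    """Merging collapsed the histogram to a single bin (uninformative)."""


@dataclass(frozen=True)
class Histogram:
    """Binned representation of a 1-D sample.

    Attributes
    ----------
    edges : ndarray, shape (B + 1,)
        Strictly increasing bin boundaries (log2 expression units).
    counts : ndarray, shape (B,)
        Non-negative observation counts; ``counts.sum() == n``.
    n : int
        Total number of observations.
    b_initial : int
        Mann-Wald bin count before any merging.
    n_relocated : int
        Total count held by initial bins with fewer than five
        observations, i.e. the observations that sparse-bin merging
        combined into larger bins.
    """

    edges: np.ndarray
    counts: np.ndarray
    n: int
    b_initial: int
    n_relocated: int = 0

    @property
    def nbins(self) -> int:
        return len(self.counts)

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n:
            raise BinningError("histogram counts do not sum to n")
        if not np.all(np.diff(self.edges) > 0):
            raise BinningError("histogram edges must be strictly increasing")


def mann_wald_bins(n: int, rounding: str = "round") -> int:
    """Mann-Wald bin count ``b = 1.88 * n**(2/5)``, at least 1.

    Parameters
    ----------
    n : int
        Sample size; must be >= 1.
    rounding : {"round", "floor"}
        The rule is stated for a real-valued ``b``; by default we round
        half-up (which minimises distortion of the target), ``"floor"``
        is available as an escape hatch.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"sample size must be a positive integer, got {n!r}")
    b = 1.88 * float(n) ** 0.4
    if rounding == "round":
        b_int = math.floor(b + 0.5)
    elif rounding == "floor":
        b_int = math.floor(b)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return max(int(b_int), 1)


def build_histogram(values, rounding: str = "round") -> Histogram:
    """Equal-width histogram over ``[min, max]`` with Mann-Wald bin count.

    Non-finite values are dropped.  Raises
    :class:`DegenerateDistributionError` when all values coincide and
    :class:`TooFewSamplesError` below :data:`MIN_SAMPLES` observations.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < MIN_SAMPLES:
        raise TooFewSamplesError(
            f"need at least {MIN_SAMPLES} finite values, got {x.size}"
        )
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0.0:
        raise DegenerateDistributionError("all observations are identical")
    b = mann_wald_bins(x.size, rounding=rounding)
    counts, edges = np.histogram(x, bins=b, range=(lo, hi))
    return Histogram(edges=edges, counts=counts, n=int(x.size), b_initial=b)


def merge_sparse_bins(h: Histogram) -> Histogram:
    """Merge adjacent sparse bins until every bin holds >= 5 observations.

    Merging proceeds from the lowest bin inward, then from the highest
    bin inward, repeating until both end bins are compliant; any interior
    sparse bins are then merged into their smaller neighbour (ties to the
    left).  Total count and the outer edges are conserved; merging an
    already-compliant histogram is the identity.
    """
    if h.n < MIN_SAMPLES:
        raise TooFewSamplesError(
            f"cannot reach two bins of {MIN_BIN_COUNT} with n={h.n}"
        )
    counts = [int(c) for c in h.counts]
    edges = [float(e) for e in h.edges]
    relocated = int(sum(c for c in counts if c < MIN_BIN_COUNT))

    def merge(i: int) -> None:
        # fold bin i+1 into bin i, removing the shared edge
        counts[i] += counts[i + 1]
        del counts[i + 1]
        del edges[i + 1]

    # end-inward passes: low end first, then high end, until stable
    while True:
        moved = False
        while len(counts) > 1 and counts[0] < MIN_BIN_COUNT:
            merge(0)
            moved = True
        while len(counts) > 1 and counts[-1] < MIN_BIN_COUNT:
            merge(len(counts) - 2)
            moved = True
        if not moved:
            break

    # interior sparse bins (present in the initial histogram, not created
    # by end merging): fold into the smaller neighbour, ties to the left
    while len(counts) > 1 and min(counts) < MIN_BIN_COUNT:
        i = next(j for j, c in enumerate(counts) if c < MIN_BIN_COUNT)
        if i == 0:
            merge(0)
        elif i == len(counts) - 1:
            merge(i - 1)
        elif counts[i - 1] <= counts[i + 1]:
            merge(i - 1)
        else:
            merge(i)

    if len(counts) == 1:
        raise SingleBinError("merging collapsed the histogram to one bin")
    return Histogram(
        edges=np.asarray(edges),
        counts=np.asarray(counts, dtype=int),
        n=h.n,
        b_initial=h.b_initial,
        n_relocated=relocated,
    )


def dynamic_histogram(values, rounding: str = "round") -> Histogram:
    """Build and sparse-merge a histogram in one step."""
    return merge_sparse_bins(build_histogram(values, rounding=rounding))
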