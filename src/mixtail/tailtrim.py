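"""Iterative tail trimming: detecting and delimiting non-normal tails.

Gene expression histograms are usually well described, after log2
transformation, by one or two Gaussian components — but a substantial
fraction carry a flat, spread-out run of outliers (a "tail") flanking
the Gaussian bulk.  A plain mixture fit overfits such data: the tail is
absorbed into a spurious wide component.  The remedy implemented here:

1. Fit 1- and 2-component mixtures to the dynamically binned data and
   pick the component count by BIC.
2. If the fit's chi-square goodness of fit is bad
   (``log2(chi2) > threshold``), trim: remove the most extreme point
   from a candidate tail (low or high side), re-bin, refit both
   component counts, and score again — iterating up to a maximum tail
   fraction and covering all four scenarios (1 or 2 components x low or
   high tail).
3. Even when the chi-square passes, a two-component fit may have
   *absorbed* a tail as a spurious minority component: a small
   component (weight <= 1/3, at least 5 points) whose centre lies
   wholly in the bulk component's outlier region (beyond its mean
   +/- 2 sd — where a tail starts by definition) is a tail suspect and
   triggers trimming on that side.
4. At every trimming step the likelihood BIC selects the component
   count (1 vs 2), exactly as at the initial fit.  Across steps and
   sides — where the shrinking sample size makes raw likelihood BICs
   incomparable — the selected models compete on the chi-square form of
   the BIC, ``chi2 + k*ln(n_remaining)``: the best fit that is also the
   least complex model wins; ties break to the lower raw chi-square,
   then fewer points removed.

The default ``log2(chi2)`` threshold 5.52 is the published microarray
reference calibration; it is dataset specific and should be recalibrated
for new data (see :mod:`mixtail.calibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import binning
from .binning import BinningError, dynamic_histogram
from .em import FitError, MixtureFit, NoCrossoverError, categorize, fit_intersection, fit_gaussian_mixture
from .gof import GofError, GofResult, chi_square_gof

__all__ = [
    "DEFAULT_LOG2_CHI2_THRESHOLD",
    "TAIL_SCENARIOS",
    "GeneCategorization",
    "is_tail",
    "trim_iteration",
    "run_itt",
]

#: published reference calibration of the tail-detection threshold
DEFAULT_LOG2_CHI2_THRESHOLD = 5.52

#: the four tail scenarios the search covers: (components, tail side)
TAIL_SCENARIOS = tuple(
    (ncomp, side) for ncomp in (1, 2) for side in ("low", "high")
)

_SIDE_RANK = {"none": 0, "low": 1, "high": 2}


def is_tail(chi2: float, threshold_log2_chi2: float) -> str:
    """Classify a chi-square value as ``'pass'`` or ``'tail'``.

    ``'tail'`` iff ``log2(chi2) > threshold``; the boundary itself
    passes.  A chi-square of zero (perfect fit) always passes.
    """
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if chi2 == 0:
        return "pass"
    return "tail" if np.log2(chi2) > threshold_log2_chi2 else "pass"


@dataclass(frozen=True)
class GeneCategorization:
    """Final per-gene verdict of the tail-trimming pipeline.

    ``labels`` aligns with the (finite) input values: 1 = low group,
    2 = high group; for a plain unimodal gene every label is 1.
    ``cutoffs`` holds 0-2 thresholds: the component intersection for a
    bimodal bulk and/or the tail boundary (the innermost trimmed value).
    """

    pattern: str  # unimodal | bimodal | unimodal+tail | bimodal+tail | degenerate
    cutoffs: tuple
    labels: np.ndarray
    fit: Optional[MixtureFit]
    gof: Optional[GofResult]
    tail_side: Optional[str]
    n_tail: int
    tail_boundary: Optional[float]
    trajectory: Optional[pd.DataFrame]
    threshold_log2_chi2: float
    trimmed_by_itt: bool = False
    notes: tuple = field(default_factory=tuple)

    @property
    def chi2(self) -> float:
        return self.gof.chi2 if self.gof is not None else float("nan")

    @property
    def log2_chi2(self) -> float:
        return self.gof.log2_chi2 if self.gof is not None else float("nan")

    @property
    def bic(self) -> float:
        return self.fit.bic if self.fit is not None else float("nan")


def _fit_and_score(x, seed, em_kwargs):
    """Fit 1- and 2-component mixtures to x and chi-square score both.

    Returns dict mapping component count -> (fit, gof); entries are None
    when binning/fitting/scoring fails for that configuration.
    """
    out = {1: None, 2: None}
    try:
        hist = dynamic_histogram(x)
    except BinningError:
        return out
    for ncomp in (1, 2):
        try:
            fit = fit_gaussian_mixture(x, ncomp, seed=seed, **em_kwargs)
            gof = chi_square_gof(hist, fit)
        except (FitError, GofError):
            continue
        out[ncomp] = (fit, gof)
    return out


#: a minority component is a tail suspect only above this many points
MIN_TAIL_POINTS = 5
#: ... and below this mixture weight (a genuine mode carries more mass)
MAX_TAIL_WEIGHT = 1.0 / 3.0


def tail_suspect_side(fit, n: int):
    """Side of a 2-component fit whose minority component looks like an
    absorbed tail, or None.

    A non-normal tail that EM soaks up into a spurious second component
    leaves a structural signature: a minority component (weight <= 1/3
    but at least :data:`MIN_TAIL_POINTS` points) centred wholly in the
    bulk component's outlier region — beyond its mean +/- 2 sd, which is
    where a tail begins by definition.
    """
    if fit is None or fit.n_components != 2:
        return None
    w = fit.weights
    m = int(np.argmin(w))
    b = 1 - m
    if w[m] > MAX_TAIL_WEIGHT or w[m] * n < MIN_TAIL_POINTS:
        return None
    sd_b = float(np.sqrt(fit.variances[b]))
    if fit.means[m] > fit.means[b] + 2.0 * sd_b:
        return "high"
    if fit.means[m] < fit.means[b] - 2.0 * sd_b:
        return "low"
    return None


def trim_iteration(values, side: str, n_removed: int, seed: int = 0, **em_kwargs):
    """Remove the ``n_removed`` most extreme points on ``side`` and refit.

    Returns ``(trimmed_values, {ncomp: (fit, gof) or None})``.  With
    ``n_removed=0`` this is the untrimmed fit.  Raises ``ValueError``
    when fewer than 10 points would remain.
    """
    if side not in ("low", "high"):
        raise ValueError("side must be 'low' or 'high'")
    x = np.asarray(values, dtype=float).ravel()
    x = np.sort(x[np.isfinite(x)])
    if x.size - n_removed < binning.MIN_SAMPLES:
        raise ValueError("too few points would remain after trimming")
    trimmed = x[n_removed:] if side == "low" else x[: x.size - n_removed]
    return trimmed, _fit_and_score(trimmed, seed, em_kwargs)


def _labels_for(
    n: int,
    order: np.ndarray,
    ncomp: int,
    side: str,
    n_tail: int,
    fit: MixtureFit,
    kept_sorted: np.ndarray,
) -> np.ndarray:
    """Assemble per-sample labels in original input order."""
    labels_sorted = np.empty(n, dtype=int)
    if side == "low":
        tail_slice = slice(0, n_tail)
        main_slice = slice(n_tail, n)
    else:
        tail_slice = slice(n - n_tail, n) if n_tail else slice(n, n)
        main_slice = slice(0, n - n_tail)

    if ncomp == 2:
        main_labels = categorize(kept_sorted, fit)
        labels_sorted[main_slice] = main_labels
        labels_sorted[tail_slice] = 1 if side == "low" else 2
    elif n_tail > 0:
        # unimodal bulk + tail: dichotomize at the tail boundary
        if side == "low":
            labels_sorted[tail_slice] = 1
            labels_sorted[main_slice] = 2
        else:
            labels_sorted[main_slice] = 1
            labels_sorted[tail_slice] = 2
    else:
        labels_sorted[:] = 1

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def run_itt(
    values,
    threshold_log2_chi2: float = DEFAULT_LOG2_CHI2_THRESHOLD,
    seed: int = 0,
    max_tail_fraction: float = 0.25,
    **em_kwargs,
) -> GeneCategorization:
    """Full categorization of one expression vector.

    Parameters
    ----------
    values : array-like
        Finite expression values (log2 scale).  NaNs are rejected here;
        matrix-level callers mask them first.
    threshold_log2_chi2 : float
        Tail-detection threshold on ``log2(chi2)``.
    seed : int
        Seeds every EM restart; the whole run is bit-reproducible.
    max_tail_fraction : float
        Largest fraction of points the trimming search may remove from
        one side (default 0.25, spanning the typical 5-25% tail sizes).
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite; mask missing data upstream")
    n = x.size

    def degenerate(note):
        return GeneCategorization(
            pattern="degenerate",
            cutoffs=(),
            labels=np.ones(n, dtype=int),
            fit=None,
            gof=None,
            tail_side=None,
            n_tail=0,
            tail_boundary=None,
            trajectory=None,
            threshold_log2_chi2=threshold_log2_chi2,
            notes=(note,),
        )

    if n < binning.MIN_SAMPLES:
        return degenerate("fewer than 10 observations")
    if np.ptp(x) <= 1e-12:
        return degenerate("all observations identical")

    order = np.argsort(x, kind="stable")
    x_sorted = x[order]

    initial = _fit_and_score(x_sorted, seed, em_kwargs)
    if initial[1] is None and initial[2] is None:
        return degenerate("initial fit failed")

    # per step the likelihood BIC picks the component count; the chosen
    # models then compete across steps on the penalized chi-square
    # chi2 + k*ln(n') ("lowest chi-square and least complex model")
    candidates = []
    records = []

    def add(side, t, scored):
        rec = {"side": side, "n_removed": t,
               "chi2_1": np.nan, "chi2_2": np.nan,
               "bic_1": np.nan, "bic_2": np.nan}
        usable = []
        for ncomp in (1, 2):
            if scored[ncomp] is None:
                continue
            fit, gof = scored[ncomp]
            rec[f"chi2_{ncomp}"] = gof.chi2
            rec[f"bic_{ncomp}"] = fit.bic
            usable.append((fit, gof))
        records.append(rec)
        if usable:
            fit, gof = min(usable, key=lambda fg: fg[0].bic)
            score = gof.chi2 + fit.k * np.log(fit.n)
            candidates.append(
                (score, gof.chi2, t, _SIDE_RANK[side], fit, gof, side)
            )

    add("none", 0, initial)
    init_fit, init_gof = candidates[0][4], candidates[0][5]

    gated = is_tail(init_gof.chi2, threshold_log2_chi2) == "tail"
    suspect = tail_suspect_side(
        initial[2][0] if initial[2] is not None else None, n
    )
    if gated:
        sides = ("low", "high")
    elif suspect is not None:
        sides = (suspect,)
    else:
        return _assemble(
            x, order, x_sorted, init_fit, init_gof, "none", 0,
            None, threshold_log2_chi2, trimmed=False,
        )

    # exhaustive scan over (side, removals); BIC picks the model per step
    max_removals = int(np.ceil(max_tail_fraction * n))
    for side in sides:
        for t in range(1, max_removals + 1):
            if n - t < binning.MIN_SAMPLES:
                break
            trimmed = x_sorted[t:] if side == "low" else x_sorted[: n - t]
            add(side, t, _fit_and_score(trimmed, seed, em_kwargs))

    trajectory = pd.DataFrame.from_records(records)
    best = min(candidates, key=lambda c: c[:4])
    _, _, t, _, fit, gof, side = best
    return _assemble(
        x, order, x_sorted, fit, gof, side, t, trajectory,
        threshold_log2_chi2, trimmed=True,
    )


def _assemble(
    x, order, x_sorted, fit, gof, side, n_tail, trajectory, threshold,
    trimmed,
):
    n = x.size
    notes = []
    ncomp = fit.n_components
    if side == "none" or n_tail == 0:
        side_out, n_tail, boundary = None, 0, None
        kept = x_sorted
    else:
        side_out = side
        boundary = float(
            x_sorted[n_tail - 1] if side == "low" else x_sorted[n - n_tail]
        )
        kept = x_sorted[n_tail:] if side == "low" else x_sorted[: n - n_tail]

    cutoffs = []
    if ncomp == 2:
        try:
            cutoffs.append(float(fit_intersection(fit)))
        except NoCrossoverError:
            # indistinguishable components: demote to a unimodal verdict
            ncomp = 1
            notes.append("2-component fit had identical components")
    if boundary is not None:
        cutoffs.append(boundary)

    pattern = "unimodal" if ncomp == 1 else "bimodal"
    if n_tail > 0:
        pattern += "+tail"

    labels = _labels_for(
        n, order, ncomp, side or "none", n_tail, fit, kept
    )
    return GeneCategorization(
        pattern=pattern,
        cutoffs=tuple(sorted(cutoffs)),
        labels=labels,
        fit=fit,
        gof=gof,
        tail_side=side_out,
        n_tail=int(n_tail),
        tail_boundary=boundary,
        trajectory=trajectory,
        threshold_log2_chi2=threshold,
        trimmed_by_itt=trimmed,
        notes=tuple(notes),
    )
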