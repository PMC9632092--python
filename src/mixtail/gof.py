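"""Chi-square goodness of fit of a Gaussian mixture to a binned sample.

Expected counts per bin come from the mixture CDF (area under the curve
between bin edges), re-normalized over the histogram range so that the
expected counts sum to n, and the statistic is

    chi2 = sum_i (O_i - E_i)^2 / E_i,      dof = b - 1.

The dof convention is deliberately ``b - 1`` (not the textbook
``b - 1 - n_params``): the statistic is used as a *comparable score*
across trimming iterations rather than as a calibrated test, and the
pipeline's tail threshold is calibrated on the same convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .binning import Histogram
from .em import MixtureFit

__all__ = ["GofResult", "GofError", "chi_square_gof", "qq_coordinates"]

_E_TINY = 1e-9  # expected counts below this are merged into a neighbour


class GofError(ValueError):
    """Chi-square statistic cannot be computed (e.g. a single bin)."""


@dataclass(frozen=True)
class GofResult:
    """Chi-square score of a mixture fit against a histogram."""

    chi2: float
    dof: int
    observed: np.ndarray
    expected: np.ndarray
    edges: np.ndarray

    @property
    def log2_chi2(self) -> float:
        return float(np.log2(self.chi2)) if self.chi2 > 0 else -np.inf


def _expected_counts(h: Histogram, fit: MixtureFit) -> np.ndarray:
    cdf = fit.cdf(np.asarray(h.edges, dtype=float))
    mass = cdf[-1] - cdf[0]
    if mass <= 0:
        raise GofError("mixture has no mass over the histogram range")
    return h.n * np.diff(cdf) / mass


def chi_square_gof(h: Histogram, fit: MixtureFit) -> GofResult:
    """Score ``fit`` against histogram ``h``.

    Bins whose expected count is (numerically) zero are merged into the
    neighbour with the larger expected mass before the statistic is
    computed; a histogram that collapses to a single bin raises
    :class:`GofError` (dof would be 0).
    """
    observed = [float(c) for c in h.counts]
    expected = list(_expected_counts(h, fit))
    edges = [float(e) for e in h.edges]

    i = 0
    while i < len(expected):
        if expected[i] < _E_TINY and len(expected) > 1:
            warnings.warn(
                "merging a zero-expected bin into its neighbour",
                RuntimeWarning,
                stacklevel=2,
            )
            if i == 0:
                j = 1
            elif i == len(expected) - 1:
                j = i - 1
            else:
                j = i - 1 if expected[i - 1] >= expected[i + 1] else i + 1
            lo, hi = min(i, j), max(i, j)
            observed[lo] += observed[hi]
            expected[lo] += expected[hi]
            del observed[hi], expected[hi], edges[hi]
            i = 0
        else:
            i += 1

    if len(observed) < 2:
        raise GofError("fewer than two bins: dof = 0")

    obs = np.asarray(observed)
    exp = np.asarray(expected)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return GofResult(
        chi2=chi2,
        dof=len(obs) - 1,
        observed=obs,
        expected=exp,
        edges=np.asarray(edges),
    )


def qq_coordinates(values, mean: float, variance: float):
    """Theoretical vs sample quantile pairs for a Q-Q diagnostic plot.

    ``values`` are the points assigned to one fitted component; the
    theoretical quantiles come from N(mean, variance) at plotting
    positions ``(i - 0.5)/n``.  Purely diagnostic — no statistic is
    attached.  Fewer than 3 points yields empty output.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    x = x[np.isfinite(x)]
    n = x.size
    if n < 3:
        return np.empty(0), np.empty(0)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theoretical = mean + np.sqrt(variance) * ndtri(probs)
    return theoretical, x


def qq_by_component(values, fit: MixtureFit):
    """Q-Q coordinate pairs for each component of ``fit``.

    Points are assigned to components by maximum posterior; returns a
    list of (theoretical, sample) pairs, one entry per component.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if fit.n_components == 1:
        groups = [x]
    else:
        lab = np.argmax(fit.posteriors(x), axis=1)
        groups = [x[lab == g] for g in range(fit.n_components)]
    return [
        qq_coordinates(g, fit.means[i], fit.variances[i])
        for i, g in enumerate(groups)
    ]
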