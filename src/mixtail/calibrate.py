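"""Data-driven calibration of the pipeline's two detection thresholds.

Both thresholds are *dataset specific* and must be re-estimated whenever
the input panel changes:

* **Tail-detection threshold** — the distribution of ``log2(chi2)``
  values over all bimodally fitted genes is itself bimodal: a lower mode
  of well-fitted genes and an upper mode of genes whose mixture fit was
  degraded by a non-normal tail.  The threshold is set ``z`` standard
  deviations below the upper mode's mean (``z = 1.96`` keeps the false
  negative rate for tail detection near 5%).

* **Background-noise threshold** — on fluorescence platforms the pooled
  distribution of *all* measurements mixes a background-noise component
  with genuinely expressed signal.  A two-component fit to the pooled
  values yields (a) the component intersection, the break-even point
  between background and signal, and (b) ``mu_bg + 2*sigma_bg``, a
  stricter bound excluding ~95% of background draws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .em import fit_intersection, select_components
from .tailtrim import DEFAULT_LOG2_CHI2_THRESHOLD

__all__ = [
    "CalibratedThresholds",
    "calibrate_chi2_threshold",
    "calibrate_background",
    "chi2_threshold_from_moments",
    "two_sigma_from_moments",
]

MIN_CALIBRATION_VALUES = 50


def chi2_threshold_from_moments(mu_upper: float, sd_upper: float,
                                z: float = 1.96) -> float:
    """Tail threshold from the upper chi-square mode: ``mu - z*sd``.

    ``z = 1.96`` targets a ~5% false-negative rate for tail detection.
    """
    return mu_upper - z * sd_upper


def two_sigma_from_moments(mu_bg: float, sd_bg: float) -> float:
    """Strict background bound ``mu + 2*sd`` (excludes ~95% of noise)."""
    return mu_bg + 2.0 * sd_bg


@dataclass
class CalibratedThresholds:
    """Thresholds consumed by the downstream categorization stages."""

    chi2_log2_threshold: Optional[float] = None
    background_intersection: Optional[float] = None
    background_two_sigma: Optional[float] = None
    background_mean: Optional[float] = None
    background_sd: Optional[float] = None
    background_bimodal: bool = True

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibratedThresholds":
        with open(path) as fh:
            return cls(**json.load(fh))


def calibrate_chi2_threshold(
    chi2_values,
    z: float = 1.96,
    seed: int = 0,
    fallback: float = DEFAULT_LOG2_CHI2_THRESHOLD,
    **fit_kwargs,
) -> float:
    """Tail-detection threshold from bimodal genes' chi-square values.

    Log2-transforms the chi-square values, fits a two-component mixture,
    and returns ``mu_upper - z * sigma_upper``.  If the pooled values are
    not bimodal (BIC prefers one component) the configured ``fallback``
    is returned with a warning.
    """
    x = np.asarray(chi2_values, dtype=float).ravel()
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < MIN_CALIBRATION_VALUES:
        raise ValueError(
            f"need >= {MIN_CALIBRATION_VALUES} chi-square values, got {x.size}"
        )
    logx = np.log2(x)
    best, _, fit2 = select_components(logx, seed=seed, **fit_kwargs)
    if best.n_components == 1:
        warnings.warn(
            "chi-square pool not bimodal; falling back to default threshold",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(fallback)
    mu_upper = float(fit2.means[1])
    sd_upper = float(np.sqrt(fit2.variances[1]))
    return chi2_threshold_from_moments(mu_upper, sd_upper, z)


def calibrate_background(
    all_values,
    subsample: int = 100_000,
    seed: int = 0,
    **fit_kwargs,
) -> CalibratedThresholds:
    """Background thresholds from the pooled expression distribution.

    ``all_values`` is the pool of every probe x sample measurement on
    the log2 scale (optionally subsampled for tractability, seeded).  If
    the pooled distribution is unimodal no background threshold exists;
    the result is flagged (``background_bimodal=False``) and downstream
    stages proceed without a background category.
    """
    x = np.asarray(all_values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < MIN_CALIBRATION_VALUES:
        raise ValueError("too few pooled values for background calibration")
    if x.size > subsample:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=subsample, replace=False)

    best, _, fit2 = select_components(x, seed=seed, **fit_kwargs)
    if best.n_components == 1:
        warnings.warn(
            "pooled distribution is unimodal; no background threshold",
            RuntimeWarning,
            stacklevel=2,
        )
        return CalibratedThresholds(background_bimodal=False)

    mu_bg = float(fit2.means[0])
    sd_bg = float(np.sqrt(fit2.variances[0]))
    return CalibratedThresholds(
        background_intersection=float(fit_intersection(fit2)),
        background_two_sigma=two_sigma_from_moments(mu_bg, sd_bg),
        background_mean=mu_bg,
        background_sd=sd_bg,
        background_bimodal=True,
    )
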