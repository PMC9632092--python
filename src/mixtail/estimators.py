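"""Scikit-learn style estimators wrapping the categorization pipeline.

These classes follow the sklearn contract — ``fit`` / ``transform`` /
``predict``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore — so they compose with sklearn pipelines and model
selection.  The module-level functions in :mod:`mixtail.tailtrim`,
:mod:`mixtail.calibrate` and :mod:`mixtail.probes` remain the underlying
engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import probes as _probes
from .calibrate import calibrate_background
from .tailtrim import DEFAULT_LOG2_CHI2_THRESHOLD, run_itt

__all__ = [
    "TailTrimmedGaussianMixture",
    "ExpressionCategorizer",
    "BackgroundThreshold",
    "ProbeFilter",
    "ProbeCombiner",
]


def _as_1d(X):
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise ValueError("expected a single feature column")
        x = x[:, 0]
    elif x.ndim != 1:
        raise ValueError("expected a 1-D sample or an (n, 1) array")
    return x


class TailTrimmedGaussianMixture(BaseEstimator):
    """Categorize one expression vector: mixture fit + tail trimming.

    Fits 1- and 2-component Gaussian mixtures on dynamically binned
    data, detects a non-normal tail via the chi-square criterion, and if
    present locates its boundary by iterative tail trimming.

    Parameters
    ----------
    threshold_log2_chi2 : float
        Tail-detection threshold on log2 of the goodness-of-fit
        chi-square (dataset specific; see :mod:`mixtail.calibrate`).
    max_tail_fraction : float
        Largest fraction of points the trimming search may remove.
    random_state : int
        Seeds every EM restart.

    Attributes
    ----------
    pattern_ : str
        ``unimodal | bimodal | unimodal+tail | bimodal+tail | degenerate``.
    cutoffs_ : tuple of float
        0-2 dichotomization thresholds (component intersection and/or
        tail boundary).
    labels_ : ndarray
        Per-sample labels (1 low / 2 high) for the training values.
    means_, variances_, weights_ : ndarray
        Final mixture parameters.
    chi2_, bic_ : float
        Goodness of fit and BIC of the final model.
    result_ : GeneCategorization
        The full verdict, including the trimming trajectory.
    """

    def __init__(
        self,
        threshold_log2_chi2: float = DEFAULT_LOG2_CHI2_THRESHOLD,
        max_tail_fraction: float = 0.25,
        n_init: int = 5,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.threshold_log2_chi2 = threshold_log2_chi2
        self.max_tail_fraction = max_tail_fraction
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        x = _as_1d(X)
        x = x[np.isfinite(x)]
        self.result_ = run_itt(
            x,
            threshold_log2_chi2=self.threshold_log2_chi2,
            seed=self.random_state,
            max_tail_fraction=self.max_tail_fraction,
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        r = self.result_
        self.pattern_ = r.pattern
        self.cutoffs_ = r.cutoffs
        self.labels_ = r.labels
        if r.fit is not None:
            self.means_ = r.fit.means
            self.variances_ = r.fit.variances
            self.weights_ = r.fit.weights
            self.bic_ = r.fit.bic
        else:
            self.means_ = self.variances_ = self.weights_ = np.empty(0)
            self.bic_ = float("nan")
        self.chi2_ = r.chi2
        return self

    def predict(self, X):
        """Label new values by the fitted cutoffs (1 low ... high).

        Threshold-based assignment agrees with the posterior-based
        training labels except within numerical tolerance of the
        crossover point.
        """
        if not hasattr(self, "result_"):
            raise AttributeError("fit the estimator first")
        x = _as_1d(X)
        out = np.ones(x.size, dtype=float)
        for cut in self.cutoffs_:
            out += (x > cut).astype(float)
        # patterns with two cutoffs still dichotomize into at most the
        # component labels; clip to the label range seen in training
        if self.pattern_ != "degenerate" and len(self.cutoffs_):
            out = np.clip(out, 1, self.labels_.max())
        out[~np.isfinite(x)] = np.nan
        return out


class ExpressionCategorizer(TransformerMixin, BaseEstimator):
    """Column-wise categorization of a samples x genes matrix.

    ``fit`` runs the tail-trimming pipeline on every gene (column);
    ``transform`` returns the per-sample labels.  With a background
    threshold supplied, tail-free unimodal genes that straddle it are
    dichotomized at the threshold ("categorical unimodal"), and samples
    of bimodal genes that fall below it are demoted to a background
    level 1 (making the gene three-level: 1 background, 2 low, 3 high).

    Attributes
    ----------
    categorizations_ : dict of column -> GeneCategorization
    labels_ : DataFrame, samples x genes (float; NaN for missing)
    summary_ : DataFrame, one row per gene (pattern, cutoffs, fit stats)
    """

    def __init__(
        self,
        threshold_log2_chi2: float = DEFAULT_LOG2_CHI2_THRESHOLD,
        max_tail_fraction: float = 0.25,
        background_two_sigma: float | None = None,
        random_state: int = 0,
    ):
        self.threshold_log2_chi2 = threshold_log2_chi2
        self.max_tail_fraction = max_tail_fraction
        self.background_two_sigma = background_two_sigma
        self.random_state = random_state

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.categorizations_ = {}
        labels = pd.DataFrame(
            np.nan, index=df.index, columns=df.columns, dtype=float
        )
        rows = []
        bg = self.background_two_sigma
        for col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            mask = np.isfinite(vals)
            cat = run_itt(
                vals[mask],
                threshold_log2_chi2=self.threshold_log2_chi2,
                seed=self.random_state,
                max_tail_fraction=self.max_tail_fraction,
            )
            self.categorizations_[col] = cat
            col_labels = np.asarray(cat.labels, dtype=float)
            categorical = False
            if bg is not None and cat.pattern == "unimodal":
                categorical = _probes.categorical_unimodal(
                    vals[mask], cat.pattern, bg
                )
                if categorical:
                    col_labels = _probes.dichotomize_at(vals[mask], bg)
            elif bg is not None and cat.pattern.startswith("bimodal"):
                below = vals[mask] <= bg
                col_labels = np.where(below, 1.0, col_labels + 1.0)
            labels.loc[mask, col] = col_labels
            rows.append(
                {
                    "feature": col,
                    "pattern": cat.pattern,
                    "categorical_unimodal": categorical,
                    "n": int(mask.sum()),
                    "n_missing": int((~mask).sum()),
                    "cutoffs": ";".join(f"{c:.6g}" for c in cat.cutoffs),
                    "tail_side": cat.tail_side or "",
                    "n_tail": cat.n_tail,
                    "chi2": cat.chi2,
                    "log2_chi2": cat.log2_chi2,
                    "bic": cat.bic,
                    "means": ";".join(
                        f"{m:.6g}" for m in (cat.fit.means if cat.fit else [])
                    ),
                    "variances": ";".join(
                        f"{v:.6g}"
                        for v in (cat.fit.variances if cat.fit else [])
                    ),
                    "weights": ";".join(
                        f"{w:.6g}" for w in (cat.fit.weights if cat.fit else [])
                    ),
                }
            )
        self.labels_ = labels
        self.summary_ = pd.DataFrame(rows)
        return self

    def transform(self, X):
        """Per-sample labels for ``X`` (training labels when ``X`` is the
        fitted matrix; otherwise cutoff-based assignment per gene)."""
        if not hasattr(self, "labels_"):
            raise AttributeError("fit the transformer first")
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if df.shape == self.labels_.shape and list(df.columns) == list(
            self.labels_.columns
        ):
            return self.labels_.copy()
        out = pd.DataFrame(
            np.nan, index=df.index, columns=df.columns, dtype=float
        )
        for col in df.columns:
            cat = self.categorizations_.get(col)
            if cat is None:
                continue
            x = df[col].to_numpy(dtype=float)
            lab = np.ones(x.size, dtype=float)
            for cut in cat.cutoffs:
                lab += (x > cut).astype(float)
            lab = np.minimum(lab, max(cat.labels.max(), 1))
            lab[~np.isfinite(x)] = np.nan
            out[col] = lab
        return out


class BackgroundThreshold(BaseEstimator):
    """Estimate the background-noise expression threshold.

    Fits a two-component mixture to the pooled values of an entire
    matrix; the component intersection separates background fluorescence
    from genuine signal and ``mean + 2*sd`` of the background component
    gives a stricter cut.

    Attributes: ``intersection_``, ``two_sigma_``, ``mean_``, ``sd_``,
    ``bimodal_`` (False when the pool is unimodal and no background
    threshold exists).
    """

    def __init__(self, subsample: int = 100_000, random_state: int = 0):
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y=None):
        vals = (
            X.to_numpy(dtype=float).ravel()
            if isinstance(X, pd.DataFrame)
            else np.asarray(X, dtype=float).ravel()
        )
        thr = calibrate_background(
            vals, subsample=self.subsample, seed=self.random_state
        )
        self.thresholds_ = thr
        self.bimodal_ = thr.background_bimodal
        self.intersection_ = thr.background_intersection
        self.two_sigma_ = thr.background_two_sigma
        self.mean_ = thr.background_mean
        self.sd_ = thr.background_sd
        return self


class ProbeFilter(TransformerMixin, BaseEstimator):
    """Drop probes with no convincing expression above background."""

    def __init__(
        self,
        background_two_sigma: float,
        min_expr_fraction: float = 0.05,
        var_range_fraction: float = 0.025,
    ):
        self.background_two_sigma = background_two_sigma
        self.min_expr_fraction = min_expr_fraction
        self.var_range_fraction = var_range_fraction

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        kept, report = _probes.probe_filter(
            df,
            self.background_two_sigma,
            min_expr_fraction=self.min_expr_fraction,
            var_range_fraction=self.var_range_fraction,
        )
        self.keep_ = kept.columns
        self.report_ = report
        return self

    def transform(self, X):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        return df.loc[:, self.keep_]


class ProbeCombiner(TransformerMixin, BaseEstimator):
    """Merge same-gene probe sets into inverse-chi-square weighted genes."""

    def __init__(
        self,
        probe_to_gene,
        per_probe_chi2,
        r_threshold: float = _probes.DEFAULT_R_THRESHOLD,
    ):
        self.probe_to_gene = probe_to_gene
        self.per_probe_chi2 = per_probe_chi2
        self.r_threshold = r_threshold

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        combined, report = _probes.combine_probes(
            df,
            self.probe_to_gene,
            self.per_probe_chi2,
            r_threshold=self.r_threshold,
        )
        self.report_ = report
        self.output_features_ = combined.columns
        self._combined = combined
        return self

    def transform(self, X):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        combined, _ = _probes.combine_probes(
            df,
            self.probe_to_gene,
            self.per_probe_chi2,
            r_threshold=self.r_threshold,
        )
        return combined
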