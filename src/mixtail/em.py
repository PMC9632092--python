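"""Univariate Gaussian mixture fitting by expectation-maximization.

One- or two-component mixtures with free weights, means and variances.
The one-component "fit" is the closed-form maximum-likelihood Gaussian.
The two-component fit runs EM from several deterministic quantile-split
initializations plus seeded random restarts and keeps the best
log-likelihood, so fits are bit-reproducible for a fixed seed.

Model selection between one and two components uses the Bayesian
Information Criterion, BIC = k*ln(n) - 2*lnL with k = 2 free parameters
for one component (mu, sigma^2) and k = 5 for two (two means, two
variances, one weight); the lower BIC wins.

The EM inner loop is a scalar-math routine that numba JIT-compiles when
available; without numba the identical Python function runs (slower but
exact in behaviour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "MixtureFit",
    "FitError",
    "NoCrossoverError",
    "fit_gaussian_mixture",
    "select_components",
    "intersection",
    "categorize",
    "VAR_FLOOR",
]

#: variance floor (log2 units squared) preventing component collapse
VAR_FLOOR = 1e-4


class FitError(RuntimeError):
    """EM failed to produce a usable fit."""


class NoCrossoverError(ValueError):
    """The two components are identical — no density crossover exists."""


def _em2_core(x, w, mu, var, var_floor, tol, max_iter):
    """EM for a 2-component univariate Gaussian mixture (in place style).

    Returns (w, mu, var, loglik, converged_flag).  Written with scalar
    loops so numba can compile it; log-space responsibilities keep far
    outliers from underflowing to zero density.
    """
    n = x.shape[0]
    ll_old = -1.0e300
    ll = ll_old
    converged = False
    for _ in range(max_iter):
        lc0 = math.log(w[0]) - 0.5 * math.log(2.0 * math.pi * var[0])
        lc1 = math.log(w[1]) - 0.5 * math.log(2.0 * math.pi * var[1])
        s0 = 0.0
        sx0 = 0.0
        sxx0 = 0.0
        s1 = 0.0
        sx1 = 0.0
        sxx1 = 0.0
        ll = 0.0
        for i in range(n):
            d0 = x[i] - mu[0]
            d1 = x[i] - mu[1]
            l0 = lc0 - 0.5 * d0 * d0 / var[0]
            l1 = lc1 - 0.5 * d1 * d1 / var[1]
            m = l0 if l0 > l1 else l1
            t = math.exp(l0 - m) + math.exp(l1 - m)
            lse = m + math.log(t)
            ll += lse
            g0 = math.exp(l0 - lse)
            g1 = 1.0 - g0
            s0 += g0
            sx0 += g0 * x[i]
            sxx0 += g0 * x[i] * x[i]
            s1 += g1
            sx1 += g1 * x[i]
            sxx1 += g1 * x[i] * x[i]
        if s0 > 1e-10:
            mu[0] = sx0 / s0
            v0 = sxx0 / s0 - mu[0] * mu[0]
            var[0] = v0 if v0 > var_floor else var_floor
            w[0] = s0 / n
        if s1 > 1e-10:
            mu[1] = sx1 / s1
            v1 = sxx1 / s1 - mu[1] * mu[1]
            var[1] = v1 if v1 > var_floor else var_floor
            w[1] = s1 / n
        tot = w[0] + w[1]
        w[0] /= tot
        w[1] /= tot
        if abs(ll - ll_old) < tol * (abs(ll) + 1e-12):
            converged = True
            break
        ll_old = ll
    return w, mu, var, ll, converged


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _em2_core = njit(cache=False)(_em2_core)
except Exception:  # numba genuinely optional
    pass


@dataclass(frozen=True)
class MixtureFit:
    """A converged 1- or 2-component univariate Gaussian mixture.

    Components are ordered by ascending mean.  ``weights`` sum to 1 and
    every variance respects the configured floor.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n: int
    converged: bool = True

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def k(self) -> int:
        """Free-parameter count: 2 for one component, 5 for two."""
        return 2 if self.n_components == 1 else 5

    @property
    def bic(self) -> float:
        """k*ln(n) - 2*lnL (lower is better)."""
        return self.k * math.log(self.n) - 2.0 * self.log_likelihood

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = np.sqrt(self.variances)
        z = (x[..., None] - self.means) / sd
        comp = np.exp(-0.5 * z * z) / (sd * math.sqrt(2.0 * math.pi))
        return comp @ self.weights

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / np.sqrt(self.variances)
        return ndtr(z) @ self.weights

    def posteriors(self, x) -> np.ndarray:
        """Per-point membership probabilities, shape (n, n_components)."""
        x = np.asarray(x, dtype=float)
        sd = np.sqrt(self.variances)
        z = (x[:, None] - self.means) / sd
        logp = (
            np.log(self.weights)
            - np.log(sd)
            - 0.5 * math.log(2.0 * math.pi)
            - 0.5 * z * z
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def _fit_one(x: np.ndarray, var_floor: float) -> MixtureFit:
    mu = float(x.mean())
    var = max(float(x.var()), var_floor)
    n = x.size
    ll = -0.5 * n * (math.log(2.0 * math.pi * var) + float(x.var()) / var)
    return MixtureFit(
        weights=np.array([1.0]),
        means=np.array([mu]),
        variances=np.array([var]),
        log_likelihood=ll,
        n=n,
    )


def _split_init(x_sorted: np.ndarray, q: float):
    """Initial (w, mu, var) from a split of the sorted data at quantile q."""
    n = x_sorted.size
    i = int(round(q * n))
    i = min(max(i, 2), n - 2)
    lo, hi = x_sorted[:i], x_sorted[i:]
    mu = np.array([lo.mean(), hi.mean()])
    var = np.array([max(lo.var(), VAR_FLOOR), max(hi.var(), VAR_FLOOR)])
    w = np.array([i / n, 1.0 - i / n])
    return w, mu, var


def fit_gaussian_mixture(
    values,
    n_components: int,
    seed: int = 0,
    n_init: int = 5,
    var_floor: float = VAR_FLOOR,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a 1- or 2-component Gaussian mixture by (seeded) EM.

    For two components EM is started from quantile splits at 0.5, 0.25
    and 0.75 plus ``n_init - 3`` seeded random restarts; the best
    log-likelihood is kept and components are returned sorted by mean.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"need at least 10 finite values, got {x.size}")
    if n_components == 1:
        return _fit_one(x, var_floor)

    x_sorted = np.sort(x)
    rng = np.random.default_rng(seed)
    global_var = max(float(x.var()), var_floor)
    inits = [_split_init(x_sorted, q) for q in (0.5, 0.25, 0.75)]
    for _ in range(max(n_init - 3, 0)):
        mu = rng.choice(x, size=2, replace=False).astype(float)
        inits.append(
            (np.array([0.5, 0.5]), np.sort(mu), np.array([global_var] * 2))
        )

    best = None
    for w0, mu0, var0 in inits:
        w, mu, var, ll, conv = _em2_core(
            x, w0.copy(), mu0.copy(), var0.copy(), var_floor, tol, max_iter
        )
        if not np.isfinite(ll):
            continue
        if best is None or ll > best[3]:
            best = (w.copy(), mu.copy(), var.copy(), ll, conv)
    if best is None:
        raise FitError("all EM initializations diverged")
    w, mu, var, ll, conv = best
    order = np.argsort(mu)
    return MixtureFit(
        weights=w[order],
        means=mu[order],
        variances=var[order],
        log_likelihood=float(ll),
        n=int(x.size),
        converged=bool(conv),
    )


def select_components(values, seed: int = 0, **fit_kwargs):
    """Fit 1 and 2 components; return (best_by_bic, fit1, fit2)."""
    fit1 = fit_gaussian_mixture(values, 1, seed=seed, **fit_kwargs)
    fit2 = fit_gaussian_mixture(values, 2, seed=seed, **fit_kwargs)
    best = fit1 if fit1.bic <= fit2.bic else fit2
    return best, fit1, fit2


def intersection(
    w1: float,
    mu1: float,
    var1: float,
    w2: float,
    mu2: float,
    var2: float,
) -> float:
    """Crossover point of two weighted Gaussian densities in [mu1, mu2].

    Solves ``w1*N(x|mu1,var1) = w2*N(x|mu2,var2)``; this is where the
    posterior probability of membership switches between the two
    components.  Requires ``mu1 < mu2``.  If the quadratic has no root in
    the interval (one density dominates everywhere between the means),
    the point of closest posterior balance in [mu1, mu2] is returned.
    """
    if not mu1 < mu2:
        raise ValueError("requires mu1 < mu2")
    if math.isclose(mu1, mu2) and math.isclose(var1, var2):
        raise NoCrossoverError("identical components have no crossover")

    # log w1*N1(x) - log w2*N2(x) = A x^2 + B x + C
    A = 1.0 / (2.0 * var2) - 1.0 / (2.0 * var1)
    B = mu1 / var1 - mu2 / var2
    C = (
        mu2 * mu2 / (2.0 * var2)
        - mu1 * mu1 / (2.0 * var1)
        + math.log(w1 / math.sqrt(var1))
        - math.log(w2 / math.sqrt(var2))
    )
    if abs(A) < 1e-300:
        roots = [] if abs(B) < 1e-300 else [-C / B]
    else:
        disc = B * B - 4.0 * A * C
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)]
    in_interval = [r for r in roots if mu1 <= r <= mu2]
    if in_interval:
        # with two in-interval roots keep the one closer to the midpoint
        mid = 0.5 * (mu1 + mu2)
        return float(min(in_interval, key=lambda r: abs(r - mid)))

    # no crossover between the means: best posterior-balance point
    grid = np.linspace(mu1, mu2, 2001)
    f = A * grid * grid + B * grid + C
    return float(grid[np.argmin(np.abs(f))])


def fit_intersection(fit: MixtureFit) -> float:
    """Component crossover of a 2-component :class:`MixtureFit`."""
    if fit.n_components != 2:
        raise ValueError("intersection requires a 2-component fit")
    return intersection(
        fit.weights[0],
        fit.means[0],
        fit.variances[0],
        fit.weights[1],
        fit.means[1],
        fit.variances[1],
    )


def categorize(values, fit: MixtureFit) -> np.ndarray:
    """Label each value 1 (lower-mean) or 2 (higher-mean component).

    Assignment is by maximum posterior probability; exact ties break to
    label 1.  A one-component fit labels everything 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if fit.n_components == 1:
        return np.ones(x.size, dtype=int)
    post = fit.posteriors(x)
    # argmax returns the first (lower-mean) component on ties
    return np.argmax(post, axis=1) + 1
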