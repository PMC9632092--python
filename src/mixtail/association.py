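"""2x2 contingency analysis of dichotomized genes and phenotypes.

Once expression patterns are reduced to binary labels (1 = low/absent,
2 = high/present), any gene-gene or gene-phenotype relationship becomes
a 2x2 table over the pairwise-complete samples:

              Y high   Y low
    X high       a       b
    X low        c       d

The association strength is the phi coefficient

    r = (a*d - b*c) / sqrt((a+b)(c+d)(a+c)(b+d)),

which satisfies chi2 = n * r^2 for the 1-dof Pearson statistic; p-values
come from that identity (no continuity correction) with Fisher's exact
test available for small cells, and families of tests are
Benjamini-Hochberg corrected.  An *inclusion* is the asymmetric pattern
with exactly one empty off-diagonal cell — every X-high sample is
Y-high, but not conversely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyResult",
    "contingency",
    "phi_from_counts",
    "bh_adjust",
    "condense_labels",
    "find_hits",
    "crosstab_report",
]


@dataclass(frozen=True)
class ContingencyResult:
    """One 2x2 comparison: counts, phi r-value, p-values, inclusion."""

    a: int
    b: int
    c: int
    d: int
    r: float
    p_raw: float
    inclusion: str  # "none" | "x_in_y" | "y_in_x"
    p_adj: Optional[float] = None
    valid: bool = True

    @property
    def n_pairs(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def chi2(self) -> float:
        return self.n_pairs * self.r**2


def phi_from_counts(a: int, b: int, c: int, d: int) -> float:
    """Phi coefficient of a 2x2 table; NaN when a marginal is zero."""
    m = (a + b) * (c + d) * (a + c) * (b + d)
    if m == 0:
        return float("nan")
    return (a * d - b * c) / np.sqrt(m)


def _result_from_counts(a, b, c, d, exact=False) -> ContingencyResult:
    r = phi_from_counts(a, b, c, d)
    valid = np.isfinite(r)
    if not valid:
        return ContingencyResult(a, b, c, d, r, float("nan"), "none",
                                 valid=False)
    n = a + b + c + d
    if exact:
        p = stats.fisher_exact([[a, b], [c, d]])[1]
    else:
        p = float(stats.chi2.sf(n * r * r, df=1))
    inclusion = "none"
    if a > 0 and d > 0 and (b == 0) != (c == 0):
        inclusion = "x_in_y" if b == 0 else "y_in_x"
    return ContingencyResult(a, b, c, d, r, p, inclusion)


def contingency(x_labels, y_labels, exact: bool = False) -> ContingencyResult:
    """2x2 contingency between two binary label vectors.

    Labels are 1 (low) / 2 (high); anything non-finite is missing and
    only pairwise-complete samples are counted.  ``exact=True`` swaps
    the chi-square p-value for Fisher's exact test (useful with small
    cells).
    """
    x = np.asarray(x_labels, dtype=float).ravel()
    y = np.asarray(y_labels, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("label vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if not mask.any():
        raise ValueError("no pairwise-complete samples")
    x, y = x[mask], y[mask]
    a = int(np.sum((x == 2) & (y == 2)))
    b = int(np.sum((x == 2) & (y == 1)))
    c = int(np.sum((x == 1) & (y == 2)))
    d = int(np.sum((x == 1) & (y == 1)))
    return _result_from_counts(a, b, c, d, exact=exact)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def condense_labels(labels, high_level: float = 2) -> np.ndarray:
    """Condense multi-level labels to binary: >= high_level -> 2, else 1.

    Three-level categorizations (1 = background, 2 = low, 3 = high) are
    condensed before 2x2 analysis; the default boundary merges
    background with low.  For three-level data pass ``high_level=3``.
    """
    x = np.asarray(labels, dtype=float)
    out = np.where(x >= high_level, 2.0, 1.0)
    out[~np.isfinite(x)] = np.nan
    return out


def find_hits(
    labels: pd.DataFrame,
    target,
    r_min: float = 0.0,
    p_max: float = 1.0,
    exact: bool = False,
    include_self: bool = False,
) -> pd.DataFrame:
    """Screen every feature against a target and rank the hits.

    Parameters
    ----------
    labels : DataFrame, samples x features
        Binary labels (1/2, NaN = missing).
    target : str or array-like
        Feature name (column of ``labels``) or an external binary
        phenotype vector aligned with the rows.
    r_min, p_max : float
        Hit filters on phi and the BH-adjusted p (adjustment is applied
        across the whole screened family, before filtering).

    Returns the hit table sorted by descending r then ascending
    adjusted p.  Pairs with an undefined phi (a zero marginal) are
    excluded from ranking.
    """
    if isinstance(target, str):
        if target not in labels.columns:
            raise KeyError(f"target feature {target!r} not in matrix")
        y = labels[target].to_numpy(dtype=float)
        skip = None if include_self else target
    else:
        y = np.asarray(target, dtype=float).ravel()
        if y.size != len(labels):
            raise ValueError("phenotype vector length mismatch")
        skip = None

    rows = []
    for feature in labels.columns:
        if feature == skip:
            continue
        try:
            res = contingency(y, labels[feature].to_numpy(dtype=float),
                              exact=exact)
        except ValueError:
            continue
        if not res.valid:
            continue
        rows.append(
            {
                "feature": feature,
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "r": res.r,
                "p_raw": res.p_raw,
                "inclusion": res.inclusion,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["feature", "a", "b", "c", "d", "r", "p_raw", "inclusion"],
    )
    if len(table):
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        table = table[(table["r"] >= r_min) & (table["p_adj"] <= p_max)]
        table = table.sort_values(
            ["r", "p_adj", "feature"], ascending=[False, True, True]
        ).reset_index(drop=True)
    else:
        table["p_adj"] = []
    cols = ["feature", "a", "b", "c", "d", "r", "p_raw", "p_adj", "inclusion"]
    return table[cols]


def crosstab_report(results, path=None) -> pd.DataFrame:
    """Render contingency results as a delimited table.

    ``results`` is a hit DataFrame from :func:`find_hits` or an iterable
    of (name, :class:`ContingencyResult`) pairs.  When ``path`` is given
    the table is written as TSV; the frame is returned either way and
    round-trips through ``pd.read_csv(..., sep='\\t')``.
    """
    if isinstance(results, pd.DataFrame):
        table = results.copy()
    else:
        table = pd.DataFrame(
            [
                {
                    "feature": name,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "r": r.r,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "inclusion": r.inclusion,
                }
                for name, r in results
            ]
        )
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
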