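"""Probe-level postprocessing: filtering, categorical-unimodal calls,
and combining multiple probe sets into per-gene profiles.

Microarray platforms measure one gene through several probe sets.  The
combining step groups a gene's probe sets whose pairwise Pearson
correlations all exceed a calibrated threshold (maximal cliques), merges
each group into a single profile by an inverse-chi-square weighted mean,

    v_j = sum_i (1/chi2_i) * v_ij / sum_i (1/chi2_i),

and keeps discordant probe sets separate as putative splice variants.
A lower goodness-of-fit chi-square means a cleaner expression pattern,
hence the inverse weighting; equal weights reduce to the arithmetic
mean.

Matrices are oriented samples x probes (features in columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tailtrim import run_itt

__all__ = [
    "probe_filter",
    "categorical_unimodal",
    "dichotomize_at",
    "calibrate_r_threshold",
    "combine_probes",
    "DEFAULT_R_THRESHOLD",
]

#: published reference calibration of the probe-association threshold
DEFAULT_R_THRESHOLD = 0.69


def probe_filter(
    matrix: pd.DataFrame,
    background_two_sigma: float,
    min_expr_fraction: float = 0.05,
    var_range_fraction: float = 0.025,
):
    """Remove probes with no convincing expression above background.

    Two rules, applied to a samples x probes matrix:

    1. Probes whose every (non-missing) value lies below the background
       threshold are removed outright.
    2. Borderline probes — expressed above the threshold in fewer than
       ``min_expr_fraction`` of samples *and* whose variance is within
       ``var_range_fraction`` of the bottom of the variance range across
       all probes — are also removed.

    Both constants are deliberately configurable defaults.  Returns
    ``(filtered_matrix, report)`` where the report lists each removed
    probe and the rule that removed it.
    """
    above = matrix.gt(background_two_sigma)
    n_obs = matrix.notna().sum(axis=0)
    frac_above = above.sum(axis=0) / n_obs.replace(0, np.nan)

    variances = matrix.var(axis=0, ddof=1)
    v_min, v_max = variances.min(), variances.max()
    var_cut = v_min + var_range_fraction * (v_max - v_min)

    all_background = frac_above.fillna(0.0) == 0.0
    borderline = (frac_above < min_expr_fraction) & (variances < var_cut)
    removed = all_background | borderline

    report = pd.DataFrame(
        {
            "probe": matrix.columns[removed],
            "reason": np.where(
                all_background[removed], "all_background", "borderline"
            ),
            "fraction_above": frac_above[removed].values,
            "variance": variances[removed].values,
        }
    ).reset_index(drop=True)
    return matrix.loc[:, ~removed], report


def categorical_unimodal(
    values, pattern: str, background_two_sigma: float
) -> bool:
    """Is a unimodal (tail-free) gene dichotomizable at background?

    True iff strictly between 5% and 95% of the samples lie above the
    background threshold — i.e. the distribution straddles background,
    so "non-expressing vs expressing" is a meaningful split.  Genes
    entirely below (pure background) or entirely above (uniformly
    expressed) are excluded; both boundaries are strict.
    """
    if pattern != "unimodal":
        raise ValueError(
            f"categorical-unimodal criterion applies to tail-free unimodal "
            f"genes, got pattern {pattern!r}"
        )
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    frac = float(np.mean(x > background_two_sigma))
    return 0.05 < frac < 0.95


def dichotomize_at(values, threshold: float) -> np.ndarray:
    """Label values 1 (<= threshold) / 2 (> threshold); NaN-preserving."""
    x = np.asarray(values, dtype=float)
    out = np.where(x > threshold, 2.0, 1.0)
    out[~np.isfinite(x)] = np.nan
    return out


def calibrate_r_threshold(
    r_values,
    seed: int = 0,
    default: float = DEFAULT_R_THRESHOLD,
    **itt_kwargs,
) -> float:
    """Probe-association threshold from same-gene pairwise correlations.

    The pooled r-values of all same-gene probe pairs split into a lower
    mode (unrelated patterns, e.g. splice variants) and an upper mode
    (probes reading the same transcript).  The full categorization runs
    on the pool; a bimodal verdict returns the component intersection,
    otherwise the configured default with a warning.
    """
    r = np.asarray(r_values, dtype=float).ravel()
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no correlation values supplied")
    if r.size < 50:
        warnings.warn(
            "fewer than 50 r-values; using default threshold",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(default)
    cat = run_itt(r, seed=seed, **itt_kwargs)
    if cat.pattern.startswith("bimodal") and cat.fit.n_components == 2:
        from .em import fit_intersection

        return float(fit_intersection(cat.fit))
    warnings.warn(
        "r-value pool not bimodal; using default threshold",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(default)


@dataclass(frozen=True)
class _Group:
    gene: str
    members: tuple
    combined_name: str
    kind: str  # "combined" | "variant" | "single"
    mean_r: float


def _pick_groups(corr: pd.DataFrame, r_threshold: float):
    """Maximal cliques under 'all pairwise r > threshold', chosen by
    highest mean pairwise r; overlapping cliques resolved greedily."""
    g = nx.Graph()
    g.add_nodes_from(corr.columns)
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > r_threshold:
                g.add_edge(a, b)

    groups = []
    remaining = set(cols)
    while True:
        sub = g.subgraph(remaining)
        cliques = [c for c in nx.find_cliques(sub) if len(c) >= 2]
        if not cliques:
            break

        def mean_r(c):
            pairs = [
                corr.loc[a, b]
                for i, a in enumerate(c)
                for b in c[i + 1 :]
            ]
            return float(np.mean(pairs))

        # highest mean pairwise r first; ties to larger, then name order
        best = max(
            cliques, key=lambda c: (mean_r(c), len(c), tuple(sorted(c)))
        )
        groups.append((tuple(sorted(best, key=cols.index)), mean_r(best)))
        remaining -= set(best)
    singles = [c for c in cols if c in remaining]
    return groups, singles


def combine_probes(
    matrix: pd.DataFrame,
    probe_to_gene,
    per_probe_chi2,
    r_threshold: float = DEFAULT_R_THRESHOLD,
):
    """Combine same-gene probe sets into weighted gene-level profiles.

    Parameters
    ----------
    matrix : DataFrame, samples x probes
        Continuous log2 values of the probes eligible for combining
        (bimodal or categorical-unimodal patterns; the caller excludes
        other unimodal probes).
    probe_to_gene : mapping or Series
        Probe id -> gene symbol.
    per_probe_chi2 : mapping or Series
        Final-model goodness-of-fit chi-square per probe (the combining
        weights are their inverses).  A missing or non-positive value is
        replaced by the group's mean weight, with a warning.
    r_threshold : float
        Minimum pairwise Pearson r (computed on the continuous values)
        for two probes to be grouped.

    Returns
    -------
    (combined, report)
        ``combined`` is samples x output-features; a combined group is
        named ``GENE_weighted``, an ungrouped probe of a multi-probe
        gene becomes a putative splice variant named ``GENE-k``, and a
        single-probe gene passes through under its gene name.
    """
    p2g = pd.Series(dict(probe_to_gene)) if not isinstance(
        probe_to_gene, pd.Series
    ) else probe_to_gene
    chi2 = pd.Series(dict(per_probe_chi2)) if not isinstance(
        per_probe_chi2, pd.Series
    ) else per_probe_chi2

    out = {}
    rows = []
    for gene in pd.unique(p2g.reindex(matrix.columns).dropna()):
        probes = [c for c in matrix.columns if p2g.get(c) == gene]
        if len(probes) == 1:
            out[gene] = matrix[probes[0]]
            rows.append(_Group(gene, (probes[0],), gene, "single", np.nan))
            continue

        corr = matrix[probes].corr(method="pearson")
        groups, singles = _pick_groups(corr, r_threshold)

        for members, mean_r in groups:
            name = f"{gene}_weighted"
            if name in out:  # a gene can split into several groups
                k = 2
                while f"{gene}_weighted-{k}" in out:
                    k += 1
                name = f"{gene}_weighted-{k}"
            weights = pd.Series(
                [1.0 / chi2[m] if (m in chi2 and chi2[m] > 0) else np.nan
                 for m in members],
                index=list(members),
            )
            if weights.isna().any():
                warnings.warn(
                    f"missing chi-square for members of {gene}; using the "
                    "group-mean weight",
                    RuntimeWarning,
                    stacklevel=2,
                )
                weights = weights.fillna(weights.mean())
                if weights.isna().all():
                    weights[:] = 1.0
            vals = matrix[list(members)]
            wmat = vals.notna() * weights
            out[name] = (vals * weights).sum(axis=1, skipna=True) / wmat.sum(
                axis=1
            )
            rows.append(_Group(gene, members, name, "combined", mean_r))

        for probe in singles:
            k = probes.index(probe) + 1
            name = f"{gene}-{k}"
            out[name] = matrix[probe]
            rows.append(_Group(gene, (probe,), name, "variant", np.nan))

    combined = pd.DataFrame(out, index=matrix.index)
    report = pd.DataFrame(
        [
            {
                "gene": g.gene,
                "output": g.combined_name,
                "members": ";".join(g.members),
                "kind": g.kind,
                "mean_pairwise_r": g.mean_r,
            }
            for g in rows
        ]
    )
    return combined, report
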