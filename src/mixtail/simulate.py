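"""Synthetic mixtures and the two validation studies.

The generator emulates the study conditions the categorization pipeline
is validated under:

* **Tail-sensitivity study** (`run_test1`) — one or two Gaussian
  components plus a uniform high tail whose spread grows from 1 to 12
  component standard deviations.  Component means are drawn U[5, 10],
  standard deviations U[0.5, 5], the total sample size U{50..150}, and
  the tail holds 5-25% of the points starting 2 sd above the (upper)
  component mean.  The score is the fraction of replicates whose 4-way
  pattern call (here: unimodal+tail or bimodal+tail) is correct.

* **Sample-size study** (`run_test2`) — balanced generation of all four
  pattern classes (unimodal, bimodal, each with/without tail) at a grid
  of sample sizes from 10 to 2000, means U[3, 10]; the tail's upper
  bound falls anywhere below 7 sd of the upper component mean.

Bimodal truths use equal component sizes and are resampled until
Ashman's D = |mu2 - mu1| / sqrt((s1^2 + s2^2)/2) >= 2, so that
"bimodal" is a well-defined ground truth.  Tail points are uniform on
their support.  Every replicate is seeded: curves are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tailtrim import DEFAULT_LOG2_CHI2_THRESHOLD, run_itt

__all__ = ["generate_mixture", "run_test1", "run_test2", "TEST2_SIZE_GRID"]

#: default sample-size grid for the sample-size study
TEST2_SIZE_GRID = (10, 25, 50, 90, 100, 150, 250, 500, 750, 1000, 1500, 2000)

_MIN_ASHMAN_D = 2.0


def _draw_components(kind, rng, mean_range, sd_range):
    if kind == "unimodal":
        m = rng.uniform(*mean_range)
        s = rng.uniform(*sd_range)
        return [(m, s)]
    if kind != "bimodal":
        raise ValueError("kind must be 'unimodal' or 'bimodal'")
    while True:  # resample until clearly bimodal (Ashman's D >= 2)
        m1, m2 = rng.uniform(*mean_range, size=2)
        s1, s2 = rng.uniform(*sd_range, size=2)
        d = abs(m2 - m1) / np.sqrt(0.5 * (s1 * s1 + s2 * s2))
        if d >= _MIN_ASHMAN_D:
            break
    comps = [(m1, s1), (m2, s2)]
    comps.sort(key=lambda c: c[0])
    return comps


def generate_mixture(
    kind: str,
    n: int,
    rng,
    tail: bool = True,
    tail_spread=None,
    tail_spread_range=None,
    mean_range=(5.0, 10.0),
    sd_range=(0.5, 5.0),
    tail_fraction_range=(0.05, 0.25),
):
    """Draw one synthetic expression vector with known ground truth.

    Parameters
    ----------
    kind : {"unimodal", "bimodal"}
        Number of Gaussian components.
    n : int
        Total number of points (components plus tail).
    rng : numpy Generator
        Source of randomness; pass a seeded generator for determinism.
    tail : bool
        Append a uniform high tail holding 5-25% of the points on
        ``[m + 2*s, m + (2 + spread)*s]`` of the upper component.
    tail_spread : float, optional
        Tail spread in upper-component sd units; mutually exclusive
        with ``tail_spread_range`` (spread drawn uniformly).

    Returns ``(values, truth)`` where ``truth`` records the pattern
    class, component parameters, tail support and per-point origin.
    """
    comps = _draw_components(kind, rng, mean_range, sd_range)
    truth = {"pattern": kind, "components": comps, "n_tail": 0,
             "tail_lower": None, "tail_upper": None}

    if tail:
        frac = rng.uniform(*tail_fraction_range)
        n_tail = max(int(round(frac * n)), 1)
    else:
        n_tail = 0
    n_norm = n - n_tail

    parts = []
    if kind == "unimodal":
        m, s = comps[0]
        parts.append(rng.normal(m, s, size=n_norm))
    else:
        n1 = n_norm // 2
        for (m, s), size in zip(comps, (n1, n_norm - n1)):
            parts.append(rng.normal(m, s, size=size))

    if tail:
        m_up, s_up = comps[-1]
        if tail_spread is None:
            lo_k, hi_k = tail_spread_range or (0.0, 5.0)
            spread = rng.uniform(lo_k, hi_k)
        else:
            spread = float(tail_spread)
        lower = m_up + 2.0 * s_up
        upper = lower + spread * s_up
        parts.append(rng.uniform(lower, upper, size=n_tail))
        truth.update(
            pattern=kind + "+tail",
            n_tail=n_tail,
            tail_lower=lower,
            tail_upper=upper,
            tail_spread=spread,
        )

    values = np.concatenate(parts)
    origin = np.concatenate(
        [np.zeros(n - n_tail, dtype=int), np.ones(n_tail, dtype=int)]
    )
    perm = rng.permutation(n)
    truth["origin"] = origin[perm]
    return values[perm], truth


def _fit_seed(rng) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_test1(
    case: str = "unimodal",
    spreads=tuple(range(1, 13)),
    replicates: int = 500,
    seed: int = 0,
    threshold_log2_chi2: float = DEFAULT_LOG2_CHI2_THRESHOLD,
    n_range=(50, 150),
    mean_range=(5.0, 10.0),
    sd_range=(0.5, 5.0),
    max_tail_fraction: float = 0.25,
    **em_kwargs,
) -> pd.DataFrame:
    """Tail-detection accuracy versus tail spread.

    For each spread (in upper-component sd units) generates
    ``replicates`` mixtures of ``case`` kind plus a uniform high tail,
    runs the full categorization, and scores the fraction of correct
    pattern calls.  The tail-boundary localisation error (median
    ``|estimated - true lower bound| / sd`` over correct calls) is
    reported as a separate column.

    Returns a frame with one row per spread: ``spread``, ``accuracy``,
    ``n_replicates``, ``boundary_mad`` and the call-confusion columns.
    """
    rows = []
    for spread in spreads:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1 if case == "unimodal" else 2,
                                    int(spread * 1000)])
        )
        expected = case + "+tail"
        n_correct = 0
        calls = {}
        boundary_errors = []
        for _ in range(replicates):
            n = int(rng.integers(n_range[0], n_range[1] + 1))
            values, truth = generate_mixture(
                case, n, rng, tail=True, tail_spread=spread,
                mean_range=mean_range, sd_range=sd_range,
            )
            cat = run_itt(
                values,
                threshold_log2_chi2=threshold_log2_chi2,
                seed=_fit_seed(rng),
                max_tail_fraction=max_tail_fraction,
                **em_kwargs,
            )
            calls[cat.pattern] = calls.get(cat.pattern, 0) + 1
            if cat.pattern == expected:
                n_correct += 1
                if cat.tail_boundary is not None:
                    s_up = truth["components"][-1][1]
                    boundary_errors.append(
                        abs(cat.tail_boundary - truth["tail_lower"]) / s_up
                    )
        rows.append(
            {
                "spread": spread,
                "accuracy": n_correct / replicates,
                "n_replicates": replicates,
                "boundary_mad": float(np.median(boundary_errors))
                if boundary_errors
                else np.nan,
                **{f"called_{k}": v for k, v in sorted(calls.items())},
            }
        )
    table = pd.DataFrame(rows)
    call_cols = [c for c in table.columns if c.startswith("called_")]
    table[call_cols] = table[call_cols].fillna(0).astype(int)
    return table


_TEST2_CLASSES = (
    ("unimodal", False),
    ("bimodal", False),
    ("unimodal", True),
    ("bimodal", True),
)


def run_test2(
    sample_sizes=TEST2_SIZE_GRID,
    replicates_per_class: int = 125,
    seed: int = 0,
    threshold_log2_chi2: float = DEFAULT_LOG2_CHI2_THRESHOLD,
    mean_range=(3.0, 10.0),
    sd_range=(0.5, 5.0),
    tail_spread_range=(0.0, 5.0),
    max_tail_fraction: float = 0.25,
    **em_kwargs,
) -> pd.DataFrame:
    """4-way pattern-classification accuracy versus sample size.

    Balanced generation over the four pattern classes at each sample
    size; accuracy is the fraction of correct 4-way calls.  Returns one
    row per sample size with the overall accuracy, its spread across
    classes (``accuracy_sd``) and per-class accuracies.
    """
    rows = []
    for n in sample_sizes:
        per_class = {}
        for ci, (kind, tail) in enumerate(_TEST2_CLASSES):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 3, int(n), ci])
            )
            expected = kind + ("+tail" if tail else "")
            correct = 0
            for _ in range(replicates_per_class):
                values, _ = generate_mixture(
                    kind, int(n), rng, tail=tail,
                    tail_spread_range=tail_spread_range,
                    mean_range=mean_range, sd_range=sd_range,
                )
                cat = run_itt(
                    values,
                    threshold_log2_chi2=threshold_log2_chi2,
                    seed=_fit_seed(rng),
                    max_tail_fraction=max_tail_fraction,
                    **em_kwargs,
                )
                if cat.pattern == expected:
                    correct += 1
            per_class[expected] = correct / replicates_per_class
        accs = np.array(list(per_class.values()))
        rows.append(
            {
                "n": int(n),
                "accuracy": float(accs.mean()),
                "accuracy_sd": float(accs.std(ddof=1)),
                **{f"acc_{k.replace('+', '_')}": v
                   for k, v in per_class.items()},
                "replicates_per_class": replicates_per_class,
            }
        )
    return pd.DataFrame(rows)
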