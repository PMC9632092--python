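# mixtail

Gaussian-mixture categorization of gene expression distributions with
chi-square tail detection, and 2×2 contingency analysis of the
resulting dichotomous phenotypes.

## The problem

Across a panel of tumour samples or cancer cell lines, the expression
of a gene that sits downstream of a driver mutation or a meta-stable
epigenetic switch is often **bimodal**: one mode for the altered
subgroup, one for the wild-type subgroup. Finding such genes, and the
cutoff that splits the panel into low/high expressors, turns continuous
expression into a discrete phenotype that can be crossed with
mutations, histology or any other binary trait in a 2×2 table.

A plain Gaussian mixture model (GMM) handles the clean cases, but a
large fraction of real expression distributions carry a **non-normal
tail** — a flat, spread-out run of outliers flanking the Gaussian bulk
(for example, a minority of lines expressing at background). A 1- or
2-component GMM either absorbs such a tail into a spurious wide
component or skews a genuine component, and the resulting cutoff is
wrong. `mixtail` addresses this with:

1. **Dynamic binning** — histograms with the Mann–Wald bin count
   `b = round(1.88·n^(2/5))`, end bins merged inward until every bin
   holds ≥ 5 observations, so the χ² goodness-of-fit test is valid;
2. **BIC model selection** — 1 vs 2 Gaussian components by
   `BIC = k·ln(n) − 2·ln L` (k = 2 or 5);
3. **Tail detection** — a calibrated threshold on `log2 χ²` of the
   selected fit, plus a structural check for a minority component
   lying wholly in the bulk component's outlier region (beyond its
   mean ± 2σ, which is where a tail starts by definition);
4. **Iterative tail trimming** — remove the most extreme point of the
   candidate tail, re-bin, refit 1 and 2 components, score; the best
   of all (side, depth, component-count) candidates wins by the
   penalized chi-square `χ² + k·ln(n′)` (best fit, least complex
   model), locating the boundary between bulk and tail;
5. **Association analysis** — per-sample labels (1 = low/absent,
   2 = high) feed 2×2 contingency tables scored by the phi coefficient
   `r = (ad − bc)/√((a+b)(c+d)(a+c)(b+d))` (so `χ² = n·r²`), with
   Benjamini–Hochberg correction across a screen and detection of
   *inclusions* (one empty off-diagonal cell: every X-high sample is
   Y-high but not conversely).

For microarray panels the package also calibrates a **background-noise
threshold** (intersection of a 2-component fit to the pooled value
distribution, and the stricter `µ_bg + 2σ_bg` bound), filters
never-expressed probes, dichotomizes "categorical" unimodal genes that
straddle background, and combines same-gene probe sets into a single
profile by an inverse-χ² weighted mean, keeping discordant probe sets
apart as putative splice variants.

## Worked example

```python
import numpy as np, pandas as pd
from mixtail import ExpressionCategorizer, find_hits

rng = np.random.default_rng(1)
n = 120
uni  = rng.normal(7.0, 0.8, n)                      # one clean mode
bim  = np.concatenate([rng.normal(4.0, 0.6, n//2),  # two modes
                       rng.normal(9.0, 0.7, n - n//2)])
rng.shuffle(bim)
tail = np.concatenate([rng.normal(6.0, 0.8, n-18),  # mode + high tail
                       rng.uniform(8.0, 12.0, 18)])
rng.shuffle(tail)
expr = pd.DataFrame({"GJC2like": uni, "CDX1like": bim, "CDH1like": tail})

est = ExpressionCategorizer(random_state=0).fit(expr)
print(est.summary_[["feature", "pattern", "cutoffs", "tail_side",
                    "n_tail", "chi2", "bic"]].round(2))
```

```
 feature       pattern cutoffs tail_side  n_tail  chi2    bic
GJC2like      unimodal                         0  8.89 256.10
CDX1like       bimodal 6.17743                 0  0.90 422.45
CDH1like unimodal+tail 8.41633      high      18  8.03 235.24
```

All three planted patterns are recovered: the bimodal gene is split at
the component intersection 6.18 (between its modes at 4 and 9), and
the tailed gene's 18 uniform outliers are trimmed with the boundary
placed at 8.42, just above where the tail support starts. Labels
(1 = low, 2 = high) are in `est.labels_`; screening them against a
feature of interest:

```python
print(find_hits(est.labels_, "CDX1like").round(3))
```

```
 feature  a  b  c  d     r  p_raw  p_adj inclusion
CDH1like 10 50  8 52 0.047  0.609  0.609      none
```

The two genes were generated independently, and the screen reports
exactly that: phi of 0.047 with an adjusted p of 0.61.

The same pipeline is available from the shell: `mixtail fit`,
`mixtail calibrate`, `mixtail probe-filter`, `mixtail combine`,
`mixtail associate` and `mixtail simulate` each write TSV outputs plus
a JSON manifest that makes the run reproducible.

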