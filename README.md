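# alleleniche

**Genic distribution modelling**: ecological niche modelling applied to
intraspecific allelic variants rather than whole species. The motivating
system is the bank vole (*Clethrionomys glareolus*) in Britain, which
carries two functionally distinct haemoglobin types — HbS (northern,
putatively cold-adapted) and HbF (southern, putatively warm-adapted) — whose
geographic boundary tracks climate. The package fits a separate climatic
niche model to the presence records of each allele, tests whether the two
climatic niches really differ, and asks how the relative climatic
favourability of the two alleles shifts under altered climates.

It is aimed at landscape geneticists and macroecologists who want a fully
scriptable, reproducible version of this workflow that runs on any
co-registered climate stack and typed occurrence table — and that can be
validated end-to-end on synthetic data with known niche ground truth.

## The model

The core is a presence/background maximum-entropy niche model. Over the
cells *x* of a background sample, suitability is the Gibbs distribution

```
q_λ(x) = exp(λ·f(x)) / Z,    Z = Σ_bg exp(λ·f(x)),
```

where `f` expands the raw climate values into bounded features (linear,
quadratic, pairwise product and hinge classes, min–max scaled to [0, 1] on
the training range). The coefficients minimize the L1-regularized negative
mean presence log-likelihood

```
J(λ) = −(1/m) Σ_i λ·f(x_i) + ln Z + Σ_j β_j |λ_j| ,
β_j = reg_multiplier · w_class(m) · s_j / √m ,
```

a convex problem solved by L-BFGS-B on the positive/negative coefficient
split; the fit satisfies the stationarity condition
`|empirical mean_j − model mean_j| ≤ β_j` per feature. Output scales follow
the MaxEnt 3.4 conventions (raw, cumulative, and cloglog
`1 − exp(−e^H · raw)` with `H` the entropy of the fitted background
distribution). Around this core the package provides:

* **AICc tuning** of feature classes and regularization multipliers, with
  `K` = number of nonzero coefficients;
* **validation** by subsampling replicates: Mann–Whitney AUC and the
  bootstrap partial-ROC ratio over the high-sensitivity region;
* **variable selection** by a reiterative jackknife (drop the variable with
  the lowest single-variable training gain) plus a pairwise |r| ≤ 0.8
  correlation cap;
* **niche overlap**: Schoener's `D = 1 − ½ Σ|p − q|` in geographic and in
  continuous environmental space, with one-sided niche-identity and
  two-sided background-similarity randomization tests;
* **projection**: suitability under shifted climates, scenario-member
  averaging, minimum/5th/10th-percentile training-presence thresholds, and
  cell-by-cell relative-favourability maps between the two alleles;
* **synthetic worlds**: smoothed, partially correlated climate layers and
  occurrences drawn from known product-Gaussian niches, so every stage can
  be tested against ground truth.

All file formats are plain text: ESRI ASCII grids, delimited occurrence
tables (longitude, latitude, allele), YAML models/configs.

## Worked example

```python
import numpy as np
from alleleniche import (make_default_world, extract_values, fit_maxent,
                         identity_test, schoener_d_geographic,
                         relative_favourability, ModelSettings)

world = make_default_world(seed=1)           # 40 HbS + 57 HbF at 94 sites
print(world.occurrences.counts())            # {'HbF': 57, 'HbS': 40}

stack = world.present.subset(["BIO10", "BIO13"])
bg = stack.values_table()                    # full 10,000-cell background
fits = {a: fit_maxent(extract_values(stack, world.occurrences.for_allele(a)),
                      bg, feature_classes="LQ")
        for a in ("HbS", "HbF")}
print(f"K active: {fits['HbS'].n_active}, "
      f"entropy H = {fits['HbS'].entropy:.3f} nats")

surfs = {a: r.predict_surface(stack, output_scale="raw")
         for a, r in fits.items()}
print(f"Schoener's D = {schoener_d_geographic(surfs['HbS'], surfs['HbF']):.3f}")

res = identity_test(world.occurrences.for_allele("HbS"),
                    world.occurrences.for_allele("HbF"),
                    stack, ModelSettings("LQ"), n_reps=99, seed=7)
print(f"identity test: one-sided p = {res.p_value:.3f}")

now = {a: r.predict_surface(stack) for a, r in fits.items()}
fut = {a: r.predict_surface(world.future.subset(["BIO10", "BIO13"]))
       for a, r in fits.items()}
print("present:", relative_favourability(now["HbS"], now["HbF"],
                                         "HbS", "HbF").percent)
print("warmed: ", relative_favourability(fut["HbS"], fut["HbF"],
                                         "HbS", "HbF").percent)
```

Output:

```
{'HbF': 57, 'HbS': 40}
K active: 4, entropy H = 8.886 nats
Schoener's D = 0.374
identity test: one-sided p = 0.010
present: {'HbS': 54.29, 'HbF': 45.71}
warmed:  {'HbS': 22.54, 'HbF': 77.46}
```

The two alleles' fitted niches overlap only partially (D ≈ 0.37) and are
significantly less similar than random repartitions of the pooled records
(p = 0.01): the climatic separation is real, not sampling noise. Under the
designed +2 standardized-unit warming of the temperature-like layer, the
warm-niche allele's favoured share of the landscape grows from ~46% to
~77% — the warm variant displaces the cold one across most of the map,
the qualitative signature the method is built to detect.

A command-line interface mirrors the library
(`alleleniche simulate|thin|select-vars|tune|fit|evaluate|project|overlap|maps|run-all`);
`alleleniche run-all --seed 1 --outdir run/` executes the whole pipeline on
the bundled synthetic demo and writes all tables, grids and test results to
the run directory.

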