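# thermoclade

Species delimitation and thermal-biogeography analysis for marine
macroalgae (and any other clade whose species boundaries are probed with
a single-locus ultrametric gene tree).

Many "cosmopolitan" seaweeds turn out to be complexes of pseudocryptic
species once sequence data are examined; once properly delimited, each
species' realized geographic range can be related to the sea-surface
temperatures (SST) it actually occupies.  `thermoclade` implements both
halves of that workflow:

1. **GMYC delimitation.**  The generalized mixed Yule-coalescent model
   locates the depth `T` (substitutions/site, measured from the tips) on
   a rooted ultrametric gene tree where branching switches from
   interspecific diversification (rate `lam1 * n^p1` for `n` lineages) to
   intraspecific coalescence (rate `lam2 * (n(n-1))^p2` within each
   cluster).  Tips coalescing below `T` form clusters; tips crossing `T`
   alone are singletons; clusters + singletons are the delimited
   entities `N_GMYC`.  The fit maximizes the likelihood over candidate
   thresholds (one per tip partition) and rate parameters, tests the
   rate shift with `LR = 2 (L_GMYC - L_0)` against chi-square(3), and
   reports a confidence set of entity counts within 2 log-likelihood
   units of the optimum.  Single- and multiple-threshold variants are
   provided, plus haplotype collapsing and uncorrected p-distance
   summaries (pairwise deletion) for the resulting species partition.

2. **Thermal tolerance vs. range size.**  Occurrence records are
   intersected with min/mean/max SST climatology rasters (ESRI ASCII
   grids, nearest-valid-cell fallback for coastal records on land
   cells).  Per species the pipeline reports latitudinal and
   longitudinal range and the **maximum thermal tolerance range** —
   `max_range_c = max_i(maxSST_i) - min_i(minSST_i)` over records `i`, an
   extreme-based statistic that always satisfies
   `max_range_c >= max_c - min_c` — and regresses `log10(range)` on
   `max_range_c` (OLS; R², Pearson r, two-sided t-test with n-2 df).

A `synthetic` module generates gene trees (Yule between species, Kingman
coalescent within), JC69 alignments, smooth SST gradients with seasonal
amplitude, and niche-constrained occurrences, so the full pipeline runs
and is tested without any external data.

## Worked example

Delimit a simulated tree of 5 species x 4 samples (tenfold separation
between species divergences and within-species coalescence), then
reproduce the published tolerance-range correlation from the packaged
ten-species *Dictyota* table:

```python
from thermoclade import synthetic, gmyc, datasets
from thermoclade.association import tolerance_range_regression

tree, truth = synthetic.simulate_gmyc_tree(
    synthetic.GmycSimConfig(k=5, m=4, separation=10.0, seed=42))
res = gmyc.fit_single_threshold(tree)
print(f"entities: {res.n_entities}, T = {res.threshold:.5f}, CI = {res.ci}")
print(f"L0 = {res.null.loglik:.3f}, L_GMYC = {res.loglik:.3f}, "
      f"LR = {res.lr:.3f}, p = {res.pvalue:.2e}")

df = datasets.load_dictyota_ranges()
r = tolerance_range_regression(df, axis="lon", log_base=10)
print(f"lon: R^2 = {r.r_squared:.3f}, p = {r.pvalue:.2e}, n = {r.n}")
```

prints

```
entities: 5, T = 0.00951, CI = (5, 7)
L0 = 106.335, L_GMYC = 124.846, LR = 37.023, p = 4.55e-08
lon: R^2 = 0.827, p = 2.62e-04, n = 10
```

All five species are recovered as clusters; the threshold 0.0095
substitutions/site sits in the gap between coalescent depths and species
divergences; the rate-shift test is decisive.  The longitudinal R² of
0.827 recomputes the published value (0.828) from the printed table; the
latitudinal analogue (~0.77 vs a published 0.751) is only approximate
because the published table rounds the underlying records.

The same analyses run from the shell:

```sh
thermoclade simulate --out world --seed 42 --species 8
thermoclade run-all --tree world/tree.nwk --alignment world/alignment.fasta \
    --occurrences world/occurrences.csv --sst-min world/sst_min.asc \
    --sst-mean world/sst_mean.asc --sst-max world/sst_max.asc --out results
```

`run-all` writes per-stage outputs (delimitation tables, threshold scan,
p-distance matrix, thermal summary, regression coefficients) and a
`run_report.json` with the headline numbers; identical inputs and seed
give byte-identical reports.

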