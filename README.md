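# metalhomeo

Quantitative machinery for metal-homeostasis microbiology: a tested,
reusable implementation of the statistics used to analyse single-channel
microarray transcriptomes, bacterial growth curves and metal-resistance
dose–response assays in studies of zinc-starved *Cupriavidus metallidurans*
deletion mutants. It is aimed at microbiologists who have spot-level array
exports, OD600 time series or endpoint plate data and want the complete
pipeline — signal extraction, significance calls, pattern classification,
kinetic parameters, IC50s — plus seeded synthetic data with planted ground
truth to validate every step.

## The statistics

Everything significance-related rests on one separation statistic. For two
quantities m₁ ± s₁ and m₂ ± s₂,

    D = |m₁ − m₂| / (s₁ + s₂),

so **D > 1 exactly when the two deviation bars do not touch**. The array
pipeline applies it twice: a spot is kept iff its background-subtracted
signal separates from the local background (spot D > 1); after replicate
averaging and per-gene probe aggregation, a gene's fold change between two
(strain, condition) cells is the ratio of mean signals,

    Q = mean₁ / mean₂,

called **U**p iff Q ≥ 2, **D**own iff Q ≤ 0.5, else **N**, and *significant*
iff additionally the comparison D exceeds 1. Genes are then classified into
U/D/N pattern strings across comparisons and tallied, and operon-region
clusters are summarised as mean ± SD of member Q values.

Growth curves follow lag → exponential → plateau: μ is the slope of the
best log-linear window fit (OD²-weighted, residual-gated extension), the
lag is the back-extrapolation of that line to the initial OD, doubling time
is ln 2/μ, and `suppressor_fraction_bound` converts a lag of n doubling
times into the 100·2⁻ⁿ % subpopulation that could instead explain it.
Dose–response endpoints are fitted with a logistic decline
od0/(1 + exp(b(c − IC50))), giving the IC50 with a seeded bootstrap error;
two strains differ significantly when their IC50 error bars do not overlap
— the same D > 1 rule again.

## Worked example

```python
import metalhomeo as mh

cfg = mh.ArraySimConfig(
    n_genes=8, probes_per_gene=2, n_replicates=3,
    strains=["d7", "zupT"], conditions=["EDTA"],
    planted_effects={"g00002": {("d7", "EDTA"): 4.0},
                     "g00005": {("d7", "EDTA"): 0.29}},
    pixel_cv=0.05, rng_seed=1)
sim = mh.simulate_spot_table(cfg)
genes = mh.gene_signal_table(mh.spot_signal_table(sim.spots))
cmp = mh.compare_table(genes, ("d7", "EDTA"), ("zupT", "EDTA"),
                       comparison_id="Q(EDTA)")
print(cmp.round(3).to_string(index=False))
```

```
gene_id comparison_id  q_value  d_comparison direction  significant status
 g00000       Q(EDTA)    1.004         0.052         N        False     OK
 g00001       Q(EDTA)    1.021         0.268         N        False     OK
 g00002       Q(EDTA)    4.026        25.610         U         True     OK
 g00003       Q(EDTA)    1.011         0.108         N        False     OK
 g00004       Q(EDTA)    0.959         0.337         N        False     OK
 g00005       Q(EDTA)    0.317         7.196         D         True     OK
 g00006       Q(EDTA)    0.952         0.545         N        False     OK
 g00007       Q(EDTA)    0.988         0.128         N        False     OK
```

The two planted genes are recovered: g00002 (planted 4-fold up) is called
U with Q ≈ 4 and a comparison D of 25.6 — its error bars are 25 bar-widths
apart — while g00005 (planted at 0.29-fold) is called D and significant;
the six null genes have Q ≈ 1, D ≪ 1 and stay N.

Growth kinetics from a noisy synthetic curve (true μ = 0.19 h⁻¹, lag
10.9 h):

```python
curve = mh.simulate_growth_curve(mh.GrowthSimConfig(
    mu_true=0.19, lag_true=10.9, noise_sd=0.005, rng_seed=4))
res = mh.GrowthCurveModel.from_dataframe(curve).fit()
print(res.summary()); print(res.suppressor_bound())
```

```
Growth-curve fit
----------------
growth rate mu         0.1979 1/h
doubling time          3.5018 h
lag phase             10.9688 h
r2 (log-linear)        0.9998
fit window         19.00-22.00 h
points in curve            41
(3, 12.5)
```

The rate and lag are recovered to a few percent, and the suppressor bound
says a 10.9 h lag at this doubling time spans 3 duplications, so a
suppressor subpopulation explaining it would have had to start at 12.5% of
the culture.

The same stages are available from the shell:
`metalhomeo simulate|spots|genes|compare|classify|growth|ic50|run`
(see `metalhomeo --help`); `run --config cfg.yaml --out dir/` executes the
whole pipeline and writes TSV tables plus a manifest with the cutoffs, seed
and per-stage row counts.

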