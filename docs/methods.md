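# Methods

`metalhomeo` packages the quantitative machinery used in transcriptome and
physiology studies of metal-starved *Cupriavidus metallidurans* mutants:
a single-channel microarray significance pipeline built on an
error-bar-separation statistic, regulation-pattern classification across
comparisons, growth-curve kinetics, and IC50 dose–response estimation.
Seeded synthetic-data generators with planted ground truth stand in for the
raw arrays and plate assays, so every estimator can be validated against
known truth.

## The D statistic and the array pipeline

For two quantities `m₁ ± s₁` and `m₂ ± s₂` the separation statistic is

    D = |m₁ − m₂| / (s₁ + s₂).

`D > 1` holds exactly when the two ± deviation bars do not touch; with
three biological replicates this is a conservative significance call that
needs no distributional assumption. The pipeline applies it twice:

1. **Spot signal (stage i).** Signal = spot-pixel mean − background-pixel
   mean; its deviation is half the sum of the two pixel deviations. A spot
   is kept iff its spot-vs-background D exceeds 1. A zero denominator is
   resolved as the continuous limit: D = +∞ if the means differ, 0 if they
   coincide.
2. **Replicate summary (stage ii).** Surviving replicate signals of one
   probe are averaged; "deviation" is the sample standard deviation (n−1
   denominator — the ± values act as error bars), and the smallest spot D
   (D_min) is carried as a quality indicator. One surviving replicate gives
   deviation 0 (sample SD is undefined at n = 1) with the count recorded.
3. **Gene aggregation (stage iii).** Probe summaries of a gene are combined
   by the unweighted mean of probe means and of probe deviations (averaging,
   not variance pooling, mirrors how the upstream values were built), with
   D_min minimised over probes. A gene with no surviving spot is status
   `NF` (not found).
4. **Comparison (stage iv).** The fold change Q is the ratio of two gene
   mean signals (numerator/denominator); the comparison D uses the two
   gene-level deviations. A change is *up* (U) iff Q ≥ 2, *down* (D) iff
   Q ≤ 0.5 (inclusive cutoffs; boundary hits are measure-zero in float
   data), else N; it is *significant* iff it is U or D **and** the
   comparison D exceeds 1. A missing or non-positive operand gives status
   `NQ` (not quantifiable); no epsilon flooring is applied, so an absent
   signal can never manufacture a fold change. Only the comparison D gates
   significance; D_min is reported for audit.

There is no between-array normalisation, no outlier rejection and no
multiple-testing correction anywhere in the pipeline; the cutoffs
(q_up = 2, q_down = 0.5, d_cut = 1) are configuration, serialised into the
header of every output table.

## Pattern classification and cluster ratios

Across an ordered set of comparisons each gene receives a string over
{U, D, N}. NQ results classify as N with a flag rather than a fourth
letter. Pattern counts separate `n_total` (every gene showing the pattern,
including nonsignificant calls) from `n_significant`; a gene counts as
significant for its pattern iff it has at least one U/D call and every
U/D call passed D > 1 — all-N genes have no call to gate, so their
significant subcount is 0. Operon-region clusters (externally supplied
gene→cluster mapping, e.g. `Op0317f`) are summarised as the mean ± sample
SD of member Q values; NQ members are dropped with a warning and a single
surviving member is flagged.

## Growth kinetics

The growth model is lag → exponential → hard cap:
`OD(t) = od0·exp(μ·max(t − lag, 0))`, truncated at od_max. The two
extracted parameters are the exponential rate μ (h⁻¹) and the lag duration
(h); doubling time is ln 2 / μ.

**Rate.** A sliding window (default 4 points, configurable) of ln OD vs
time is fitted by weighted least squares with weights OD² — the correct
weighting when turbidity noise is additive in linear scale, since the log
residual of a point with OD x has standard deviation ∝ 1/x. The steepest
window with r² ≥ 0.98 (configurable) seeds the exponential phase. The
window is then extended a point at a time while (a) the candidate point's
linear-scale residual stays within 3.5× the current fit's RMS residual and
(b) the widened fit keeps r² above the threshold. The residual gate makes
the extension a no-op on noise-free data (any point off the exponential law
is rejected at zero tolerance), preserving exact inversion of clean curves,
while on noisy curves it widens the window across the whole exponential
phase and averages read noise down — the short default window alone is
upward-biased, because maximising slope over many noisy 4-point windows
selects positive noise. Points at or below the detection floor (default
1e−6) are excluded. A flat curve is an exact fit with μ = 0 (doubling time
is then undefined and raises); a curve where no window reaches the r²
threshold raises `NoExponentialPhase`.

**Lag.** The fitted line is back-extrapolated to the initial OD level
(Monod's geometric construction), clipped at 0. Two refinements control
noise: the baseline OD is the mean over the pre-growth plateau (points
earlier than the first crossing estimate) rather than the single
inoculation reading, and the line's intercept is re-anchored on the first
e-fold of the exponential phase, which keeps the extrapolation lever arm
short — extrapolating from the window centre amplifies any slope error by
the full (centre − lag) distance. Both refinements are exact no-ops on
noise-free curves. Replicate OD columns are averaged point-wise before
fitting.

**Suppressor-fraction bound.** A lag of duration L at doubling time T
admits n = round(L/T) duplications; a pre-existing subpopulation that
merely grew through the "lag" would therefore have started at
100·2⁻ⁿ percent of the culture. The bound halves exactly per unit n.

## Dose–response IC50

The endpoint turbidity after a fixed incubation is modelled as
`OD(c) = od0 / (1 + exp(b·(c − IC50)))` — the minimal sigmoid whose
half-maximal point is an explicit parameter; OD(IC50) = od0/2 identically.
The three parameters are fitted by bounded least squares
(`scipy.optimize.curve_fit`), with the initial IC50 guess at the first
concentration whose endpoint drops below half the zero-concentration
level. Replicate series are pooled for the point estimate. The fit is
declared unconverged when the observed endpoints never bracket half the
uninhibited level (the half-maximal point would be pure extrapolation).
IC50 uncertainty is a seeded residual bootstrap (default 200 resamples):
residuals are resampled onto the fitted curve and the model refitted; the
reported error is the SD of the bootstrap IC50s. Two strains differ
significantly when their IC50 ± error bars do not overlap — deliberately
the same non-touching-bars rule as the array D > 1 criterion, rather than
an imported t-test.

IC50 is invariant under rescaling all endpoints by a positive constant, and
raising high-concentration endpoints (weaker inhibition) never lowers the
fitted IC50 on clean data; both are tested.

## Synthetic-data generators

The generators emulate the statistical structure the estimators assume,
with all truth recorded for recovery checks and mandatory seeds (no global
randomness; identical configs give identical tables).

* **Arrays.** Only pixel *summaries* exist in real exports, so the
  generator draws summaries directly: reported means are normal around the
  true spot/background means with SD = pixel_cv × truth, and reported
  deviations are the true SD times a chi-distributed factor
  (`sqrt(χ²(30)/30)`, the 30 playing the role of a per-spot pixel count),
  hence strictly positive. Defaults: baseline signal 1000 a.u. over a
  background of 200 a.u., pixel_cv 0.05, 3 biological replicates, 2 probes
  per gene (the spot count per gene on the real 8×15K layout is not fixed,
  so probes_per_gene is a free knob). Planted effects multiply the baseline
  of chosen (gene, strain, condition) cells.
* **Growth.** The lag/exponential/cap model above plus additive Gaussian
  read noise (default SD 0.005 OD), sampled hourly over 0–40 h from
  od0 = 0.05 to a 2.0 cap — typical plate-reader settings for this
  slow-growing β-proteobacterium (doubling times 2–12 h).
* **Dose–response.** The logistic decline above with od_uninhibited 1.0,
  shape 0.03 µM⁻¹ and 8 concentrations spanning 0–400 µM, bracketing the
  IC50s of interest (tens to hundreds of µM).

What the generators deliberately do **not** emulate: spatial artefacts and
gradients on the array, probe-sequence effects, between-array intensity
shifts (the pipeline has no normalisation to exercise), non-Gaussian pixel
statistics, diauxie or death phases in growth curves, and hormesis in
dose–response. Passing recovery suites therefore demonstrates correctness
of the algorithms under their own model assumptions, not robustness to
artefacts absent from the model.

## Validation suites and problem sizes

The test suite and `scripts/acceptance.py` recompute, from scratch:

* the printed doubling-time and suppressor-bound arithmetic;
* the D > 1 ⟺ non-touching-bars equivalence over 10⁴ random pairs;
* exact agreement between the vectorised pipeline and a straight-line
  loop reference on 50-gene tables (noise high enough to exercise the
  NF/NQ paths);
* array recovery at pixel_cv 0.05 with 3 replicates: sensitivity for
  50 genes planted at 4-fold and the false-call rate among 1000 null
  genes, averaged over 10 seeds;
* growth recovery: median |error| of μ and lag over 100 noisy curves with
  μ ∈ [0.06, 0.34] h⁻¹ and lag ∈ [0, 11] h (the published parameter
  range);
* IC50 recovery: median |error| over 100 series at 5% endpoint noise,
  three replicates each; and the published zinc IC50 pair (53 ± 4 vs
  113 ± 8 µM) under the bar-overlap rule.

These sizes keep the whole suite in single-digit seconds on one CPU while
leaving the binomial sampling error of the rate estimates well inside the
stated tolerances.

## Known limitations

* The replicate/probe deviation convention (sample SD, then unweighted
  averaging) is one faithful reading of "mean value plus deviation";
  variance pooling would weight probes differently. The choice is recorded
  in every output, so alternatives can be audited.
* The lag construction is the classical back-extrapolation; lag values
  obtained by visual inspection of published curves need not coincide.
* The logistic decline is a substitute for the unpublished IC50 formula of
  the original plate-assay method; absolute published IC50 values are used
  only as inputs to the comparison rule, never as fit validation.
* `NF` and `NeF` ("never found" anywhere vs not found in one strain) are
  collapsed into a single `NF` status; the distinction needs genome-level
  bookkeeping outside this package's scope.
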