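# Methods

## Data model and conventions

Internal coordinates are 1-based and inclusive; BED input/output converts
at the boundary. Probe indices are 0-based within a chromosome. Call
states use the CGHcall convention {−2, −1, 0, 1, 2}; downstream logic only
distinguishes neutral (0) from non-neutral, so any integer coding with
0 = neutral is accepted. Strand is stored but ignored by breakpoint
mapping — no strand rule exists for this event class.

## Breakpoint extraction and gene mapping

A breakpoint is the transition between two adjacent segments of one
chromosome. Two exclusions apply: the first segment of a chromosome has no
preceding segment (its start is the chromosome end, not a break), and
neutral–neutral transitions are discarded as re-segmentation artifacts
rather than copy-number changes.

The true break lies between the last probe of the old segment and the
first probe of the new one. Gene assignment therefore overlaps the
half-open *uncertainty interval* `(pos(left), pos(right)]` with gene
spans; a breakpoint whose interval covers several genes counts for all of
them, which is the honest treatment of inter-probe resolution and also
generates the shared-probe gene pools the reporting convention expects.
A point-assignment mode (right probe only) exists behind
`map_breakpoints_to_genes(..., mode="point")` for sensitivity analyses.

Genes whose breakpoint-supporting probe pairs intersect are pooled
transitively (connected components of the gene–probe bipartite graph,
keyed per chromosome); a pooled row is the OR of member rows and pools are
named after the alphabetically first member with a `*` suffix. Pooled
entities are the unit of testing, since their member genes are supported
by the same breakpoints and cannot be statistically distinguished. A
pooled entity's covariates are the union of member probe sets and the
length of the union of member spans.

## Recurrence test

Step 1 fits one pooled logistic regression over all (testable gene,
profile) pairs — response 1{breakpoint in gene g of profile s}, covariates
`log(n_probes_g + 1)`, `log(span_g)`, `log(B_s + 1)` — rather than a
separate regression per profile. Per-profile baselines are still obtained
through the burden covariate, while profiles with few events do not
destabilize the fit; a per-profile interpretation of the baseline step
would be unfittable for low-burden profiles. Genes without associated
probes are untestable and carry p₍gs₎ = 0. "Gene length by probe
coverage" enters as two covariates (span and probe count); their
collinearity is left to the ML fit. If the fit degenerates (no events, or
separation) a closed-form uniform-placement fallback
p₍gs₎ = 1 − (1 − B_s/N)^{n_g} over inter-probe intervals is available and
flagged in the model's `method` field.

Step 2 computes, per gene, the exact Poisson-binomial tail
P₀(T ≥ t_obs) by the standard O(n²) dynamic-programming convolution
(vectorized across genes). The DP is numerically stable at cohort scale;
the pmf sums to 1 within 1e−10 at n = 352.

Step 3 adjusts for multiple testing with a step-up that respects the
discreteness and heterogeneity of the nulls. Each gene's p-value lives on
its attainable support {P₀(T ≥ k)}. At threshold t the estimated FDR is
FDR̂(t) = Σ₍g₎ P₀(P₍g₎ ≤ t) / max(1, #{p₍g₎ ≤ t}), evaluated on the union
of attainable values, and q₍g₎ = min over attainable t ≥ p₍g₎ of FDR̂(t),
capped at 1. Ties across hypotheses are collapsed so the numerator at a
threshold includes every attainable jump at exactly that value. When all
nulls coincide this is algebraically the standard Benjamini–Hochberg
step-up, which is why the probe-level test (uniform per-profile
breakpoint probability B_s/N across probes — one shared null) simply uses
BH. No mid-p variant is offered; attainable CDFs are evaluated exactly.

By default all probe-covered genes enter the test: genes without an
observed breakpoint receive p = 1 but still contribute their null
distribution to the FDR numerator. Restricting the tested set to
candidate genes (≥ 1 observed breakpoint, available via
`genes="candidate"`) makes the plug-in estimate anti-conservative,
because hypotheses that could have produced small p-values are then
missing from the numerator; on planted-signal simulations this roughly
doubles the realized false-discovery proportion. The default keeps the
estimator calibrated: across 25 planted replicates the mean empirical FDP
at the 0.1 threshold sits near or below the nominal level (the plug-in
targets the level exactly and has no π₀ slack, so individual replicate
sets fluctuate around it).

## Network-based stratification

Events from the breakpoint matrix (restricted to significant recurrent
genes with prevalence > 3%, the convention for "prevalent recurrent
breakpoint genes") and the mutation panel are merged by gene-wise OR; a
gene may carry both event types. Samples with no event are flagged and
dropped before clustering.

Propagation iterates F ← αFA + (1−α)F₀ with A the symmetric
degree-normalized adjacency D^{−1/2}AD^{−1/2} — a contraction for α < 1 —
followed by quantile normalization of each sample's vector to the mean
empirical distribution, so per-sample event burden does not dominate the
factorization. Default α = 0.7.

Each of `n_iter` consensus iterations subsamples 80% of samples and genes,
runs graph-regularized NMF (‖V − WH‖²_F + λ·tr(HLHᵀ), multiplicative
updates, λ = 1, tol 1e−5, ≤ 500 iterations, non-negative uniform random
initialization from the master seed), and assigns each selected sample to
its argmax factor (ties to the lowest index). Co-clustering counts
normalized by co-selection counts give the sample similarity matrix;
final subtypes come from average-linkage hierarchical clustering of
1 − similarity cut into k clusters (k = 4 by convention for this cohort
type). The per-iteration reconstructions Vᵢ = WᵢHᵢ are accumulated into
gene aberration scores R₍s₎ = (1/C₍s₎)ΣᵢVᵢ₍s₎ with C₍s₎ the number of
iterations selecting sample s; never-selected samples get zero vectors
and a flag. A streaming accumulator is used unless per-iteration factors
are requested; both paths produce identical R₍s₎. Subtype–gene
association uses two-sided Mann–Whitney U of a gene's scores inside vs
outside each subtype (sidedness and the optional BH adjustment are
package decisions; no convention exists for this grid).

## Clinical analyses

Survival curves are Kaplan–Meier product-limit estimates; group
comparisons use the k-group log-rank test. Hazard ratios come from a Cox
proportional-hazards model with the single binary group covariate (the
method behind reported subtype HRs is not standardized; Cox is this
package's documented choice). Median OS is read from the KM curve (first
time the estimate reaches 0.5), respecting censoring. The per-gene screen
tests carriers vs non-carriers per gene with log-rank and Bonferroni
adjustment, skipping genes with fewer than 5 carriers or non-carriers.
Fisher exact tests expose sidedness explicitly and return the 2×2 table
for auditability; degenerate margins yield p = 1 with a warning.

## Synthetic cohort generator

The generator emulates the *structure* of a segmented, state-called
array-CGH cohort — it does not simulate probe-level log2 noise or run
segmentation. Probes sit on an even grid (17 kb default). Breakpoints are
drawn as inter-probe boundary events: a negative-binomial background
count per sample (mean 40, dispersion 1.0, giving burdens spanning orders
of magnitude as real cohorts show) placed uniformly over boundaries, plus
planted events inside designated genes with per-sample hit probability θ.
Boundary sets become segments with alternating neutral / non-neutral
calls, so no simulated boundary is ever neutral–neutral and
`derive_breakpoints` recovers the planted set exactly — ground truth
bookkeeping is exact by construction. Gene lengths are log-normal (median
30 kb, σ = 1); planted and panel genes are forced to at least 3× the
probe spacing so they are probe-covered and testable.

Preset scenarios fix the study conditions: `null` (no signal; calibration),
`planted` (100 samples, 2 000 genes, 20 000 probes, 20 planted genes at
θ = 0.08; the power/FDR benchmark), and `subtypes` (200 samples, 4 groups,
1 000 network genes, 15 drivers per subtype at θ = 0.4 inside vs 0.05
outside the subtype — magnitudes mirroring reported in-subtype vs rest
breakpoint enrichments such as 59%/13% and 33%/5%; exponential survival
with a 2.5× hazard subtype, 30%/1% MSI enrichment, and a mutation panel
with one subtype-enriched gene). A `full-scale` preset documents the
emulated cohort's magnitudes (352 samples, ~169k probes) but is not used
by tests; test and benchmark problem sizes are desk-scale by design.

What passing tests on synthetic cohorts does **not** show: robustness to
segmentation errors, to wavy log2 baselines, to probe-density
irregularities, or to breakpoint calls blurred across more than one
probe gap — real profiles produce neutral–neutral boundaries and missed
calls that the generator deliberately omits because they are upstream of
this pipeline's contract.

## Numerical and design notes

- Poisson-binomial DP in float64; tails clipped to [0, 1] after reverse
  cumulative summation.
- The propagation fixed point is detected by max-norm change < tol
  (default 1e−6); the closed form (1−α)F₀(I−αA)^{−1} is used as a test
  oracle only.
- NMF multiplicative updates guard denominators with 1e−12; the objective
  is asserted non-increasing in tests.
- Consensus clustering is fully reproducible given `NBSConfig.seed`; one
  `numpy` Generator drives subsampling and NMF initialization.
- Degenerate inputs fail loudly: gapped/overlapping segments, non-binary
  matrices, zero-event logistic fits, k exceeding matrix rank, groups
  without events.

## Known limitations

- The logistic null is fitted on the full cohort including any true
  signal, which slightly inflates baseline probabilities (a conservative
  bias); no signal-exclusion refit is implemented.
- The discrete-FDR step-up assumes independent hypotheses, as does BH;
  genes sharing samples' burdens are weakly dependent.
- Pool covariates (union probes/span) treat a pool as one long gene; for
  pools spanning megabases this can over-penalize genuinely recurrent
  members.
- The probe-level test conditions on per-sample totals B_s rather than
  modelling them.
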