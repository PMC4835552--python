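# Methods

This note documents the models, estimators and numerical choices behind
`mztstage`, what the synthetic generator does and does not emulate, and the
problem sizes used in the validation suite.

## Synthetic MZT dynamics

The generator (`mztstage.synthetic`) draws a gene universe of three
classes and evolves noise-free expected abundances in time $t$ (minutes
after egg deposition):

* **maternal** — first-order decay $m_g(t) = m_g(0)\,2^{-t/t_{1/2,g}}$
  with per-gene half-lives $\log_2 t_{1/2} \sim N(\log_2 60\ \mathrm{min},
  0.8)$. The geometric-mean half-life of 60 min and the ~0.8 log2 spread
  put most genes between ~20 min and ~3 h, the range reported for maternal
  transcripts in early fly embryos.
* **zygotic** — logistic activation
  $z_g(t) = z_g^{\max}\,\sigma\!\big((t - t_{on})/\tau\big)$ with onset
  $t_{on} = 130$ min (the major wave of zygotic genome activation at the
  start of cycle 14) and time-scale $\tau = 15$ min. The logistic is the
  minimal smooth monotone form with an interpretable midpoint; nothing in
  the analysis depends on this exact shape.
* **stable** — constant housekeeping genes, included so that normalization
  choices are testable against genes with no timing signal.

Baseline abundances are log2-normal ($\mu = 5$, $\sigma = 2$ in log2
RPKM-like units). The default reference grid has 8 stages at
{60, 80, 95, 105, 115, 130, 150, 170} min labelled c10…c14D — a documented
placeholder with realistic nuclear-cycle spacing (short cycles early,
stretched cycle-14 sub-stages late); real analyses supply their own
stage→time table.

Observation noise is multiplicative log-normal with sd 0.25 in log2 units
per observation, applied to the expected abundance. Published work does not
report the replicate noise of the RNA-seq this emulates; 0.25 log2
(≈ ±19%) is a conventional figure for bulk RNA-seq biological replicates
and is the package-wide default. A count mode (Poisson with library-size
scaling) exists for workflows that want integer counts; it is not the
default because the continuous model keeps every closed-form check exact.

All randomness flows through explicit integer seeds (NumPy `SeedSequence`
with fixed stream keys); identical (config, seed) pairs are bit-identical.

**What the generator does not emulate:** mapping/quantification artifacts,
gene–gene correlation, batch effects, strain differences, spatial
patterning, zygotic re-expression of maternal genes (maternal decay is
pure), or deviations from first-order decay. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every failure mode of real embryo RNA-seq; the free-intercept
and robust decay fits and the banded-overlap metric exist precisely for
data that violate the clean model.

## Ruler compilation

A gene enters the ruler iff it is classified maternal (classification is
an input — published lists, or `derive_gene_class` from a reference) and
passes three filters on the reference: first-stage expression
≥ 1 abundance unit, no consecutive-stage increase beyond a 5% tolerance,
and ≥ 2-fold total decline. The tolerance absorbs replicate jitter in real
references; the decline filter removes near-flat genes that carry no
timing information. Output order is descending first-stage expression, and
the compile parameters are recorded in the written ruler file's header.
Published ruler lists can be supplied directly in place of compilation.

## Stage mapping

Similarity between a query and each reference stage is computed over ruler
genes on $\log_2(x + 0.5)$ values. The pseudocount of 0.5 abundance units
guards zeros; RPKM-scale data are heavy-tailed, and working in log space
keeps the rank statistics stable. The default metric is the Spearman rank
correlation — scale-free, so library-size differences cannot move the
argmax. The alternative "overlap" metric is the fraction of ruler genes
whose query/reference log-ratio lies within a 2-fold band *centered on the
per-stage median ratio*; centering makes the band insensitive to residual
per-sample scale. The overlap metric quantizes coarsely (many stages can
tie at fraction 1 when half-life spread is modest) and is kept as a
faithful reading of "highest overlap" mapping; Spearman is recommended.

Ties at the argmax resolve to the earliest stage: maternal rulers lose
resolution late in the time-course (many transcripts fully decayed), so
late ties are less informative.

**Continuous time.** Since $\log_2$ maternal abundance is linear in time,
geometric (log-linear) interpolation between stage columns reconstructs
the expected maternal profile *exactly* at any interior time. The default
interpolation therefore densifies the reference on a 1-minute grid and
takes the similarity argmax over the grid; noise-free recovery error is
bounded by half the grid step. A 3-point parabola through the similarity
peak is available (`interp_method="parabola"`) but is less accurate:
Spearman similarity is not locally quadratic in time, and the vertex can
miss by several minutes even without noise.

**Normalization.** `normalize_to_reference` applies one factor per sample:
the median over ruler genes of reference-first-stage expression over query
expression. Anchoring at the reference start makes the factor independent
of zygotic activation; it recovers planted library-size factors exactly
for queries near the start of the time-course and, for later queries,
additionally carries the accumulated maternal decay. The Spearman metric
is unaffected by any per-sample scale; scale-sensitive steps downstream
(the residual comparison) re-anchor at the matched stage, see below.

**Replicates** are estimated independently and summarized by the median
(similarity vectors element-wise, times by median), keeping per-replicate
spread observable. The gene-resampling bootstrap (`bootstrap_stage`,
≥ 100 resamples) reports the sd of the interpolated time; it is seeded and
deterministic.

## Decay clock

`log2_foldchanges` computes per-gene
$\log_2\!\big((\bar{x}_B + c)/(\bar{x}_A + c)\big)$ over replicate means
with pseudocount $c$ (default 0.5). `estimate_delta_time_decay` regresses
these on $x_g = 1/t_{1/2,g}$ over maternal genes; under pure decay the
slope is $-\Delta t$. Numerical and filtering choices:

* **Through-origin** least squares is the default — the decay law forces
  FC = 0 at $\Delta t = 0$. Free-intercept mode absorbs normalization
  offsets in real data; robust mode swaps in median-based slopes (median
  per-gene ratio through the origin, Siegel repeated medians otherwise).
* **Induction exclusion:** genes with $\log_2 \mathrm{FC} > +0.5$ violate
  the decay-only assumption (zygotic re-expression) and are excluded and
  counted.
* **Detection floor:** genes below 1 abundance unit in either condition
  are excluded when the fold-change table carries condition means. Once a
  transcript decays to the order of the pseudocount its measured
  fold-change saturates at $-\log_2((\bar{x}_A + c)/c)$ instead of
  tracking $-\Delta t/t_{1/2}$; because the saturated genes are exactly
  the short-half-life, high-leverage points, leaving them in biases
  $\hat{\Delta t}$ toward zero (by roughly a third at the default noise
  level). The floor equals the ruler's expression threshold.
* **Degenerate inputs:** a zero offset makes every extent of reduction 0;
  correlations are then reported as 0 with a `degenerate` flag rather than
  NaN.

The half-life correlation (Spearman and Pearson between $-\log_2\mathrm{FC}$
and $t_{1/2}$) is reported alongside; it is exactly −1 on noise-free
decay-only data because $\Delta t/t_{1/2}$ is strictly decreasing in
$t_{1/2}$.

The stage clock and the decay clock are deliberately independent readouts.
On data satisfying the generator's assumptions they agree to within
interpolation and Monte-Carlo error; on real data they need not, and the
package reports both without adjudicating.

## Stage-matched residuals

`stage_matched_profile` returns the reference column at the estimated
discrete stage, or the geometric interpolation between flanking columns at
the interpolated time (zeros propagate to zero; out-of-span times are
clamped with a warning). For the residual comparison the *discrete* column
is recommended and is what the `report` pipeline uses: log-linear
interpolation is exact for exponentially decaying genes but systematically
undershoots the concave (in log space) zygotic activation between stages,
which would bias zygotic residuals upward whenever the estimated time
falls between stages.

`residual_foldchanges` compares the query's replicate mean against the
matched profile. When given the ruler it first rescales the query by the
median ruler-gene ratio matched/query — the same maternal-gene
normalization, re-anchored at the matched stage — so that the residuals
are free of the whole-time-course decay factor introduced by first-stage
anchoring. `global_shift` on the residuals then shows directional
fractions near 0.5 for both classes on timing-only data, while planted
condition effects stand out in the top |residual| tail.

The sign test in `global_shift` is the exact two-sided binomial test; zero
fold-changes carry no sign and are dropped from the test but counted and
reported. Directional fractions use the full class denominator, so all-zero
data give fractions of 0, not 0.5.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use deliberately desk-scale
simulations chosen to keep every check fast while leaving comfortable
statistical margins: a 350-gene default universe (200 maternal /
100 zygotic / 50 stable) on the 8-stage grid; 100 simulated pairs for
offset-recovery medians (planted $\Delta t = 35$ min, single replicates,
noise sd 0.25); 150 maternal genes for the decay-clock noise runs; 200
permutations for the half-life null; 50 randomized references for the
ruler oracle; 20 simulated query pools (3 replicates each) for the
residual-fraction averages; and a 1000-gene universe for planted-effect
recovery so that the top-5% residual tail (50 genes) can contain all 20
planted genes. Queries for the shift analyses sit at grid stages (115 and
150 min), mirroring the practice of comparing against a named-cycle
reference column.

## Known limitations

* Gene identifiers match by exact string equality (after whitespace
  stripping); no symbol aliasing between annotation releases.
* Half-lives are inputs, never estimated from the data.
* Single-query mapping only: the package does not align two full
  time-courses to each other.
* The decay clock assumes no new synthesis of maternal transcripts; in
  systems with substantial re-expression, the induction filter removes
  affected genes but the remaining estimate still leans on the decay-only
  assumption.
* Downstream interpretation of residual fold-changes (functional
  enrichment etc.) is out of scope; the residual table is the endpoint.
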