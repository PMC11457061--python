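# Methods

This note documents the model, the defaults, and the numerical and design
choices behind `abcne`, in the spirit of the methods documentation shipped
by simulation and statistics packages.

## Inference model

The estimand is the contemporary effective size Ne of the population from
which one sample of S diploid individuals, genotyped at L biallelic loci,
was drawn. Inference is likelihood-free: J parameter draws from a uniform
prior are pushed through a forward simulator that reproduces the sampling
design (same S and L), each simulated sample is reduced to the same
five-statistic vector as the observed sample, and the posterior is formed
from the accepted draws after a regression adjustment. The estimate is a
Wright–Fisher-equivalent Ne: whatever the true demography, the method
reports the size of the idealized two-sex Wright–Fisher population whose
samples look like the observed one under these statistics.

## Summary statistics

* **Ĥe** — mean over loci of 2p(1−p), p the allele-1 frequency over called
  alleles. No small-sample (2S/(2S−1)) correction is applied: observed and
  simulated samples share the same S, so any such factor cancels in the
  matching. Monomorphic loci contribute 0.
* **F̂is** — 1 − mean over loci of Ĥo/Ĥe (mean of per-locus ratios, not
  ratio of means). Loci with Ĥe = 0 are an error by default (the MAF filter
  removes them from real data); inside the pipeline they are skipped, and
  the same skipping rule is applied to observed and simulated samples so
  the two remain comparable. Slightly negative values are expected under
  the two-sex model (heterozygote excess in small populations).
* **ĥ, v̂h** — mean and (S−1)-denominator variance of the per-individual
  count of homozygous called loci.
* **r̂²** — mean over usable locus pairs of the squared Burrows composite
  correlation: Δ̂ = Σxy/(2n) − 2pq on dosages x, y over the n individuals
  called at both loci, r̂ = Δ̂/√((p(1−p)+D₁)(q(1−q)+D₂)) with
  Dᵢ the homozygote-excess departure from Hardy–Weinberg, clamped to
  [−1, 1]. Pairs are unusable (excluded, not an error) when a locus is
  monomorphic within the jointly called set, n < 2, or the denominator
  vanishes. Squaring precedes averaging — the form LD-based Ne theory
  uses; averaging r̂ before squaring (which nearly cancels by symmetry of
  coupling/repulsion) is available via `square_first=False`.
* Missing data: per-locus deletion for the single-locus statistics,
  pairwise deletion for LD.

The all-pairs LD scan dominates runtime. For panels beyond a few thousand
loci, `max_pairs` caps it by seeded random pair subsampling; the default is
all pairs.

## Simulator

Census size ne, split into ne/2 males and ne/2 females (odd draws round up
to even, with a warning). Each generation every offspring draws a
uniform-random father and mother and inherits one uniformly chosen allele
from each parent per locus — free recombination, no selfing, discrete
generations. Transmitted alleles flip state with probability mu (default
1.2×10⁻⁸ per allele per generation; flips are placed by a binomial draw at
low rates and by a dense Bernoulli mask when mu ≥ 0.01). Under this scheme
the effective size slightly exceeds the census size; the drawn census value
is recorded as the trial's ne without correction, matching the target
definition above.

Initialization emulates mutation–drift equilibrium conditioned on
polymorphism: each locus's initial allele-1 frequency is drawn from the
folded neutral spectrum (weight ∝ 1/k + 1/(2ne−k) on the grid k/(2ne))
restricted to minor frequency ≥ `maf_floor`, and genotypes are
Hardy–Weinberg draws at that frequency. Every simulated locus therefore
starts polymorphic, mirroring a MAF-filtered input panel of exactly L
loci. A consequence is that the drawn population mutation rate θ, while
recorded in every reference-table row, does not influence the conditioned
draw — the 1/x shape is θ-free once the number of polymorphic loci is
fixed — so θ acts as an inert nuisance in this implementation.

The sampled individuals are a fresh progeny cohort produced by the
generation-t adults. The cohort has size max(ne, S): progeny counts are
not bounded by the parental census size, and the method's validation
designs include S = 200 with priors whose lower bound is below 200. S
individuals are drawn from the cohort without replacement.

Priors: ne ~ discrete-uniform [lNe, uNe] (default [50, 150]; the model
supports [4, 400]), t ~ discrete-uniform [2, 8], θ log-uniform on
[4.8×10⁻⁵, 4.8×10⁻³] (the range spans two decades, making the log scale
the scale-neutral reading; a linear option exists).

Reference tables are bit-for-bit reproducible and worker-count invariant:
trial k always consumes the k-th spawned child of the root seed sequence.
Trials whose sample leaves the LD statistic undefined are redrawn from a
further substream (counted; a warning fires above 1% of trials).

## ABC step

* **Standardization**: each statistic is centered by the reference table's
  median and scaled by its raw MAD before the Euclidean distance.
  Without this, the distance would be dominated by whichever statistic has
  the largest numeric scale (ĥ, v̂h) and the information in r̂² (~1/S
  scale) would vanish. A statistic with zero MAD carries no distance
  information and is dropped with a warning. Raw distances remain available
  (`standardization="none"`).
* **Acceptance**: δ is the `acceptance_fraction` (default 0.02) quantile of
  the J distances; all records with d ≤ δ are accepted, ties included.
  Fewer than 20 accepted records is an error (a 5-covariate regression
  needs at least that); fewer than 100 draws a warning.
* **Adjustment**: weighted least squares of Box–Cox(ne), λ = −0.2, on the
  standardized statistics with Epanechnikov weights 1 − (d/δ)²; adjusted
  values are the fitted value at the target plus each record's residual.
  The Box–Cox transform stabilizes the regression across the prior's scale;
  its λ is part of the method's definition, not a tuning knob. Adjusted
  values are clipped to the transform's image of the prior bounds before
  inversion, then clamped into [lNe, uNe] — clamping rather than discarding,
  since discarding out-of-support samples would shrink intervals
  artificially. A rank-deficient weighted design (e.g. all accepted records
  share identical statistics) falls back to pure rejection with a warning,
  which makes rejection and regression modes agree exactly in that
  degenerate case. δ = 0 (target identical to records) gives uniform
  weights.
* **Summary**: weighted median and weighted 2.5%/97.5% quantiles by the
  inverted-CDF rule — sort samples, accumulate normalized weights, report
  the first sample whose cumulative weight reaches q.

## Filters

Fixed order: loci above the missing-data cutoff, then individuals above
theirs (computed over retained loci), then MAF. Removing bad loci first
avoids discarding individuals over loci that would be dropped anyway.
Missing-rate removal is strict (>); the MAF bound is inclusive (a locus at
exactly the cutoff stays). Removing all loci containing any missing data —
as one may want with genotyping-error-prone data — is the special case
`max_missing_locus = 0`. A result with no loci or fewer than two
individuals is a hard error naming the cutoff to relax.

## Validation protocol and what it shows

The recovery experiments (`abcne.experiments`, `scripts/acceptance.py`,
`tests/test_acceptance.py`) simulate target datasets at true Ne = 100 and
200 over grids of S ∈ {50, 100, 200} and L ∈ {40, 80, 160, 320} and
estimate each with a prior bracketing the truth ([50, 150] and [150, 250]).
Protocol choices:

* Target datasets come from the package's own simulator with
  `maf_floor = 0.05` and contain no missingness or genotyping artifacts,
  so the estimator runs with filters disabled and the same `maf_floor`.
  Filtering the target on *sample* MAF while the reference simulations stay
  unfiltered would compare conditioned with unconditioned statistics and
  make the filtered L replicate-specific; disabling the filters keeps the
  experiment well-specified and the reference table shareable. The filters
  themselves are exercised by the unit tests and remain the defaults for
  real data.
* Desk-scale budgets: J = 2,000 trials per reference table, one table
  shared by a cell's ten replicates (the table depends only on prior, S, L
  and seed); the in-suite version further reduces to two locus settings,
  five replicates and J = 1,000. At J = 2,000 and 2% acceptance each
  posterior rests on 40 draws, so per-run quantiles are coarse; the
  experiment-level averages over 40–120 runs are the meaningful outputs.
* Because the targets are drawn from the same process as the reference
  simulations, these experiments demonstrate calibration and precision of
  the *inference machinery* under a correctly specified model. They do not
  probe model misspecification on real data: linked loci, population
  structure, non-equilibrium ascertainment, or genotyping error are outside
  what passing these tests shows.

## Known limitations

* The posterior cannot leave the prior: with truth near or outside a prior
  bound the median is pulled inward and intervals pile up at the bound.
* Equal sex ratio, non-overlapping generations, neutrality and demographic
  stationarity within a trial are assumed; none are checked against data.
* The two-sex excess of Ne over census size (< 1 individual) is not
  corrected for, nor is the chromosome-number correction some downstream
  analyses apply to LD-based estimates.
* Runtime grows as S·L² per simulation trial through the all-pairs LD scan;
  beyond roughly 2,000 loci use `max_pairs` or thin the panel.
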