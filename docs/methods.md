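# Methods

This note records the statistical model behind `classnet`, the numerical
conventions adopted where the field's practice is ambiguous, and what the
synthetic-data generator does and does not emulate.

## Dyad universe and network types

All statistics run over the n(n−1) *ordered* off-diagonal dyads of an
n-child roster (a 16-child classroom has 240). Symmetric networks
(teacher ratings, observation counts) are stored mirrored so the same
machinery applies to every informant; a directed nomination network and
an undirected rating network are therefore comparable cell-by-cell
without collapsing the nomination's directionality. The diagonal is
formally undefined: it is stored as zero and masked out of every
statistic. Nonconsented children are excluded before matrix construction,
so the *effective classroom size* n_eff used by the chance threshold
equals the matrix dimension n.

Matrix order follows the header order of the input CSV, not sorted order,
and is canonical across all networks of a run; mismatched labels are a
hard error rather than a reorder, because silent reordering is the
classic source of spurious (non-)congruency.

## Binarization schemes

* **Rating cutoff** c ∈ {0,…,4}: tie iff rating ≥ c (inclusive).
* **Ratio thresholds**: r_ij = f_ij / Σ_k f_ik is the share of child i's
  observed interactions going to j; tie i→j iff r_ij ≥ t with t the
  chance level 1/(n_eff−1), twice chance, or a fixed proportion
  (conventionally 5%). The comparison is inclusive ("at or above"). The
  output is *directed* even from symmetric counts, because row
  normalization breaks symmetry; no automatic OR/AND symmetrization is
  performed. Children with zero observed interactions have undefined
  shares: they produce no outgoing ties and are reported in the log.
  Note chance > 5% exactly when n_eff < 21, so which scheme is more
  stringent depends on classroom size.
* **Frequency thresholds**: the reference distribution is the unordered
  off-diagonal pair frequencies, zeros included, each pair counted once
  (with zeros excluded a median of 1 would be unobtainable in sparse
  classrooms where just over half the pairs interact at least once). The
  half-median rule codes a tie *strictly above* half the median; with
  integer counts and a median of 1 this coincides with "observed
  interacting at least once". Percentiles use the nearest-rank convention
  (the ⌈q·m/100⌉-th order statistic), which yields integer cutoffs on
  integer counts; interpolated percentiles would produce fractional
  cutoffs that no count attains exactly. Percentile and fixed rules are
  inclusive.

Monotonicity (a stricter threshold never adds a tie) holds by
construction within every family and is property-tested.

## QAP inference

The congruency statistic is the Pearson correlation over the ordered
off-diagonal cells. The permutation scheme is the classic full-matrix
form: a uniform random node permutation is applied simultaneously to the
rows and columns of one matrix, which preserves its dyadic dependence
structure exactly; semi-partialling variants belong to multivariate QAP
regression and are out of scope. Conventions:

* p-values use the add-one rule (1 + #{r_π ≥ r_obs})/(1 + M), so the
  smallest achievable p is 1/(M+1) and the test is valid at any M;
* ties at the observed statistic count toward rejection (conservative),
  with a 1e−9 floating-point tolerance so an exactly tied permutation is
  never dropped by rounding noise in the correlation arithmetic;
* both one-sided (greater) and two-sided p-values are reported; the
  one-sided value is the headline number since congruency hypotheses are
  directional;
* M defaults to 10,000 and every result records its seed; an exhaustive
  n! enumeration (`qap_exact`, n ≤ 8) serves as the reference
  implementation for the Monte-Carlo test.

Degenerate networks (no off-diagonal variation) raise an error rather
than returning NaN: the correlation is undefined, and the variance of the
off-diagonal multiset is permutation-invariant, so the null is degenerate
too.

## Jaccard overlap

J = C/(A+B+C) over ordered dyads, where C = both-present, A/B =
present in exactly one. Both-absent dyads are excluded from the ratio but
reported, together with the full 2×2 decomposition; J is defined as 0
when no tie is present in either network. This is the present-tie
Jaccard, not the simple matching coefficient: including 0–0 agreements
would saturate sparse comparisons. For independent Bernoulli(d) networks
E[C] = m·d², E[A] = E[B] = m·d(1−d), so the components' ratio is
d/(2−d): J grows with density even under independence. This bias is
measured by simulation (d ∈ {0.1, 0.5, 0.9}, n = 100) in the acceptance
checks; congruency read from J should always be interpreted jointly with
the densities table the report emits.

## Bootstrap validity analysis

Per-child strength measures — in-strength of nominations (nominations
*received*), total rating strength, total observed interactions — are
correlated with outcome score vectors. Children are resampled with
replacement as units (case resampling; outcomes are child-level), 1,000
resamples by default, pairwise-missing entries dropped first, and
degenerate resamples (constant vector) redrawn and logged. Significance
is read from whether the 95% CI excludes zero.

The default interval is **BCa** (bias-corrected, accelerated via the
jackknife). The plain percentile interval is provided as
`ci_method="percentile"`, but at classroom sample sizes it is
anti-conservative for a correlation coefficient: in our calibration
simulations (bivariate normal, ρ = 0.6, n = 16, 1,000 resamples, 3,000
replicates) the percentile interval covered the true value 91.5% of the
time versus ~93–94% for BCa. Pearson correlation is the default; Spearman
is available (ranks are computed once before resampling, a standard
approximation at the jackknife step).

## Synthetic classroom generator

The generator draws a **latent affinity matrix**: children are
partitioned into `n_groups` balanced play groups, dyads get a
within-group or between-group per-cycle interaction probability, and each
dyad's value is jittered on the logit scale so blocks are heterogeneous.
Three conditionally independent measurements follow:

* **observation counts**: over `n_cycles` coding cycles each child is
  available with probability `availability_prob`; each jointly available
  unordered pair interacts with probability equal to its affinity, and
  counts accumulate. Hence E[count_ij] = n_cycles · p_avail² ·
  affinity_ij, a closed form the tests check, and counts can never exceed
  the joint-availability cycle count. This per-cycle dyadic Bernoulli is
  a deliberate simplification of a roster-scan protocol (one focal child
  observed at a time): it preserves the count marginals and the
  availability censoring that ratio thresholds are designed to absorb,
  which is what the pipeline exercises.
* **teacher ratings**: affinity plus Gaussian noise
  (`rating_noise_sd`) mapped through four fixed cutpoints onto 0–4 —
  the simplest mechanism with a single interpretable noise knob.
* **peer nominations**: directed Bernoulli with a logistic link,
  P(i→j) = σ(intercept + slope · affinity_ij).

Defaults (16 children, 4 groups, 44 cycles, availability 0.72,
within/between affinity 0.25/0.018, cutpoints (−0.03, 0.08, 0.18, 0.40)
with noise SD 0.06, nomination link −3.4 + 12·affinity) were derived from
the closed-form count expectation and the normal-ogive rating/nomination
links so that a typical draw lands near a nomination density of 11%, a
rating grand mean of 1.35 (SD 0.90) and a pair-count mean of 1.47
(SD 2.65) — the descriptive regime of a small preschool classroom.
Measured over 60 seeds the generator gives density 0.118, rating mean
1.34 (SD 0.97) and count mean 1.54 (SD 2.63). Availability is homogeneous
by default; `availability_sd > 0` switches to heterogeneous per-child
probabilities.

What the generator does **not** emulate: informant-specific bias
mechanisms (teacher salience or relationship effects), correlated errors
across informants, negative-interaction networks, non-stationarity across
observation days, and the discreteness of an actual roster scan. Passing
tests therefore demonstrate that the pipeline recovers structure and is
statistically calibrated under a clean measurement model — not that any
particular classroom's informants are congruent.

## Problem sizes and determinism

The test suite and the acceptance script use deliberately compact problem
sizes chosen to estimate each property with usefully small Monte-Carlo
error: 999–9,999 permutations per QAP call, 500 replicates for type-I
calibration, 300 replicates × 1,000 resamples for bootstrap coverage, 50
classroom seeds for the congruency rates, n = 100 for the Jaccard bias
curve. The QAP null is generated vectorised (all permuted off-diagonal
vectors gathered in one indexing operation), so these all run in seconds.
Every stochastic component takes an explicit seed; pipeline runs derive
per-call sub-seeds from the top-level seed, so reports are byte-identical
across reruns.

## Known limitations

* The QAP variant is bivariate full-matrix permutation only; no MR-QAP,
  ERGM or SIENA modeling.
* Jaccard comparisons mix directed and symmetric networks on the ordered
  dyad universe; a symmetric network's mirrored cells are counted twice,
  which matches the QAP convention but differs from unordered-pair
  counting by a factor that cancels in J itself.
* Ratings are assumed symmetric as stored; if a rater scored both
  directions of each pair, the reader requires an explicit symmetrization
  flag rather than guessing.
* The BCa acceleration uses the jackknife on the (possibly rank-
  transformed) data, the standard nonparametric estimate; at n < 5 it is
  unstable, and the minimum supported sample is 3 complete pairs.
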