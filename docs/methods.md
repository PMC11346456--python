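# Methods

## Data model

The unit of analysis is the antibacterial drug *class* — a family of
structurally or mechanistically related drugs treated as a single entity.
A timeline table holds, per class, three integer calendar years: first
discovery (required), first clinical use (optional) and first detection
of clinical resistance (optional). Years are integers because the
historical record has yearly resolution; fractional years are rejected
on input rather than silently truncated. A missing resistance year means
the class is right-censored at the chosen observation year: it
contributes resistance-free exposure, not an event. The default
observation year is the largest year appearing anywhere in the table,
since input tables do not carry an explicit horizon; it should be set
explicitly whenever known. Zero-length intervals (resistance detected in
the discovery year) are retained — pre-existing environmental resistance
makes them real events, not artefacts.

## Exponential time to resistance

Discovery-to-resistance intervals are modelled as exponential with
constant hazard λ (per year); the reported "clinical half-life" is the
median t½ = ln 2 / λ. Two fits are provided.

**Censored maximum likelihood.** The log-likelihood is
Σ_events (log λ − λ d_i) + Σ_censored (−λ d_i), maximised in closed form
by λ̂ = (number of events)/(total exposure). This is the statistically
correct treatment of censored classes. The library default includes
censored exposure; the pipeline's headline stage defaults to events-only
(`include_censored: false`), which reproduces a fit to the histogram of
realised times — the two options answer slightly different questions and
both are one flag away.

**Binned Poisson maximum likelihood.** Observed (uncensored) intervals
are histogrammed into half-open bins [i·w, (i+1)·w), default w = 5 years
(a conventional width for a ~90-year record with tens of classes), and
the count in bin (a, b) is treated as Poisson with mean
N (e^(−λa) − e^(−λb)). Because the bins span only up to the last
non-empty bin, probability mass beyond the sample maximum M is never
penalised; the small-width limit of this estimator therefore solves the
truncated score N/λ − Σd − N·M·e^(−λM) = 0 rather than the plain MLE
score. The two agree within a few percent once M ≫ 1/λ (in practice for
a few hundred events or more); the test suite pins both facts. If all
events fall in the first bin the likelihood increases without bound in λ
and the fit aborts with a diagnostic rather than returning a boundary
value.

**Uncertainty.** The confidence interval for t½ is a percentile
bootstrap over classes (resampling entries with replacement, censoring
flags preserved; default 1000 replicates; seed mandatory). Replicates
that draw no events carry no information about λ and are redrawn, with a
hard cap of 100 rounds. Simulation at the package's reference conditions
shows empirical coverage of the nominal 95% interval within [0.90, 0.99]
for ~40-class datasets. The bootstrap was chosen over profile-likelihood
or Fisher-information intervals for its robustness at small n and
because it requires no asymptotic assumptions; it is not asserted to be
the construction behind any previously published interval.

## Coupon-collector discovery model

Screening draws arrive as a homogeneous Poisson process at rate n per
year, starting t_lag years after the origin year t₀; each draw lands on
one of k classes uniformly at random, and a class is discovered at its
first draw. Conditional on m draws the expected number of distinct
classes is k(1 − (1 − 1/k)^m); marginalising m over its Poisson
distribution gives the exact expectation

    E[D(t)] = k (1 − e^(−n τ / k)),   τ = max(0, t − t₀ − t_lag).

A Poisson *rate* was preferred over a fixed draws-per-year schedule
because "a constant rate" describes an intensity, and because the
marginal expectation above is then exact (the mixture identity is a
test). The infinite-pool limit recovers linear growth at rate n.

**Fitting.** Yearly counts of newly discovered classes are treated as
independent Poisson variates with means equal to the yearly increments
of E[D(t)]. True increments are negatively correlated near saturation
(each discovery depletes the pool), so this is a composite likelihood;
it is unbiased in the mean and is what "Poisson maximum likelihood on
yearly counts" means throughout the package. The likelihood is maximised
over integer k from the observed class count to k_max (default 200),
integer t_lag from 0 to t_lag_max (default 60), and continuous n by
bounded scalar search (absolute tolerance 1e−8) at each grid point. Lags
that place a positive count before the sampling onset have zero
likelihood for every n and are pruned; ties break toward the smallest k,
then the smallest lag, making the search deterministic. The searched
ranges are recorded verbatim in the fit object.

Two numerical points matter. Yearly means are computed in incremental
form k e^(−aτ₀)(1 − e^(−aΔτ)), a = n/k, never by differencing the
cumulative curve: near saturation 1 − e^(−aτ) rounds to exactly 1 in
double precision and differencing would declare late-year counts
impossible. And the scalar search in n (likewise in the detection-side
half-life) is bracketed by a coarse log-spaced scan before bounded
refinement, because the likelihood basin can be narrow relative to the
stated bounds and an unbracketed bounded search can settle on a
shoulder.

**Identifiability.** t_lag is anchored by the origin year: the counts
window must start at t₀ (including the informative pre-discovery zero
years), otherwise lag and rate trade off along a ridge. The pipeline
uses the simulation origin when the data are simulated and otherwise
defaults t₀ to the first observed discovery year (in which case the
fitted lag is ~0 by construction and t₀ should be supplied explicitly
for a meaningful lag). k is weakly identified from the curvature of a
single realisation — typical spread is tens of percent at ~30 classes —
and is reported but not treated as a headline quantity.

## Dynamics: D, R and the not-yet-resistant repertoire

The default resistance curve lets every discovered class start an
independent exponential resistance clock at its discovery:

    R(t) = ∫₀^τ D′(s) (1 − e^(−λ(t−s))) ds,

evaluated by adaptive quadrature (absolute tolerance 1e−8); a closed
form of the same integral serves as an independent oracle in the tests.
This choice is mechanistically consistent with the per-class half-life
model and guarantees 0 ≤ R ≤ D ≤ k, hence U = D − R ≥ 0. An alternative
`literal_exponential` mode draws R(t) as a bare growth curve
min(E[D(t)], e^((t−t_R)/t½)); it has no mechanistic amplitude, so the
onset t_R defaults to the end of the lag phase for curve construction
and to the first non-zero resistance-count year when fitting. The
per-class hazard uses λ = ln 2 / t½ by default; a `reciprocal` flag
selects λ = 1 / t½ for users who want the literal rate-equals-reciprocal
reading — the two differ by a factor ln 2 ≈ 0.69 and the package always
reports which convention produced a number.

The detection-side half-life is fitted stagewise: discovery parameters
are estimated first and held fixed, then t½ is estimated by Poisson
maximum likelihood on yearly counts of first resistance detection, whose
model means are increments of R(t). Stagewise fitting mirrors the
separate roles of the two data columns and keeps each stage
interpretable; a joint five-parameter likelihood is out of scope. The
fit is deterministic — identical inputs give bit-identical estimates.

## Synthetic data

The simulator draws the generative process exactly as modelled: Poisson
draw times on (t₀ + t_lag, horizon], uniform class assignment, per-class
exponential resistance delays with median t½, and an optional
exponential discovery-to-use delay (default mean 8 years — a realistic
decade-scale development lag; this column is generative garnish and is
fitted by nothing). Continuous event times are floored to integer years
on output, matching the real tables' resolution; resistance falling
after the observation year is recorded as missing. A single
`numpy.random.Generator` seeded from the mandatory config seed drives
all sampling.

Reference conditions used throughout the tests and the acceptance
script: k = 30, n = 1.5 draws/year, t_lag = 28 years, t₀ = 1900,
t½ = 15 years, window 1900–2020 — a deliberately data-poor regime
(~30 classes) chosen to match the scale of the real historical record.
What passing tests show is that the estimators are correct and
well-calibrated *under the model's own assumptions*; real timelines
additionally contain curation choices (what counts as a class, first
report versus widespread resistance), non-uniform class discovery
probabilities, time-varying screening effort and reporting delays, none
of which the simulator emulates.

The distribution of simulated integer-year intervals is checked against
the exact discretised law of floor(t + E) − floor(t) (with the
within-year discovery-offset density implied by the discovery
intensity), not against the continuous exponential: an integer-valued
sample can never pass a continuous Kolmogorov–Smirnov test at n = 2000,
because the KS statistic is bounded below by half the largest atom mass.

## Test-oracle choices

Noise-free recovery checks feed the fitters integer counts obtained by
rounding the *cumulative* expected curve and differencing, which
preserves the total and the timing to within half a class. Rounding the
per-year means instead would flatten the sub-unit yearly means
(peak ~1.5/year) into a block of 0s and 1s whose genuine maximum
likelihood lies substantially away from the generating parameters — a
property of the rounding, not of the fitter, verified against a
brute-force grid oracle. The instant-resistance limit (R → D as
t½ → 0) is asserted after discovery saturation; mid-discovery the gap
D − R ≈ D′(t)/λ is irreducible, since freshly discovered classes need
one clock tick to become resistant.

## Known limitations

* Increment independence is an approximation near pool saturation; the
  fitted k inherits extra variance from it.
* The coupon collector assumes equal discovery probability per class; a
  weighted pool would stretch the late tail of D(t).
* No covariates: the resistance hazard is era-independent, although
  long use-delay outliers suggest shelf time modulates it.
* The bootstrap CI is percentile-based; at very small event counts
  (< ~10) its coverage degrades and profile methods would be preferable.
* k and n are jointly weakly identified from one realisation of D(t);
  only t_lag and the half-life are sharply recovered at the reference
  data size.
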