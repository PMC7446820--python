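# Methods

## Model and assumptions

`crneutral` simulates a closed community of `S` consumer species competing
for `K` abiotic, substitutable resources (the analysis fixes `K = S`).
Resources flow in at constant rates ρ_k and are depleted only by
consumption; consumers reproduce only by consuming and die at per-capita
rates η_i. The stochastic process is a continuous-time Markov chain over
integer abundances with four event types (inflow, death, consumption
without reproduction, consumption with reproduction); conversion efficiency
ε is the probability that a consumption event yields a birth. ε defaults to
1 — lower values only rescale time — but remains a parameter.

Species richness is maintained by a *speciation floor*: a species of
abundance 1 selected for death stays at 1 while the event is logged as an
extinction (turnover). This is the minimal stand-in for point speciation or
rare immigration; the "new" species inherits the old one's resource
profile, so analyses of extant dynamics are insensitive to the detail.

The mean-field counterpart replaces abundances by their expectations and
drops higher moments. Given any consumption matrix with positive row and
column sums, choosing ρ_k = r n Σ_j C_kj and η_i = ε r Σ_j C_ji makes the
uniform state (r·1, n·1) the coexistence fixed point; all simulations start
there unless a cold start is supplied.

## Simulation engine

The simulator is an exact event-driven (Gillespie) algorithm: waiting times
are exponential in the total rate and events are selected in proportion to
their rates — no tau-leaping or other approximation. Consumption events are
drawn resource-first (probability ∝ R_k (C N)_k), then consumer
(∝ C_ki N_i), which is algebraically identical to joint selection but lets
the per-resource weights be maintained incrementally at O(S + K) per event.
Category sums are recomputed from scratch every 2²⁰ events to cancel
floating-point drift. The inner loop is compiled with numba; the compiled
kernel's stationary law is tested against a brute-force linear solve of the
truncated master equation on a 1-consumer/1-resource system, and a pure
Python reference stepper exposes the same event logic transparently.

Every run is reproducible bit-for-bit from its inputs and one integer seed;
per-community seeds in ensembles are derived from (master seed, grid index,
replicate index), so serial and parallel execution give identical tables.

Times are reported in generations (1 generation = 1/η̄, the expected
individual lifespan). Snapshots are taken on a fixed generation cadence —
the original study recorded on a wall-clock cadence, which is
hardware-dependent; a generation cadence (default 50) is the reproducible
equivalent. Extinction analysis links each snapshot observation of a
species to that species' *next* logged extinction; observations with no
later extinction in the run are dropped (right censoring is ignored, which
slightly biases the longest waits downward).

## Spectral theory and thresholds

At the calibrated fixed point the Jacobian splits into a fast bulk — the
K − 1 pure resource relaxations plus two global modes coupling total
resource and total consumer biomass — and S − 1 slow consumer modes (the
drift directions; exactly zero in the neutral limit). `spectrum_split`
places the boundary at the largest multiplicative gap in the sorted
eigenvalue magnitudes (searching cut positions S − 2 … S), because a strict
"largest K magnitudes" partition necessarily strands one global mode in the
consumer bulk (the global modes form a conjugate pair, or straddle the
resource band when real), which would pin λ₊ at a fast mode and collapse
the separation ratio to 1. The strict count partition remains available via
`split="count"`. λ₊ is the most negative real part in the consumer bulk;
1/|λ₊| is the stabilisation timescale. For the study's parameterisations
the fast/slow separation exceeds a factor of 10 — a structural feature of
the bipartite consumer-resource architecture, not a parameter accident.

The drift timescale is T_n/η̄, where T_k is the expected extinction time of
a species of abundance k under the matched neutral birth–death process
(per-capita death 1, birth p, absorbing at 0):

    T_k = (1/(1−p)) ( p^{−k} B(p; 1+k, 0) + H_k + log(1−p) )

The product p^{−k} B(p; 1+k, 0) is evaluated as the combined series
Σ_{j≥1} p^j/(k+j), which is overflow-free and accurate for k well beyond
10⁴; at k = 1 the whole expression reduces to −log(1−p)/p, used as an exact
check, and the formula is validated against Monte-Carlo absorption times.

Setting 1/|λ₊| ~ T_n/η̄ yields the threshold scalings

    CV* ~ sqrt( S/(4n) · (1 − εr/(2n)) )                      (generalist)
    (Cd/Co)* ~ (1 + γ(S−1))/(1 − γ),  γ = (1/n)(1 − εr/(2n))  (specialist)

both defined up to a multiplicative constant (a relaxation *rate* converts
to a relaxation *time* only up to the chosen decay fraction); the package
therefore compares scalings, not absolute values, against simulations.

## Neutral baselines

The neutral SAD is Fisher's log-series P_k = α p^k/k, α = −1/log(1−p); p is
estimated by solving αp/(1−p) = mean abundance (the moment estimator), and
baselines always use the *realized* sample mean of the simulation under
test, not the calibration target, since realized means can drift from
targets. Short-timescale fluctuations use the exact transition law of the
subcritical linear birth–death process (Kendall's geometric-offspring
form), giving closed-form first two moments of n(t) | n₀ including the
absorbing state, hence var D(t) = Var[n(t)]/n₀² for D = (n(t)−n₀)/n₀. The
transition pmf and moments are cross-validated against each other and
against Monte-Carlo ensembles of the same chain.

## Detection pipeline

* **Goodness of fit** — discrete Cramér–von Mises statistic
  W² = n Σ_j (S_j − T_j)² p_j over abundance cells 1..max(sample) plus one
  aggregated tail cell. Because p is estimated from the sample, p-values
  come from a parametric bootstrap with re-estimation (default 999
  replicates; the scaled-down suites use 99–199), with
  p = (1 + #{W²_boot ≥ W²_obs})/(n_boot + 1). A fit "succeeds" when
  p > 0.05. Type-I error is verified to sit in [0.03, 0.08].
* **Threshold** — logistic regression of per-community success on the
  non-neutrality index; the threshold is the index at 50% fitted success
  (configurable), with a delta-method standard error. Complete separation
  is detected and bracketed rather than fitted. For generalist ensembles
  the regression uses each community's *realized* matrix CV (normal draws
  are resampled away from negative values, so the nominal CV overstates the
  realized one).
* **Extinction times** — linked (abundance, wait) records binned in powers
  of 2; per-bin means compared with T_k at the bin's geometric-mean
  abundance; a through-origin regression (bins weighted by count) of
  observed on predicted waits gives the departure slope.
* **Fluctuations** — ensembles of histories from a common burned-in
  snapshot, sampled every generation; a species logging an extinction
  counts as zero thereafter. var D(t) is averaged over species with
  n₀ ≥ 20 (smaller n₀ are too noisy at feasible ensemble sizes).
* **Preference cosines** — consumers' empirical preference vectors are
  their per-resource consumption-event counts; the mean pairwise cosine
  carries a normal-approximation CI over pairs (pairs share species, so
  they are only approximately independent; the method is recorded in the
  output).

## Synthetic-data conditions and problem sizes

The simulator *is* the data generator; its defaults are the study
conditions. Reference experiments use S = K = 50 with n = r = 100 (the
observational-cosine experiment observes 250 generations — one average
species lifetime, T₁₀₀ ≈ 252 generations — after a 1500-generation burn-in,
about six lifetimes). Full-scale threshold ensembles (hundreds of
communities, 30,000-generation runs, n up to 500) are reachable through
config but not run by default; the shipped replications are scaled down:

* generalist threshold scan: S = K = 50, r = 20, n ∈ {90, 135, 200},
  9 communities per grid point, 4-point CV grids, normal-distributed
  entries (the uniform parameterisation caps CV at 1/√3, below the
  small-community thresholds). Below n ≈ 90 the 50-sample test's success
  curve is too flat for the crossing to be measurable, so smaller
  abundances are excluded from the scan;
* specialist scan: S ∈ {15, 25, 40}, n = r = 30, 14 communities/point;
* NNI comparison: the study's own S = K = 50, n = r = 100, 12
  communities/point, 100-generation recording after a 500-generation
  burn-in;
* extinction runs: 3 communities × 3,000 generations per condition;
* fluctuation ensembles: 100 histories × 100 generations, S = K = 20,
  n = r = 50.

Burn-ins for SAD experiments scale as 5n generations (the drift time T_n is
roughly 2.5n generations at these parameters, so this allows ≈ two full
drift times for the abundance distribution to forget the uniform initial
condition).

What the generator does *not* emulate: real communities have immigration,
environmental (not just demographic) noise, K ≠ S, correlated consumption
structure, and observational sampling error. Passing tests show the
*method* behaves as designed under the model's assumptions — they say
nothing about whether a field SAD that fits a log-series is actually
neutral, which is precisely the point of the study.

## Numerical choices and edge cases

* Uniform generalist entries use the symmetric support [μ−√3σ, μ+√3σ];
  cv > 1/√3 is rejected. Normal draws below zero are resampled (truncation
  would bias the mean); resample counts are recorded.
* Specialist matrices allow C_o = 0 (full specialisation, NNI = 1); the
  neutral limit C_d = C_o is allowed; C_d < C_o is rejected as undefined.
* log-series fitting requires sample mean > 1; all-ones bootstrap
  replicates count as maximally extreme.
* Degenerate logistic inputs (single outcome class) raise; complete
  separation returns a bracketed threshold with a NaN standard error and a
  flag.
* Abundance bins with a single record keep their mean but flag the SE as
  undefined.
* Spectrum bulks with separation below 2 warn rather than raise, keeping
  parameter scans alive through pathological corners.

## Known limitations

* The niche/neutral thresholds predict scalings only; the multiplicative
  constant is fitted empirically and, at reduced community sizes, test
  power (sample size = S) inflates measured thresholds relative to the
  large-S limit — visible as a shallower apparent scaling when S is small.
  The shipped scans use S = 50 for this reason.
* Right-censoring of extinction waits is ignored; the longest-abundance
  bins are biased low in short runs.
* The cosine CI treats species pairs as independent; the true correlation
  structure would widen it slightly.
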