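# crneutral

**When do stochastic consumer–resource communities look neutral?**

Ecological neutral theory — the assumption that all individuals have the same
birth and death probabilities regardless of species — predicts the log-series
species abundance distribution (SAD) seen in many high-diversity communities.
Yet real consumers plainly differ in their resource use. `crneutral`
implements a complete computational study of this tension: an exact stochastic
simulator of `S` consumers competing for `K` externally supplied resources,
deterministic spectral theory predicting when niche differences are strong
enough to leave a detectable imprint, closed-form neutral baselines, and the
statistical pipeline that tries to tell the difference. It is aimed at
theoretical community ecologists and anyone studying the identifiability of
interaction structure from macroecological pattern.

## The model

The community state is integer abundances (N_i, R_k). Four event types define
a continuous-time Markov chain:

    T(R_k → R_k + 1)              = ρ_k                    resource inflow
    T(N_i → N_i − 1)              = η_i N_i                consumer death
    T(R_k → R_k − 1)              = (1 − ε) R_k Σ_j C_kj N_j
    T(R_k → R_k − 1, N_i → N_i+1) = ε R_k C_ki N_i         consumption (+birth)

with a *speciation floor*: a species at abundance 1 selected for death stays
at 1 and the event is logged as an extinction (turnover). The K×S consumption
matrix `C` encodes niche structure. Two departures from the neutral limit
(all entries equal) are studied: **generalist** (i.i.d. entries with
coefficient of variation CV) and **specialist** (preferred diagonal `C_d`,
off-diagonal `C_o`). Inflow and mortality rates are calibrated so the
mean-field model

    dR_k/dt = ρ_k − R_k Σ_j C_kj N_j
    dN_i/dt = ε N_i Σ_j C_ji R_j − η_i N_i

has the uniform fixed point (r·1, n·1).

Linearising at that point splits the Jacobian spectrum into a fast resource
bulk and a slow consumer bulk; λ₊, the most negative consumer-bulk
eigenvalue, sets the niche-stabilisation timescale 1/|λ₊|. Comparing it with
the neutral drift-to-extinction time T_n/η̄ yields threshold scalings (up to
a multiplicative constant):

    CV_threshold    ~ sqrt( S/(4n) · (1 − εr/(2n)) )        (generalist)
    (Cd/Co)_thresh  ~ (1 + γ(S−1)) / (1 − γ),  γ = (1/n)(1 − εr/(2n))

Below threshold, drift wins and the community *looks* neutral: log-series
SADs (tested with a discrete Cramér–von Mises bootstrap test), extinction
times matching the neutral closed form T_k, and abundance fluctuations
var D(t) matching a subcritical birth–death process.

## Worked example

```python
from crneutral import (build_specialist_matrix, calibrate_community,
                       run_simulation, Schedule, cvm_discrete_test)

C = build_specialist_matrix(50, Cd=1.0, Co=1.0)        # neutral limit
params = calibrate_community(C, n=100, r=100, eps=1.0)
traj = run_simulation(C, params, Schedule(burn_in=1500, runtime=250,
                                          cadence=250), seed=11)
sad = traj.N[-1]                                        # final snapshot
res = cvm_discrete_test(sad, n_boot=199, seed=3)
print(round(res.p_hat, 4), round(res.p_value, 2))
```

prints

```
0.9985 0.54
```

the log-series parameter fitted from the snapshot's mean abundance
(`p ≈ 0.9985`, i.e. mean ≈ 100) and the bootstrap p-value 0.54: the neutral
community's SAD is, as it should be, indistinguishable from a log-series.
A specialist community with `Cd/Co` far above threshold yields p-values
below 0.05 — the fit is rejected.

The same pipeline at scale is driven by the CLI:

```bash
crneutral sad-ensemble config.json out/     # fit-success curve + threshold
crneutral cosine-obs out/ --s 50 --n 100 --r 100 --window 250
```

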