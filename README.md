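# relclock

Relative divergence-time estimation two ways — a fast, deterministic
relative-rate framework (RRF, RelTime-style) and a Bayesian autocorrelated
CIR relaxed clock — together with the diagnostics needed to see *when the
fast method silently stops relaxing the clock*, and to audit the joint
time prior whose truncation by fossil calibrations can predetermine
absolute dates.

It is written for molecular-clock methodologists and for anyone dating
deep phylogenies (the motivating case is the age of the animals, where
relative-dating shortcuts and diffuse root priors have produced
conclusions differing by half a billion years).

## What is inside

| module | contents |
| --- | --- |
| `relclock.treeio` | strict binary `Phylogeny` (preorder ids), `Chronogram`, Newick/FASTA/PHYLIP I/O, MRCA resolution, calibration TSVs |
| `relclock.simulate` | birth-death timetrees conditioned on tip count, CIR rate histories, Poisson / JC-alignment branch-length noise |
| `relclock.rrf` | tip-averaged lineage depths with `Var(b)=b/L` error propagation, SE-driven parent/child rate merging (`z_merge=2`), median-normalized rates, relative times |
| `relclock.cir` | CIR stationary/transition log-densities (overflow-safe Bessel assembly), closed-form moments, exact noncentral-chi-square simulation |
| `relclock.timeprior` | uniform-order base prior, gamma/exponential/fixed root densities, 5% soft bounds, prior-only MCMC, specified-vs-effective (truncation) reports |
| `relclock.mcmc` | posterior MCMC over ages, node rates and CIR hyperparameters (relative and calibrated absolute modes), numba-compiled core, tracecomp-style convergence checks, mean + 95% HPD summaries |
| `relclock.diagnostics` | chronogram regressions (R²), collapse index/depth, SE profiles, prior-shift tables |
| `relclock.experiments` | the packaged study designs: collapse contrast, HPD coverage, truncation toy oracle |

The core statistical objects: branch rates under the CIR diffusion
`dr = θ(μ−r)dt + √(σ²r) dW` (stationary Gamma(2θμ/σ², 2θ/σ²), exact
noncentral-χ² transitions, branch rate = mean of endpoint node rates);
RRF merging when `|D(c)−H(v)|/√(Var D + Var H) < z`; and the joint time
prior `root density × uniform-order base × soft-bound factors`, whose
marginals are obtained by running the MCMC with the likelihood switched
off.

## Worked example

Simulate one 16-taxon dataset under the CIR clock (root age 1, θ=1,
σ²=0.5, Poisson branch noise) at two alignment lengths, then date it with
both engines:

```python
import numpy as np
from relclock import simulate, rrf, mcmc, timeprior, diagnostics
from relclock.treeio import Chronogram

for L in (100, 2000):
    truth = simulate.simulate_dataset(simulate.SimulationConfig(n_tips=16, L=L, seed=42))
    rates, rrf_chron = rrf.reltime(truth.observed, L=L)
    idx, _ = diagnostics.collapse_metrics(rates, rrf_chron)
    res = mcmc.run_mcmc(truth.observed, timeprior.TimePriorSpec(timeprior.FixedRoot(1.0)),
                        mode="poisson", L=L, n_samples=20000, seed=1, check=True)
    bayes = Chronogram(truth.observed, np.zeros(truth.observed.n_nodes))
    for _, row in res.summary().iterrows():
        bayes.ages[int(row.node_id)] = row["mean"]
    print(L, idx, diagnostics.compare_relative_ages(rrf_chron, truth.timetree.relative()).r2,
          diagnostics.compare_relative_ages(bayes, truth.timetree.relative()).r2)
```

Output (reformatted):

```
L=100:  merged 30/30 branches, collapse index 1.00, RRF-vs-truth R2 0.808, Bayes-vs-truth R2 0.954
L=2000: merged 24/30 branches, collapse index 0.29, RRF-vs-truth R2 0.986, Bayes-vs-truth R2 0.996
```

At 100 sites the depth standard errors swamp every parent/child rate
contrast, the RRF merges **all** branches onto the median rate — a
strict clock it was never asked to assume — and its relative ages
degrade (R² 0.81 against truth), while the Bayesian CIR clock keeps
relaxing rates and holds R² 0.95. With 2,000 sites the merging recedes
and the two methods agree. The `maxdiff`/ESS line printed by
`check=True` is the tracecomp-style convergence report for the two
chains.

The prior side of the story, on a 3-tip toy:

```python
from relclock import experiments
print(experiments.toy_truncation_exact_mean())        # 2237.1
marg = experiments.toy_truncation_mcmc(seed=1)
print(marg.root_report()["effective_mean"])           # ~2237 (MCMC)
```

A root calibrated with a "vague" Exp(mean 1,000 Ma) density, plus a
single hard minimum of 800 Ma on a descendant, yields an *effective*
root prior with mean ≈ 2,237 Ma: truncation more than doubles the
nominal mean before any data are seen.

A CLI mirrors the library: `relclock simulate | reltime | prior | date |
diagnose` (see `relclock --help`).

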