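# Methods

`relclock` implements two routes from branch lengths (expected
substitutions per site) to divergence times on a fixed rooted binary
topology, plus the machinery needed to compare them and to audit the
priors that absolute dating rests on. This note records the models, the
conventions, the numerical choices, and what the synthetic experiments do
and do not establish.

## 1. The relative-rate framework (RRF)

The RRF (`relclock.rrf`) is a deterministic, RelTime-style scheme. It is
a documented variant built from four pieces; fidelity to any particular
program's internals is not claimed.

**Lineage depths.** For tip `c`, `H(c) = 0`; for an internal node `v`
with children `x, y`, the lineage depth of a child is `D(c) = b(c) + H(c)`
and `H(v) = (D(x) + D(y))/2` — the tip-averaged expected number of
substitutions below `v`. Branch-length sampling variance is modeled as
`Var(b) = b/L` (Poisson substitution counts at alignment length `L`) and
propagated through the same recursion:
`Var D(c) = b(c)/L + Var H(c)`, `Var H(v) = (Var D(x) + Var D(y))/4`.

**Rates, top-down.** Each child lineage receives a raw rate factor
`rho(c) = D(c)/H(v)`; branch rates are the running product of the factors
down from a virtual rate of 1 above the root.

**SE-driven merging.** Parent and child get the *same* rate when their
depths are statistically indistinguishable:
`|D(c) − H(v)| / sqrt(Var D(c) + Var H(v)) < z_merge` (default 2,
roughly a two-sided 95% test). The covariance between `D(c)` and `H(v)`
(which contains `D(c)`) is deliberately ignored; this inflates the
denominator and is conservative *toward* merging. With infinite `L` the
test degenerates to exact equality. A zero-depth lineage or subtree
carries no rate signal and is merged to its parent with a warning.

**Median normalization and times.** All branch rates are divided by
their median (ties: mean of the two central values), so a fully merged
tree carries rate 1 everywhere. Relative node ages follow from
`t(v) = mean over children of (t(c) + b(c)/r(c))`, rescaled so the root
is exactly 1. The per-branch SE reported is the delta-method SE of the
local rate ratio, `rho · sqrt(Var D/D² + Var H/H²)`, on the raw
(unnormalized) scale.

**Behavior worth knowing.** (i) On any tree whose branch lengths are
exactly proportional to durations, the RRF returns all rates 1 and the
true relative ages — the clock identity. (ii) As `L` falls, merges can
only increase, and at very small `L` the entire tree collapses onto a
single strict-clock rate: this information-starved collapse is the
mechanism the comparison experiments exercise. (iii) Under this
independent-noise variance model, depth averaging makes the *relative*
error of deep lineage depths saturate while the depths grow, so the
rate-ratio SE is largest on short tipward branches and smallest rootward.
Real alignments violate the independence assumption (all branch estimates
share one alignment and one substitution model), which is how SEs that
grow toward the root can arise in practice; that regime is outside the
simulated-noise model used here. (iv) The averaging recursion for
relative times does not enforce parent-older-than-child on noisy,
clock-violating data; diagnostic code treats RRF chronograms as point
estimates, not as validated chronograms.

## 2. The CIR relaxed clock and Bayesian dating

Node rates evolve along the tree as a Cox–Ingersoll–Ross diffusion
`dr = theta (mu − r) dt + sqrt(sigma2 r) dW` (`relclock.cir`):
mean-reverting, strictly positive under the Feller condition
`2 theta mu ≥ sigma2`, with stationary law
Gamma(`2 theta mu/sigma2`, rate `2 theta/sigma2`) and a noncentral
chi-square transition law, which gives exact simulation and closed-form
transition densities. `sigma2 → 0` is the strict-clock limit — the
legitimate, parameterized analogue of the RRF's involuntary collapse.
The rate of a branch is the arithmetic mean of its endpoint node rates,
in both the simulator and the likelihood, so generation and inference
share one convention. In relative mode `mu` is fixed to 1 and the root
age to 1, which resolves the rate–time scale non-identifiability.

The posterior (`relclock.mcmc`) combines: the branch-length likelihood
(Poisson counts `K = b_hat L` with mean `r d L`; or Felsenstein pruning
under JC(+discrete-gamma) for sequence data; or a delta "exact" mode used
only for likelihood-level tests), the CIR process density (stationary at
the root, transitions along edges), the joint time prior (below), and
hyperpriors `theta ~ Exp(1)`, `sigma2 ~ Exp(1)` truncated to the Feller
region. These hyperpriors are this package's declared defaults; they are
deliberately weakly informative on the O(1) relative-rate scale.

**Proposal mixture.** Node-age slides (window-uniform and adaptive local
steps), single-rate lognormal multipliers, log-scale hyperparameter
walks, and — in absolute mode — root scale moves with all-ages rescale,
an independence rescale that redraws the root age from its calibration
density, and a joint rates-vs-ages trade-off scale. Three further move
families are essential for mixing and deserve explanation. The posterior
of a relaxed clock has soft ridges: branch lengths `r·d` are well
determined, but times and rates trade off along them, jointly across
whole clades. The sampler therefore includes

* a *compensatory move*: shift one node age and re-solve the node rates
  of its subtree so every branch length is preserved exactly (the
  cascade terminates at the tips; the Jacobian is the product of the
  three adjacent duration ratios);
* a *subtree scale*: ages × `s` and rates ÷ `s` inside one subtree,
  which preserves every internal branch length exactly because both
  endpoints of each branch scale together (principal-component analysis
  of slow chains shows exactly this subtree-block ridge);
* a *global stretch*: a power transform `t → t_root (t/t_root)^gamma`
  of all internal ages with per-branch rate rescaling `r → r d/d'`.

Proposal scales adapt toward ~30% acceptance during burn-in only
(detailed balance holds for all retained samples). Burn-in is 20% by
default, two chains are mandatory, and full traces are kept.

**Engines.** The reference implementation is pure Python with cached
per-edge terms. The production engine (`relclock._engine`) is the same
move set compiled with numba, with a hand-written `log I_q(z)`
(`relclock._bessel`: ascending series, large-argument Hankel expansion,
and Olver's uniform large-order asymptotics; validated to <1e-6 relative
error against an independent library implementation over
q ∈ (0.01, 250), z ∈ (1e-8, 1e4)). Tests cross-validate the two engines
both state-by-state (identical log-posterior values) and
distributionally. The compiled engine covers Poisson and prior-only
modes; sequence-likelihood runs use the Python engine.

**Convergence.** Chains are compared tracecomp-style: for every
monitored scalar (internal node ages, hyperparameters, mean rate) the
relative difference of chain means `|m1 − m2| / pooled sd` must stay
below 0.1 and the summed per-chain ESS above 100. ESS uses Geyer's
initial monotone positive sequence estimator on the FFT autocovariance.
Summaries report posterior means and shortest-interval 95% HPDs by
sorted-window minimization over pooled post-burn-in samples.

## 3. The joint time prior and truncation

The prior on node ages (`relclock.timeprior`) multiplies (i) a base
density — uniform-order statistics: non-root internal ages i.i.d.
U(0, t_root) restricted to ancestor-older-than-descendant order, i.e.
∝ `t_root^−(n−1)` on the feasible region; (ii) a root calibration density
(gamma by mean/sd, exponential by mean, or a point mass for relative
dating; a gamma with sd = mean has shape 1 and *is* the diffuse
exponential); and (iii) soft-bounded fossil calibrations: inside a bound
the factor is 1; outside, an exponential tail starting at the stated
tail mass (default 5%, halved per side for min+max pairs) with decay
scale 0.1 × bound, continuous at the bound; tail mass 0 makes a bound
hard.

Because ancestors must predate descendants, internal calibrations
*truncate* what other nodes — the root above all — actually receive.
The effective (marginal) prior of each node is therefore obtained by
sampling the prior alone ("MCMC with no data"): Metropolis-within-Gibbs
age slides plus, when the root is free, a scale random walk and the
independence rescale, which draws the root i.i.d. from its calibration
density whenever no calibration factor interferes. The diagnostic
surface reports specified vs effective means and intervals, the shift in
Myr, and a flag for intervals carrying less than a stated cumulative
probability (default 0.025) in the effective marginal.

A closed-form anchor is kept alongside the sampler: on the 3-tip tree
with root `T ~ Exp(m)` and a hard minimum `t_min` on its single interior
node, `P(accept | T) = (T − t_min)/T`, so the marginal root mean is
`m e^{−a} / (e^{−a} − a E1(a))` with `a = t_min/m` — 2,237 Ma for
`m = 1000`, `t_min = 800`, an inflation of the nominal 1,000 Ma mean by
a factor of 2.2 from a single minimum bound. The prior-only MCMC is
required to reproduce this number within Monte-Carlo error, and to
reproduce the specified root density exactly when no internal
calibration exists.

## 4. Synthetic data

`relclock.simulate` generates the study datasets: birth-death timetrees
conditioned on tip count by rejection (forward simulation from the root
split; extinct runs rejected; the present is placed at the end of the
waiting interval in which the target count is first reached; extinct
lineages pruned, unary nodes suppressed; ages rescaled so the root sits
at the configured age, attempt cap 10,000), CIR node-rate histories
(root from the stationary law, children by exact transitions), and
branch-length noise: `poisson` (counts at length `L`, reproducing
`Var(b) = b/L` exactly — the closed loop with the RRF's variance model),
`alignment` (JC sequences simulated node by node; per-branch estimates
from the JC-corrected mismatch fraction between the simulated endpoint
sequences), or `none`.

Defaults are the study conditions used throughout: 16 tips, relative
time scale (root age 1), CIR(theta=1, sigma2=0.5, mu=1) — stationary
rate CV 50%, autocorrelation time equal to the root age — L = 5,000
sites of Poisson noise, pure birth at rate 1. The collapse experiment
uses 64 tips and contrasts L = 100 with L = 100,000 on one tree.

What this generator does *not* emulate: correlated branch-length errors
from a shared alignment and model misspecification (hence the SE-depth
direction discussed above), site-heterogeneous substitution processes,
fossil tips, and topology error. Conclusions from passing tests are
about the estimators under their stated noise model, not about any real
alignment.

## 5. Calibration of the experiments themselves

Two design points were genuinely open and are settled as follows.

**Coverage protocol.** 95% credible intervals provably cover 95% of
truths only when truths are drawn from the prior the sampler uses.
The default coverage experiment therefore draws node ages from the
uniform-order prior on a birth-death topology (simulation-based
calibration); measured coverage is ~0.92–0.96 across seeds and tree
sizes, and ~0.958 on 6-tip trees where mixing is easy. Setting
`ages_from_prior=False` instead takes the birth-death simulator's own
node ages, which are systematically younger than the uniform-order
prior; coverage then plateaus around 0.83–0.91 *regardless of chain
length*. That gap is not a sampler defect: it measures how strongly
node-age posteriors under a relaxed clock remain prior-sensitive even
with long alignments, because rates and times are only jointly
identified — the same fact that makes the choice of time prior, and its
truncation by calibrations, decisive in absolute dating.

**Collapse metric.** The collapse index is the fraction of nonterminal
branches whose median-normalized rate equals 1 within 1e-6 (merging
produces exact equality, so the tolerance is tight). Under
autocorrelated rate variation the merge *fraction* at L=100 reaches
~0.9, but every unmerged branch re-anchors its whole subtree on a new
rate value, so the index equals the largest root-connected merged
fragment and sits far below the merge fraction. The index contrast
across L (large at small L, 0 at large L) is the robust signature; a
fixed high absolute index at a fixed L is not, and the collapse-depth
statistic is likewise reported descriptively only.

## 6. Numerical choices and degenerate inputs

* Newick round trips write 12 significant digits; trees must be strictly
  binary (polytomies are an error, never silently resolved) with lengths
  on all non-root branches and unique tip labels.
* CIR densities are assembled in log space; naive Bessel evaluation
  overflows for small time steps. The ergodic limit (`u → 0`) falls back
  to the stationary density analytically.
* Poisson likelihood terms clamp the mean at 1e-300 to keep zero-count
  branches finite; exact-mode comparisons use atol 1e-12.
* Sampler caches (per-edge likelihood and process terms) are refreshed
  every 500 sweeps to bound floating-point drift from the
  likelihood-preserving moves.
* Degenerate RRF inputs (zero-depth subtrees, zero-length lineages) are
  merged to the parent rate with a `RuntimeWarning`; infinite SEs are
  excluded from SE profiles with a reported count.
* HPD intervals are the shortest single interval; on multimodal samples
  this is still a single interval by construction.

## 7. Known limitations

* The RRF variant here is one defensible reading of a scheme whose
  published description omits formulas; only its qualitative contract
  (median-1 normalization, clock identity, information-starved merging)
  should be relied on.
* Absolute-mode dating has been exercised on toy trees and prior-only
  runs; large calibrated analyses will be slower to converge and should
  be checked with the built-in tracecomp report.
* The base time prior is uniform-order only; a birth-death base density
  is not implemented (the gap matters when reproducing literature priors
  exactly).
* Alignment-mode likelihood is JC(+Gamma) without pattern compression,
  intended for desk-scale validation, not production phylogenomics.
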