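# Methods

## The quantity of interest

For a gene measured across single cells, let `M` be the mean protein number
and `CV²` the squared coefficient of variation. Across many *E. coli* genes
in balanced growth, noise and mean follow the scaling

    CV² = Ω / M,

with a common constant Ω. Ω is a signal-to-noise inflation factor: Ω = 1 for
Poissonian expression, Ω > 1 under translational bursting or promoter
locking. If protein numbers are Gamma distributed — the common empirical
finding, and the assumption this package makes explicit — then Ω is the Gamma
scale parameter, the shape is `M/Ω`, and the skewness follows with no free
parameters:

    S = 2·sqrt(Ω / M).

Two analytic results tie Ω to kinetics. For the one-rate-limiting-step model
(transcription at `k1`, translation at `k2` per RNA, RNA decay `λ1`, protein
decay/dilution `λ2`, all s⁻¹):

    Ω = 1 + k2/(λ1 + λ2),

so with `λ1 ≫ λ2` (the assumption check `RateSet.timescale_separation_ok`),
Ω is controlled by the translational burst size `k2/λ1`. For a telegraph
(ON–OFF) promoter that locks at `k₋` and unlocks at `k₊`, the Ω of the
perturbed condition relative to an always-ON reference is *proportional to*

    1 + k1·k₋/(k₊ + k₋)².

This factor is ≥ 1 everywhere, equals 1 when either `k₋ = 0` or `k1 = 0`,
and, at fixed `k₊`, peaks at `k₋ = k₊` with value `1 + k1/(4k₊)`. The
proportionality constant is never hard-coded; it is co-fitted wherever the
factor meets data (`dynamics.fit_kplus_model`).

## Stochastic simulation

`stochastic.simulate` runs Gillespie's direct method exactly (no tau-leaping,
no delays); dilution by division is folded into `λ2`. Five transcription
variants share translation and decay reactions:

* one step: `Pro → Pro + RNA` at `k1`;
* two step: `Pro → Pro*` at `k1a`, `Pro* → Pro + RNA` at `k1b`;
* ON–OFF: telegraph switching plus one-step transcription from ON;
* two-step + ON–OFF: locking interrupts the wait for the *first* initiation
  sub-step (the locked state is the promoter awaiting closed-complex
  formation);
* dual ON–OFF: each of the two sub-steps is independently lockable, with a
  shared (`k₊`, `k₋`) pair.

The composite variants are reaction-set compositions only: no published
parameterization exists for them, so they default to an even split of the
initiation time between sub-steps, and no moment closure is attempted for
them (simulation only).

Stationary ensembles pool states sampled every `sample_interval` seconds
after a burn-in (default 10% of the horizon) across `n_runs` independent
runs, promoter initially ON, RNA = protein = 0. Run `i` is seeded
`base_seed + i`, so scaled-down ensembles are bit-reproducible. Monte-Carlo
standard errors of mean, CV² and Ω are delete-one-run jackknife estimates,
which are robust to within-run autocorrelation.

**Mean matching.** To compare noise across variants at identical means, the
free production parameter is solved from the mean cycle time of the promoter.
With duty cycle `φ = k₊/(k₊+k₋)`: ON–OFF needs `k1 = k1_ref/φ`; two-step
needs `1/k1a + 1/k1b = 1/k1_ref` (harmonic mean); the composites stretch the
lockable waits by `1/φ`. These closed forms are not transcribed from any
published material — they are derived here and validated two ways in the test
suite: against `stationary_mean_protein` and against a direct stationary
solution of the chemical master equation on a truncated state space
(`tests/_cme.py`, scipy.sparse), which also checks CV² to 2%.

**Problem sizes.** The package default mirrors the reference ensemble
(10⁶ s horizon, 100 runs). Tests and the acceptance script use scaled-down
ensembles chosen as this package's own desk-scale conditions: 20 runs ×
10⁵ s (sampling every 10³ s) for the Ω-vs-closed-form checks, and 20 runs ×
10⁵ s at 500 s sampling for the relative-CV² ordering. At the slowest
parameter set (1/λ2 ≈ 3300 s) the 10⁴ s burn-in leaves a small transient
contribution in the pooled variance; it stays well inside the 3-SEM
Monte-Carlo tolerance those checks state, and vanishes at the full-scale
ensemble.

## Single-cell moments

Measured intensity is modeled as signal plus independent autofluorescence,
`X = T + B`, with `B` measured on unlabeled cells under the same condition.
Because cumulants of independent variables add, the first three corrected
moments are `μ_X − μ_B`, `v_X − v_B`, and `k3_X − k3_B` (unbiased
k-statistics). Independence of background and signal is an assumption; the
exact correction used for the original data is not published in the main
text, so cumulant subtraction is this package's explicit stand-in. Intensity
moments convert to molecule scale with a multiplicative factor (default 0.1
molecules per a.u.); CV², skewness, and between-condition Ω ratios are
invariant to this factor, Ω itself scales linearly with it.

A gene is *below the noise floor* when its corrected variance is smaller
than `floor_multiplier` (default 1) times the background variance; the floor
curve is `var_B/M²`. Flagged genes are excluded from all fits and reported
separately. Each sample needs ≥ 30 events (configurable) for moment
stability.

Cohort Ω is fitted by unweighted, no-intercept OLS of CV² on 1/M — exactly
the stated estimator, with alternatives (e.g. log–log) deliberately not the
default. The skewness comparison pairs empirical `m3/v^1.5` with
`2·sqrt(Ω/M)` per gene above the floor and reports the OLS slope and Pearson
r; genes failing the Gamma assumption announce themselves through this
comparison rather than being silently modeled.

## Ω dynamics

Relative Ω series (normalized to 1 at t = 0) are fitted with a sigmoid
`L/(1 + exp(−a(t − x0)))` whose steepness is *fixed* at `a = 0.1 min⁻¹`
(fitting `a` is available behind a flag, off by default). Given `a` and
`x0`, `L` enters linearly and is solved exactly, so fitting reduces to a 1-D
profile over `x0` evaluated on a 401-point grid spanning one range-width
beyond the data, then polished by bounded scalar minimization — multi-start
by construction, so local minima in `x0` are not an issue. A flat series
leaves `x0` unidentifiable and is flagged instead of fitted.

Order-0 vs order-1 polynomial fits are compared with the extra-sum-of-squares
F-test, `F = (RSS0 − RSS1)/(RSS1/(n−2))` on (1, n−2) degrees of freedom. Its
type-I error is verified by simulation (iid Gaussian noise around a constant)
to sit at the nominal 5%.

Four temperature-sensitive families for the unlocking rate are shipped:
`k₊(t) = κe^(−βt)` (exponential), `κ` (constant), `κ − βt` (linear, rejected
wherever it predicts `k₊ ≤ 0`), and `κ(1+t)^(−β)` (power). Only the winning
family of the original analysis is known (exponential); the other three are
documented stand-ins, pluggable when the true forms are available. Each
family is mapped through `c·(1 + k1·k₋/(k₊(t)+k₋)²)` with the scale `c`
solved in closed form, optimized by Nelder–Mead from a multi-start grid over
`(κ, β)`, and selected by R² (AIC is reported alongside for transparency).
With `k₋ = 0` the mapping is constant and the fit is flagged degenerate.

## Cohort classification

A gene is *cold-shock repressed* (CSR) iff `LFC_CS < 0` with `p < 0.05` AND
`LFC_CTRL ≥ 0` with `p < 0.05`, both at 20 min, p-values raw (no
multiple-testing correction) and all inequalities strict — exactly the
stated rule. Reporter candidates additionally require YFP-library
membership, optimal-condition expression above a configurable percentile
(the original cutoff is unstated), and `LFC_CS < −0.23` (≥ 15% RNA
reduction, since 2^−0.23 ≈ 0.85). Strong responses use `|LFC| > 0.8` for
cold shock and `> 0.4` for novobiocin — half, because the mean response to
15 °C was about twice the response to 50 µg/ml novobiocin.

Overlap statistics report the 2×2 counts, the sample odds ratio `ad/bc`
(flagged when a cell is zero), the conditional-MLE odds ratio, the two-sided
Fisher exact p, and the expected overlap `|A||B|/N` under independence.

The operon analysis builds all ordered (upstream, downstream) pairs of CSR
genes sharing an operon and regresses `|LFC_down|` on `|LFC_up|`. Its null
model preserves the per-operon distribution of CSR counts but fills each
operon with randomly drawn CSR genes, destroying co-membership; the ANCOVA
is the interaction-term F-test of `|LFC_down| ~ |LFC_up| × group` between
the real pairs and one null replicate.

Promoter pairs: two promoters pair when their TSS-to-TSS distance is
strictly < 1500 nt and the open interval between the TSSs contains no other
TSS, no terminator, and no third-party gene body. Coordinates are 1-based
inclusive; the interval excludes both TSSs; distance is `|TSS_a − TSS_b|` on
linear coordinates (circularity is ignored; the generator never places
fixtures across an origin). The two paired genes' own bodies do not
disqualify a pair — a convergent pair necessarily holds both bodies between
its TSSs. Geometry: opposite strands pointing apart = divergent, towards
each other = convergent, same strand = tandem.

Fitness variability compares the cohort's fitness CV² (= var/mean²) with
same-size random cohorts drawn without replacement, optionally stratified on
the cohort's function-tag composition; the cohort's empirical percentile in
the null distribution is the headline number. Fold enrichment is
`observed/expected` per tag with an upper-tail hypergeometric p — an
in-package replacement for ontology web services, operating on free-form
tags.

## Synthetic data: what it emulates and what it does not

`synth.SynthSpec` freezes every generative choice; all generators are pure
functions of (spec, seed). Defaults (chosen once, as this package's study
conditions): 300 genes in operons with size probabilities
{1: .55, 2: .20, 3: .12, 4: .08, 5: .05}; 20% planted CSR with `LFC_CS ~
N(−1.5, 0.3)` and control drift `N(+0.4, 0.05)`; observed LFCs and p-values
from a simulated 3-replicate t-test with replicate noise σ = 0.05, so effect
size and significance are coherent; half of the CSR cohort is
supercoiling-sensitive, drawing (LFC_CS, LFC_NOVO) from a bivariate normal
with ρ = 0.7 and novobiocin effects at half strength; in half of the
multi-CSR operons downstream members inherit the upstream effect plus
N(0, 0.1) noise; non-CSR TF genes respond with half-normal(0.5) short-term
LFCs that propagate to their targets' mid/long-term LFCs with coefficient
0.6. Flow cytometry: 30 reporter genes with means log-uniform on
[50, 5000] molecules, Gamma numbers with Ω = 25 in control and Ω × 1.26
under cold shock, 10⁴ events per sample, lognormal autofluorescence
(mean 100 a.u., sd 20 — right-skewed and non-negative, as real
autofluorescence is), scale factor 0.1.

Two generator choices exist specifically so that planted labels are exact
ground truth, and should be kept in mind when interpreting closure tests:

* responding non-CSR TFs are *induced* (positive LFC) — a repressed TF with
  a stable control would itself satisfy the CSR rule, making the label
  wrong, not the classifier;
* truly-null genes are conditioned, by rejection resampling of their
  short-term replicates, never to display the full CSR signature
  (significantly negative CS and significantly non-negative CTRL) by chance.
  Without this conditioning a null gene passes both raw 5% filters with
  probability ≈ 6×10⁻⁴, so "specificity = 1" would hold only for ~86% of
  300-gene datasets. The conditioning changes each null gene's marginal
  negligibly and is documented here rather than hidden.

What the generator does **not** emulate: read-level RNA-seq (the pipeline
starts at LFC tables by design), dispersion sharing across genes
(DESeq-style shrinkage), cytometry gating/compensation and cell-size
effects, genuine sequence–function relationships (promoter sequences carry
AT content but no motifs), and circular-chromosome effects. Passing closure
tests therefore demonstrate that the estimators recover the structures they
assume, at realistic sizes and noise levels — not that those structures are
correctly extracted from arbitrary real data.

## Numerical conventions and degenerate inputs

Zero production rates are legal and yield the all-zero ensemble (moments
flagged, CV² undefined at mean 0). Decay rates must be positive so total
propensity can never stall with molecules present. Ties at classification
thresholds resolve by strict inequality. `estimate_omega` refuses cohorts
with < 2 usable genes; `skewness_comparison` needs ≥ 3 genes above the
floor; `tf_propagation` needs ≥ 3 edges. All resampling (operon nulls,
fitness nulls) is seed-deterministic via `numpy.random.default_rng`.

## Known limitations

* The jackknife SEM treats runs as exchangeable; with very few runs (< 5) it
  is itself noisy.
* Cumulant subtraction can return negative corrected variances for dim
  genes; these are flagged, not repaired.
* The k₊ model families other than the exponential winner are stand-ins and
  make no claim to match any unpublished alternatives.
* ANCOVA compares the real pairs against a single null replicate; the full
  null-slope distribution is returned for anyone wanting a permutation-style
  comparison instead.
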