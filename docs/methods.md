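# Methods

## Task and data model

A session is a sequence of delayed-alternation trials on a T-maze. Six
scored events per trial (start-box placement, gate removal, branch point,
arm choice, reward, pickup) delimit six intervals — Delay, Run, Branch,
Choice, Reward, Pickup — that tile the session timeline: every Pickup
interval ends at the next trial's start-box time (the last trial's ends
after a configurable tail, default 5 s). All times are seconds on one
session clock and intervals are half-open `[start, end)`, so each instant
and each count bin belongs to exactly one interval. Incorrect trials lack
a reward event; their Choice interval runs to pickup. Analysis is
restricted to correct trials, excluding the first trial of each session
(always rewarded by design). Units are classified from the extracellular
waveform's peak-to-peak width: wide-spike (WS, > 200 µs; putative
pyramidal) units enter the GLM analyses, narrow-spike (100–200 µs) and
narrower waveforms do not.

Two composite intervals serve the interaction models: ExtendedDelay =
Pickup ∪ Delay (the pickup phase is effectively part of the delay, and the
union maximizes the data behind the many interaction terms) and Response =
Run ∪ Branch ∪ Choice.

## Conditional-intensity GLMs

Counts are taken in 250 ms bins; the history covariates are the counts of
the previous K = 10 bins (a 2.5 s window), computed over continuous session
time so lags cross trial and interval boundaries — this avoids artificial
zero-history edges at every trial start. The observation bin equals the
history bin, so counts and lags share one grid; μ is therefore a log
expected count per 250 ms, and rates in Hz are count/0.25. Bins whose full
history window precedes the session start, and bins outside analyzed
trials, contribute no likelihood terms (their spikes still feed the lags
of later bins).

Model families (columns after reference coding):

| id      | columns                                                             | count |
|---------|---------------------------------------------------------------------|-------|
| `h0`    | intercept                                                           | 1     |
| `inhom` | + 5 interval dummies (Delay reference)                              | 6     |
| `1b`    | intercept + stress + α₁..α₁₀ (baseline bins) + η₁..η₁₀ (stress bins)| 22    |
| `1a`    | 1b + 5 interval dummies                                             | 27    |
| `2`/`3` | intercept + γ₁..γ₁₀ + stress + composite dummy + α/η interactions   | 33    |

Interval dummies are coded against Delay because the intervals tile each
trial: a full dummy set plus intercept would be rank-deficient. The
baseline and stress sessions of one unit are fit jointly by default (the
within-day design); in a single-condition fit the off-condition history
columns are structurally zero and are dropped, as is a constant stress
column. Remaining rank deficiencies raise an error naming the dependent
columns.

Fitting is Poisson maximum likelihood with log link via IRLS
(statsmodels GLM; max 100 iterations, tolerance 1e−8), covariance from the
inverse Fisher information at the optimum (observed = expected for the
canonical link). Wald 95% CIs are formed on the log scale and
exponentiated, matching rate-ratio reporting. Any |coefficient| > 15
(a rate ratio beyond 3×10⁶) marks a separated/degenerate fit; such fits
are excluded from population aggregation with a logged count. Nested
models are compared with the deviance test (χ² with df = column
difference); the interaction models 2 and 3 are not nested in each other
and the comparison is refused.

## Synthetic sessions

The generator draws trial plans (arms alternate; an error repeats the
previous arm; delay duration exact, other interval durations uniform
around their means) and then simulates spikes from the same log-linear
conditional intensity the models fit: the intensity of each 250 ms bin is
computed from the counts of the previous K bins (so a bin's own spikes
first influence the next bin), and spikes are placed by Bernoulli thinning
on a 5 ms grid within the bin. A per-step spike probability reaching 1
raises an error.

Default study conditions: 41 trials per session (first trial excluded from
analysis), delay 10 s (task range 10–40 s), Run/Branch/Choice/Reward/Pickup
means 3/2/3/5/5 s with uniform jitter, error rates 7% (baseline) vs 35%
(stress, matching ~93% vs ~65% task accuracy), background μ = log 0.06 per
bin (≈0.25 Hz; ≈0.3 Hz effective with self-excitation, in the sparse range
typical of rodent PFC), baseline history gains decaying exponentially
1.5 → 1.05 across the ten lags with decay constant 0.35 s, stress gains
0.9× baseline. The decay constant matters for stability: a log-linear
self-exciting process is only conditionally stable, and the fixed-point
analysis of Σα against μ shows slower decays (τ ≳ 0.6 s at this gain
range) admit runaway cascades. Even at the defaults a cascade has small
positive probability on a finite session; `simulate_cohort` rejects such
realizations and redraws the unit from a deterministically spawned fresh
substream (≈0 observed per 600 sessions at the defaults), so cohorts are
conditioned on non-explosive realizations while remaining exact functions
of the seed. Interaction-model truths set a `history_scope` composite so
the history terms act only inside ExtendedDelay or Response, plus an
optional global γ.

What the generator does *not* emulate: refractory periods and bursting
beyond what the history terms produce, left/right arm rate differences,
slow nonstationarities (satiation, drift), electrode artifacts, and
spike-sorting errors. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness of the model to real-data violations of them.

## Rate analyses

PETHs align 5 ms-binned counts to interval onsets and report spike
probability per bin (count / trials). Because interval durations vary
across trials, interval profiles are temporally normalized onto 20 equal
sub-bins per occurrence (the resolution is a package choice) before
averaging; a stationary train yields a flat profile regardless of the
duration mix. Stress effects on interval rates are expressed as percent of
the baseline session's rate, computed within matched T-maze arms and
averaged over arms present in both sessions; intervals with zero baseline
rate are flagged undefined and excluded. Across units, a one-way ANOVA
tests for interval dependence and two-sided one-sample t-tests against 100
are Benjamini–Hochberg corrected at q = 0.05 (sidedness and q are package
choices).

## Goodness of fit

Time-rescaling: with Λ the cumulative fitted intensity (piecewise linear,
constant within bins; no sub-bin covariate interpolation), the quantities
z = 1 − exp(−ΔΛ) between consecutive spikes are Uniform(0,1) under a
correct model. The ordered z are compared to quantiles (j−0.5)/n with a
95% K-S band of half-width 1.36/√n (1.63 at 99%). Spike times keep their
5 ms resolution; exact ties within a bin are respaced evenly across the
bin to avoid zero rescaled intervals. No discreteness correction is
applied; at these rates the band is mildly conservative (measured ≈96–97%
pass under the generating model).

## Population statistics

Per-unit gains (not log-gains — rate ratios are averaged and tested
against 1.0) are aggregated as mean ± SEM per condition × lag over
non-degenerate WS fits. The baseline profile is fit with
g(x) = a + b·exp(−(x−Δ)/τ) by nonlinear least squares, multi-started over
τ ∈ {0.25, 0.5, 1, 2} s. Condition and history-lag effects are tested with
a two-way repeated-measures ANOVA (unit as subject); LSD post-hocs are
deliberately unadjusted paired t-tests per lag; per-cell one-sample tests
against 1.0 are BH-corrected. If both condition profiles are numerically
identical, the Condition F ratio is 0/0 and is reported as F = 0, p = 1.

A unit is flagged "delay-related" when its baseline delay-interval spike
count exceeds the counts produced by within-trial circular shifts of its
spike train (permutation p < 0.05, 1000 shifts); the flagged fraction is
compared to a configurable null proportion (default 5%) by one-proportion
chi-square. This rule is an explicit package construction — delay
selectivity has no unique definition — and both its level and the null
proportion are exposed in the API.

## Verification sizes

The acceptance tests run at: recovery, 20 units × (40+40) correct trials;
stress suppression, 20 replicate cohorts of that size; interaction
specificity, 10 cohorts of 12 units with interaction gains 1.08 over the
first 1.5 s of history (the magnitude reported for delay-specific SHPD);
deviance calibration, 500 null units with compact 12-trial sessions and
30 modulated units at full length; K-S calibration, 400 simulations under
the generating intensity and 50 under a 3×-misspecified one. The
acceptance script reports the same quantities at moderately reduced sizes.
One caveat on interaction specificity: because Models 2 and 3 share a
global history term, a truth whose history effect lives only in
ExtendedDelay leaks a small negative bias into Model 3's interaction
estimates (the global term averages over non-Response bins); at the
default rates this bias is well inside cohort SEM, and the per-lag FDR
tests against 1.0 are non-significant for ≈98% of lag-level tests.
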