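# Methods

`callgram` analyses combinatorial structure in the alarm-call sequences of a
forest monkey whose repertoire contains two acoustically discrete call
types — a short, low-frequency "A" call and a long, high-frequency "B"
call. The pipeline has five stages: a calibrated synthetic-corpus
generator, call-type clustering, inter-call-interval sequence segmentation,
grammar-rule/trie analysis, and context-specificity count models. This
note records the models, the tunable parameters, the numerical choices, and
what the synthetic corpus does and does not establish.

## Synthetic corpus generator (`callgram.synth`)

The generator emulates a playback/visual-model field study. Defaults
(all overridable in `GeneratorConfig`):

| parameter | default | unit | note |
|---|---|---|---|
| A call: max frequency | 1.00 ± 0.16 | kHz | truncated normal, ±3 SD |
| A call: duration | 0.12 ± 0.12 | s | floored at 1 ms |
| B call: max frequency | 7.72 ± 1.73 | kHz | truncated normal, ±3 SD |
| B call: duration | 0.58 ± 0.28 | s | |
| within-sequence gap | 0.12 ± 0.14 | s | log-normal, resampled to < 1 s |
| between-sequence gap | 22.8 ± 21.3 | s | log-normal, resampled to > 2 s |
| analysis window | 160 | s | per trial |
| gram repetitions | 1 + Geometric, mean ≈ 1.9 | — | gives mean length ≈ 4 calls |
| sequences per responding trial | 1 + Poisson(1.4) | — | mean 2.4 |

Interval laws are log-normal because the empirical interval distribution is
analysed on a log axis; the (μ, σ) on the log scale are moment-matched so
the *arithmetic* mean/SD equal the configured values. Feature laws are
normals truncated at ±3 SD, which makes the two classes' maximum-frequency
supports disjoint (A ≤ 1.48 kHz, B ≥ 2.53 kHz) and keeps durations
positive.

Sequence symbol strings are drawn from four pattern classes — `A{2,}`,
`(BA)+`, `A+(BA)+`, `(BA)+A+` — with stimulus-conditioned probabilities
(leopard → 0.72 on `(BA)+`; eagle → 0.36 on `A+(BA)+`; falling tree → 0.60
on `(BA)+A+`; the remaining mass uniform over the other classes, since only
the dominant shares are known). Response probabilities per playback
stimulus are 0.614 (leopard), 0.367 (eagle), 0.506 (tree), 0.0
(chimpanzee); visual models elicit responses for leopard only (0.667).
Each responding trial has exactly one caller. Trials whose drawn layout
overflows the window are regenerated and counted; this censors the long
tail of between-sequence gaps, so corpus-level between-gap means sit
~1–2 s below the configured 22.8 s even though the sampling law itself is
exact (the tests distinguish the two).

The repetition and sequences-per-trial laws are conventions: only their
means are constrained by the corpus statistics being emulated (mean
sequence length ≈ 4.2, ≈ 2.4 sequences per responding trial); the geometric
and shifted-Poisson shapes are the simplest laws with the right support.

What passing tests on this corpus show: the pipeline recovers structure
*when the generating assumptions hold* (discrete types, log-normal gap
mixture, one caller, regex-pattern sequences). They do not show robustness
to graded intermediate calls, multi-caller overlap, or measurement error in
acoustic features — none of which the generator models.

## Call-type clustering (`callgram.calltype`)

Features (duration, maximum frequency) are z-scored — the two axes are on
incommensurate scales — and clustered by classic Partitioning Around
Medoids (deterministic BUILD + SWAP, best-improvement exchanges, first
exchange in scan order on ties). The cluster count is chosen by maximal
mean silhouette over k = 2…10 (silhouette is undefined at k = 1; ties break
toward smaller k); singleton clusters get silhouette 0. With two clusters,
the lower-frequency cluster is labelled "A".

Two empirical caveats, both verified against independent references:

* On unstructured (single-blob) data, BUILD+SWAP can stop in a local
  optimum a fraction of a percent above the exhaustive-search best; the R
  reference implementation (`cluster::pam`) returns the identical medoids
  on the same data. On clustered data the global optimum is reached, which
  is what the equality-to-brute-force tests check.
* Under the default ±3 SD acoustic laws, roughly 1–3% of B calls fall on
  the A side of the optimal two-medoid Voronoi boundary in standardized
  space, so label agreement with the generating types plateaus at ~98–99%,
  not 100% — a property of the synthetic feature geometry, not of the
  clustering (the optimum itself is verified by brute force).

## Sequence segmentation (`callgram.segment`)

Inter-call intervals are silent gaps (offset → next onset) within a trial,
floored at 10⁻⁴ s. A K-component Gaussian mixture on natural-log intervals
is fitted by EM: unequal variances, SD floor 10⁻⁴ log-s, tolerance 10⁻⁸ on
the log-likelihood gain, ≤ 1000 iterations, best of 10 quantile-offset
initializations; the log-likelihood is asserted non-decreasing at every
step. The number of components is chosen by sequential parametric
bootstrap likelihood-ratio tests (K vs K+1 from K=1, α = 0.05, p-values
with the +1 convention so p > 0). Bootstrap refits use lighter EM settings
(3 starts, ≤ 300 iterations): null refits converge slowly and the tail of
the bootstrap statistic is insensitive to the final digits. Degenerate
refits are dropped and counted; more than 20% aborts the test.

Segmentation itself uses the operative field definition: a sequence is a
maximal run of ≥ 2 calls with consecutive gaps strictly below 1 s;
isolated calls are counted separately. The fitted posterior-0.5 crossing
between the two components (`boundary_s`, typically 1–2 s) is exposed as a
data-derived alternative threshold (`--threshold auto`).

## Grammar analysis (`callgram.grammar`)

Sequences are strings over {A, B}, length ≥ 2. Two corpus descriptions are
kept distinct: *sequence types* (exact string identity; used for
type/singleton counts) and *patterns* (the four regex classes plus
"other"). Three combinatorial rules are evaluated per sequence:

1. **A-Dominance** — B calls never outnumber A calls, #B ≤ #A. The
   non-strict form is the operative one: the modal two-call sequence "BA"
   (#A = #B) conforms, and membership in any of the four pattern classes
   then implies all three rules (verified exhaustively to length 10).
2. **A-Suffixation** — the final call is A.
3. **B-Singularity** — "BB" never occurs.

The trie aggregates sequences by prefix with per-node pass counts and
terminal (end-of-sequence) counts; the conservation law
`terminal + Σ child passes = pass` holds at every node and is
property-tested. Export is Graphviz DOT with depth as rank.

## Context-specificity models (`callgram.glmm`, `callgram.stats`)

Counts of sequences per trial and category level (initiation A/B; pattern
class; termination AA-/BA-gram) with explicit zeros are modelled as

    count ~ Poisson(exp(Xβ + log(N_tot + 1) + u_trial)),  u ~ N(0, σ²)

with treatment coding (references: category A / A-repetition / AA-gram,
stimulus eagle, location north). The offset `log(N_tot + 1)` uses every
sequence in the trial's window, including "other"-pattern sequences
(configurable). Inference is Laplace-approximate maximum likelihood: with
a scalar intercept and log link each trial's contribution reduces to
sufficient statistics (ΣY, Σe^{xβ+off}), so the inner mode solve is a
damped scalar Newton per group and the outer problem a quasi-Newton
optimization over (β, log σ). Standard errors come from the numerical
Hessian at the optimum. The Laplace likelihood is tested against a
non-adaptive 80-node Gauss–Hermite quadrature oracle and against the
Poisson GLM limit σ → 0 (statsmodels).

Complete separation (a cell with all-zero counts) is handled by an
optional zero-mean Gaussian ridge on the fixed effects (`ridge_sd`,
typically 1.0 on the log scale), equivalent to a weakly-informative prior;
the intercept is unpenalized by default (`penalize_intercept` extends it to
all coefficients). Likelihood-ratio tests, `drop1`-style per-term tests
respecting marginality (interactions first; main effects tested only after
removing non-significant interactions, in a refit), Tukey-style pairwise
contrasts of estimated marginal means (nuisance factors averaged uniformly
over levels; p-values calibrated by seeded Monte Carlo on the maximum
absolute standardized contrast under the joint normal, Holm fallback),
parametric-bootstrap percentile CIs, leave-one-trial-out stability ranges,
and a simulation-based dispersion check complete the inference toolkit.

The underdispersed-count family used in parts of the original analysis
(Conway–Maxwell–Poisson) is deliberately out of scope: the Poisson fit is
paired with the dispersion check, which flags both under- and
over-dispersion relative to the fitted model. One caveat, verified by
simulation: when groups have only one or two rows, the random-intercept
variance absorbs overdispersion into σ̂ and the simulation test is
(correctly, conditional on the fitted model) blind to it; the test detects
extra-Poisson noise when groups carry several replicate rows. The
dispersion statistic uses Pearson residuals against the *unconditional*
fitted means so the random-effect variance enters the observed and
simulated sides symmetrically.

## Problem sizes used in the checked claims

The repository's acceptance checks run at the study's own scales wherever
those are known: 921 + 325 calls for clustering, N = 1,119 intervals (918
within, 201 between — the split implied by 1,246 calls, 284 sequences and a
96.5% in-sequence share) with 199-replicate bootstrap LRTs, ≥ 5,000
generated sequences for the grammar counts. The simulation studies behind
the inference properties use 500 trials for parameter recovery, 500 null
replicates of 100 trials for LRT size, and 200 replicates × 99 bootstrap
refits of a two-coefficient model for CI coverage; the mixture-component
means are averaged over five replicate interval samples to damp the
Monte-Carlo noise of the ~200-draw between component.

## Known limitations

* No audio: acoustic features are simulated or supplied, never measured.
* No graded/intermediate call types; the generator draws discrete classes.
* One caller per trial; no overlap, no inter-group interaction.
* The Poisson family can misstate uncertainty for genuinely underdispersed
  counts; the dispersion check guards, but does not correct, this.
* Tukey adjustment is the multivariate-normal max-|z| calibration, not the
  studentized range (which is undefined for GLMM contrasts).
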