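# Methods

## Scientific setting

Couples practicing natural family planning (NFP) chart daily fertility
signs — basal body temperature (BBT) and cervical mucus symptoms and
secretions (CMS) — and concentrate or avoid intercourse in the fertile
days those signs delimit. Two questions arise from such charts: *where is
the fertile window in each cycle*, and *what drives the probability of
conception within it*, once observed covariates and unobserved couple
heterogeneity are both taken into account. `fecundlmm` implements both
stages: a symptothermal rule engine that reads daily charts, and a
two-state latent Markov (LM) model for the per-window conception
indicator. Because the motivating cohort data are not public, a
synthetic-data module reproduces the study conditions (cohort moments,
chart structure, outcome model) and every quantitative claim in this
package is established on that synthetic cohort.

## Fertile-window rule engine

**CMS scale.** Mucus is scored 0–4 from the (feeling, appearance,
secretion) triple: 0 = not registered, 1 = dry/nothing seen, 2 = damp but
nothing seen, 3 = damp with yellowish sticky secretions, 4 = wet and
slippery with transparent stretchy watery secretions. Level 0 is treated
as missing, never as dry.

**Three-over-six rule.** The thermal shift is the first day `d` such that
the temperatures on three consecutive recorded days `d, d+1, d+2` are each
strictly greater than the maximum of the six most recent recorded
temperatures before `d`. Missing and disturbance-flagged days are skipped,
not imputed; the three high days may be separated by at most
`max_gap_days` (default 1) missing calendar days; ties never qualify.
Fewer than nine usable temperatures leave the shift undefined. A
brute-force scan over all (six-before, three-after) windows is kept in the
test suite as an independent oracle. Note one consequence of the strict
baseline-maximum reading: an isolated spike that starts a failed rise
enters the "previous six" of later candidates and can block the shift for
six recorded days.

**Peak and window.** The mucus peak is the last day attaining the cycle's
maximum CMS level (at or above the opening threshold) not later than the
thermal shift; the rule itself cites the peak without defining it, so
this is a package definition. The window opens on the first day with CMS
≥ 2 (a threshold of 3 gives the less restrictive opening and is a config
option) and closes on the third recorded high-temperature day, where the
shift is re-detected among start days strictly after the peak. In
non-strict mode, charts whose shift cannot be placed after the peak are
salvaged with the whole-cycle shift and flagged (`salvaged`); how the
original algorithm handled non-conforming charts is not documented, so
this mode is a construction of this package and is off by default.

**Phases and filters.** The cycle is partitioned into pre-ovulatory
[1, open−1], fertile [open, close], post-ovulatory [close+1, end], all
closed intervals, days 1-based from the first day of menses. Cycles are
excluded in a fixed cascade: (1) any protected intercourse, (2) window not
delimitable (missing BBT/CMS information), (3) no intercourse act inside
the window; the filter report preserves per-stage counts. Per-couple model
covariates are the mean window length and mean intra-window intercourse
count over retained cycles plus the baseline covariates.

## The latent Markov model

The latent process U(1),…,U(T) is a homogeneous first-order Markov chain
on {1 = infecund, 2 = conception-prone} with initial probabilities π_u and
transition matrix π_{u|ū}. Given the state and covariates x, the
conception indicator Y(t) in fertile window t is Bernoulli with

    logit P(Y(t) = 1 | U(t) = u, x) = μ + α_u + x′β .

The pair (μ, α_u) is overparameterized, so α₁ = 0: μ is the infecund-state
baseline log-odds and α₂ ≥ 0 the conception-state shift (the sign
convention labels state 2). Covariates act only on the measurement model;
the chain carries the unexplained, time-varying heterogeneity between
couples. Responses are conditionally independent given the chain and x.
Sequences of unequal length enter through their own T_i; drop-out is
treated as ignorable.

**Estimation.** EM with scaled forward–backward recursions (exact
smoothed posteriors γ and joint posteriors ξ). The M-step updates π and
the transition rows in closed form from the expected counts, and the
measurement coefficients (μ, α₂, β) by Newton–Raphson on the
γ-weighted Bernoulli log-likelihood with a state-2 indicator column, run
to its own 1e-10 gradient tolerance — a full M-step, not a generalized-EM
step. Covariates are standardized internally and coefficients reported on
the original scale. Convergence: relative log-likelihood change below
1e-8 or 5,000 iterations.

**Initialization.** One deterministic start (uniform π, 0.8/0.2
diagonal-heavy transitions, measurement from a pooled logistic fit with
α₂ = 1) plus 20 random starts by default, each a multiplicative
perturbation of the deterministic start (probabilities rescaled by
U(0.2, 1.8) and renormalized; coefficients scaled by U(0.5, 1.5) with a
small additive jitter so near-zero coefficients also move; α₂ rescaled by
U(0.25, 2.5)). All starts run a bounded screening phase (100 EM
iterations); the best by log-likelihood is polished to full tolerance.
The likelihood is multimodal in mixtures of this kind, hence the
multi-start; the screening schedule is a cost choice that leaves the
selected optimum unchanged in all checks. If the polished fit has α₂ < 0
the states are relabeled (π and rows/columns of the transition matrix
permuted, μ ← μ + α₂, α₂ ← −α₂).

**Standard errors** come from the observed information: a central
finite-difference Hessian of the incomplete-data log-likelihood in an
unconstrained parameterization (logits of π₂ and of the off-diagonal
transition entries, raw measurement coefficients), mapped back to the
probability scale by the delta method. They are meaningful only at a
local maximum; non-positive-definite information triggers a warning and
NaN entries. **Decoding** is local: per-window argmax of γ, ties toward
state 1.

## Identifiability and the likelihood ridge

With a moderate support point (α₂ = 2 on the logit scale) the two states'
emission distributions overlap substantially, and the latent parameters
(π₂, α₂, μ, transitions) sit on a nearly flat likelihood ridge: fits with
π₂ anywhere between ~0.13 and ~0.37 can differ by less than one
log-likelihood unit at n = 5,000 when conception terminates a sequence.
Two consequences shape the package defaults:

- **Recovery experiments use complete sequences.** The recovery module
  simulates full T-window sequences (re-entry mode) rather than
  truncating at the first conception. This mirrors the motivating
  cohort, where women re-enter after a pregnancy — without post-conception
  windows the second row of the transition matrix is barely identified —
  and makes the replicate-mean estimates unbiased at the reference values.
- **The decline curve is computed under a single estimated model.** The
  model is fitted once by full multi-start EM at the largest requested
  window count, and its smoothed posteriors are evaluated on the nested
  sub-panels of windows 1..T. Refitting independently per T
  (`refit=True`, retained as an option) lets each fit land on a different
  point of the ridge, which destroys the comparability across T that the
  per-window averages require. The headline series averages γ_T(2) over
  couples still observed at window T; the variant averaging over all
  windows is also reported. On absorbing cohorts the risk set at later
  windows is selected toward the infecund state, producing the
  characteristic monotone decline.

## Synthetic cohort

The covariate generator draws woman's/man's ages from normals with the
cohort's published moments (30/3.98 and 32/4.72 years) truncated to
[18, 45] (the study enrolled women aged 18–40; the upper bound is ours),
window length and intercourse frequency from normals (12/3.12 days,
3/1.99 acts) truncated to (0, ∞) — truncation at zero raises the raw
intercourse mean to ≈3.27 — and previous pregnancy (≥1) and prior hormonal
contraception as Bernoulli(0.48) and Bernoulli(0.2957). The model
covariate for contraception is the *absence* indicator, matching the sign
reported for it. Previous pregnancies default to the binary form; a count
mode is not provided because the reference coefficients were estimated on
the binary form.

Outcome sequences are drawn from the LM model exactly as specified above;
conception is absorbing by default within one enrolment (pregnancy is the
dominant drop-out reason), with `absorbing=False` reproducing re-entry
cohorts. One global seed spawns per-couple substreams keyed by the couple
index, so a couple's data is invariant to cohort size.

Daily charts are a deliberately minimal emulation: a two-level BBT step
(36.5 °C + 0.35 °C) at a latent ovulation day (mean day 14, SD 1.5, cycle
length 28 ± 3 days clipped to [21, 40]) with i.i.d. Gaussian noise
(SD 0.07 °C), a stepwise CMS trajectory 1→2→3→4 peaking the day before
ovulation and collapsing to 1 at ovulation, daily Bernoulli intercourse,
and per-day missingness of BBT. The mucus onset is placed
`cms_onset_before_ovulation` days (default 8) before ovulation so the
rule-engine window length is 12 days for noiseless charts, matching the
cohort mean. Real BBT exhibits slow drifts, luteal-length heterogeneity
and autocorrelated baselines that this generator does not model; the
within-window intercourse pattern of the cohort was never published, so
the daily-Bernoulli choice is a stand-in, not a claim about behavior.
Passing tests therefore demonstrate correctness of the rules and
estimators under the stated generating process, not performance on real
charts.

## Problem sizes and numerical choices

The recovery experiment runs 20 replicates of 5,000 couples × 4 windows
with 20 random starts each; replicate-mean probabilities recover the
generating values to well within ±0.02 and coefficients to within
Monte-Carlo error. The analysis scripts use an 800-couple absorbing
cohort — large enough to exercise every stage, small enough to run in
seconds — and their fitted latent parameters can sit visibly off the
generating values on the flat ridge discussed above; their purpose is the
pipeline narrative, not recovery. Emission probabilities are clipped at
1e-12 before logs; a structurally zero-probability sequence reports a
−inf log-likelihood rather than raising. Degenerate fits (a state whose
posterior mass vanishes) are flagged, not repaired.

## Known limitations

- Covariates cannot enter the initial/transition probabilities.
- Drop-out is assumed ignorable; no joint survival model.
- The number of latent states is fixed at two (the code is structured for
  K states but only K = 2 is exercised and supported).
- The symptothermal engine omits the cervix sign, which the method's full
  protocol also records.
- With weakly separated states, single-cohort latent-parameter estimates
  carry large ridge uncertainty; reported standard errors describe local
  curvature and can understate it.
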