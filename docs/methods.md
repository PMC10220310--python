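# Methods notes

This note records the modelling assumptions, parameter choices, numerical
decisions and known limitations behind the package, in the order the
pipeline runs.

## Preprocessing

Traces are epoch-level count magnitudes (triaxial inputs are collapsed to
the Euclidean vector magnitude before any processing). Timestamp gaps are
filled with zero-count epochs — a gap is indistinguishable from device-off
time and the non-wear detector will absorb long gaps; a warning is logged.

**Non-wear.** A maximal run of epochs with magnitude below the
minimal-movement threshold counts as non-wear when its duration *strictly*
exceeds 60 min ("longer than one hour" is read literally, so a run of
exactly 60 min remains wear time). The threshold itself is not part of the
rule's definition and is exposed as configuration; the default is 5 counts
per second of epoch (so 5 counts at 1-s epochs, 25 at 5-s epochs), scaled
this way because counts accumulate over the epoch.

**Inclusion.** A day is valid with ≥ 5 h of wear (inclusive). The analysis
window is the block of at most 7 consecutive calendar days maximizing total
wear hours — ties go to the earliest start, then the shortest window, purely
for determinism — and the recording is eligible when the window holds ≥ 3
valid days. Days are assigned by the local calendar date of each epoch's
start. No overnight exclusion is applied beyond non-wear detection itself.

## The segmentation model

Six latent intensity states with Gaussian emissions N(μ_k, σ_k²) on raw
count magnitudes and explicit dwell durations d ~ 1 + Poisson(λ_k); the
shift guarantees a minimum dwell of one epoch, since a zero-length visit is
meaningless. Self-transitions are disallowed (dwell length already models
persistence) and the transition matrix has a zero diagonal. For inference
the dwell pmf is truncated and renormalized at D_max (default 600 epochs),
which bounds the O(T·K·D) recursions; an optional `log1p` flag models
emissions on log-transformed counts instead (off by default — the Gaussian
is placed on the magnitude itself).

**Censoring convention.** The last dwell of every wear segment is treated
as right-censored: its likelihood contribution is the dwell survival
function, not the exact pmf, because the record ends while the state is
still ongoing. In the one-state limit the likelihood therefore reduces to
the emission product times the truncated probability of a single dwell ≥ T,
which is also how the enumeration oracles in the test suite are written.

**Fitting.** One pooled model is fitted on the concatenated wear segments
of all eligible children and then decoded per child; each maximal wear
segment is an independent observation sequence (dwells are never bridged
across non-wear gaps, where their semantics would break). EM runs the
explicit-duration forward–backward recursions in log space. The M-step for
λ_k maximizes the expected complete-data dwell log-likelihood — including
the censored terms — by bounded one-dimensional search, keeping the old
value if no improvement is found; this makes the update a generalized
M-step, so the marginal log-likelihood is non-decreasing, which the code
asserts on every iteration. Emission SDs are floored at 10⁻³ of the pooled
SD. Initialization is deterministic and scale-adaptive: emission means at
the K equally spaced quantiles of the pooled magnitudes, λ_k = 10, uniform
off-diagonal transitions; restarts beyond the first jitter the means and
rates (seeded). A state whose responsibility mass collapses aborts that
restart with a warning; if every restart degenerates the fit fails loudly.
After fitting, states are relabelled ascending by emission mean so that the
0–5 labels always order by intensity.

**Decoding.** Duration-constrained Viterbi with the same censored-tail
convention; within-wear runs can never exceed D_max. States 0–1 map to
*inactive*, 2–3 to *active*, 4–5 to *intense*; "total active" at analysis
level is states 2–5.

## Activity metrics

Proportions of wear time use pooled wear epochs over the included valid
days as the denominator (the proportion-of-wear normalization controls for
children wearing the device for different lengths of time); hours-per-day
figures weight included days equally regardless of wear duration.

Cut-point minutes re-aggregate counts to 5-s windows by summation (windows
aligned to the series start; a window counts only if fully within wear
time) and threshold at 40 counts per 5-s window. The alternative
per-minute formulation is selectable via configuration
(`cutpoint_epoch_seconds=60`); the 5-s form is the default. Guideline
compliance uses the mean of daily active minutes over included days
against 180 min (a stricter every-day rule is available as
`guideline_rule="all_days"`); compliance is monotone in the threshold.

The diurnal profile bins clock time (default 10 min) and reports, per bin,
the fraction of child-day epochs in each of {non-wear, inactive, active,
intense}; clock time outside a child's recorded span counts as non-wear.
Per-bin fractions sum to 1 by construction.

## Association analysis

All variables — outcome included, binary codes too — are standardized to
zero mean and unit sample variance on the analysis sample, so coefficients
are standardized β. Screening uses Spearman rank correlation per candidate
on pairwise-complete rows with the liberal p ≤ 0.2 criterion (chosen to
limit false negatives; no multiplicity correction at this stage, by
design). p-values use the t approximation for n > 20 and a seeded
Monte-Carlo permutation test (10,000 draws) for n ≤ 20, where the
approximation is unreliable and full enumeration is impractical. Parent-
action items are screened through two-predictor models (item + mobility),
so an item's association is judged after adjusting for the child's
capacity; mobility is always retained in the final models.

The multivariable stage is OLS on listwise-complete rows. Structural
coefficients are defined the standard way, r_s² = corr(x_j, ŷ)², the share
of the model's explained variation a predictor can carry on its own. The
condition number is the ratio of largest to smallest singular value of the
standardized design matrix without the intercept column, making it a
scale-free collinearity diagnostic. Rank-deficient designs fail with the
aliased columns named.

The HRQoL total is the mean of the answered 0–4 item scores, requiring at
least half the items (configurable); item scores are assumed already
oriented with 4 = best. The HRQoL model is pre-specified (age, deprivation
decile, mobility, social-cognitive capacity, recruitment pathway, total
time active) with no screening.

## The synthetic cohort generator

The generator is first-class, tested code: it exists so that the full
pipeline has a ground truth to be scored against.

**What it emulates.** Wear between a uniform start in 07:09–10:09 and a
uniform end in 18:18–20:33; a midday nap removal (probability 0.8, length
70–110 min inside 12:00–14:00) producing the characteristic non-wear dip;
six-state semi-Markov switching with zero-truncated Gaussian magnitudes
(counts cannot be negative) and shifted-Poisson dwells; covariates with
realistic marginals — age 12–36 months, sex, deprivation deciles spanning
1–10, a specialist-pathway fraction of ~42% shifted lower on capacity
scores, mobility and social-cognitive scores correlated at ρ = 0.8,
19 five-level ordinal parent-action items (the response scale of such
questionnaires is not standardized; five levels is the package's stand-in),
carer work hours, time to outdoors, daily maximum temperature — and 23
HRQoL items on 0–4 with a questionnaire-level 60% missingness, plus
column-level MCAR missingness elsewhere so listwise deletion is exercised.

**Emission scale.** Default state means are 1, 5, 12, 22, 35 and 55 counts
per second of epoch with SDs 1.5–15 (means scale linearly and SDs with the
square root of the epoch length), and dwell means of roughly 14–25 s. On
the 5-s epoch grid this places the 40-counts-per-5-s cut-point between
states 1 and 2, so the cut-point notion of "active" roughly coincides with
the state-based one.

**The planted link.** Each child's intense-activity propensity is
η = Σ β_j z_j + ε over empirically standardized covariates, with the
default β = 0.76 on mobility and ε sized so Var(η) = 1 — making the planted
R² equal to 0.76² ≈ 0.59. The propensity is realized *latently*: the target
occupancy of states 4–5 is base + SD·η (defaults 0.29 and 0.05, so the
cohort SD of the measured proportion matches the target spread), achieved
in closed form by scaling the dwell rates of states 4–5 (and 2–3 for the
total-active link, default effects 0.41 on mobility and −0.17 on one
parent action with base 0.62, SD 0.11). Planting on the latent dwell rates
rather than on measured proportions means a recovery test exercises the
whole chain: simulation → non-wear detection → pooled fitting → decoding →
occupancy bookkeeping → standardized regression. Targets are clipped to
keep the occupancy identity solvable (intense within [0.05, 0.55], active
at least 0.08 above intense, at most 0.92), which is far outside the ±3 SD
range of the defaults.

**What it does not emulate.** Raw 30+ Hz waveforms and device-specific
filtering; autocorrelated emission noise within a state; weekday/weekend or
seasonal structure beyond a daily temperature column; informative
missingness; any dependence of wear behaviour on the child's activity
level. Passing tests therefore demonstrate correctness of the pipeline's
logic and estimators under the stated generative assumptions, not
robustness to the messiness of real device data.

## Problem sizes used for validation

End-to-end recovery runs use 282 children, 3 recording days at 5-s epochs,
a dwell truncation of 40 epochs for inference and a 50,000-epoch pooled
fitting subsample — sizes chosen so a complete replicate runs in tens of
seconds while leaving occupancy estimates an order of magnitude more
precise than the planted between-child spread. CI coverage of the planted
mobility effect is spot-checked over 20 replicates in the test suite (10 in
the acceptance script). Oracle-equivalence checks enumerate all labellings
for T ≤ 8, K ≤ 3, D ≤ 4 at tolerance 1e-9; EM recovery uses 50,000 epochs
from a 3-state model (means recovered within 5%, dwell rates within 10% —
the residual bias on the lowest mean comes from the generator's
zero-truncated emissions, which inference deliberately ignores).

## Known limitations

- The Gaussian emission ignores zero-truncation and count discreteness;
  for states whose mean is within ~2 SD of zero the fitted mean is biased
  upward by a few percent.
- One pooled model assumes all children share emission and dwell
  parameters up to the planted dwell-rate scaling; per-child fitting is
  possible through the same API but is not the default.
- K = 6 is fixed; no model selection over the number of states is offered.
- The Monte-Carlo permutation p-values for tiny screening samples are
  exact only in the limit of the permutation count (10,000 by default).
- Guideline compliance in synthetic cohorts sits near 100% because the
  default generator keeps every child's cut-point activity well above
  180 min/day; the compliance machinery is validated on constructed
  sequences instead.
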