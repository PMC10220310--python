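# actikid

Accelerometer-based physical-activity analysis for cohorts of very young
children (roughly 12–36 months). The package turns raw epoch-level movement
counts from a waist-worn device into per-child activity outcomes and
population-level association models, and ships a fully synthetic cohort
generator with planted ground truth so every stage can be validated end to
end without any real data.

It is aimed at researchers in child health and physical-activity
epidemiology who want a tested, reproducible implementation of this kind of
analysis pipeline:

1. **Preprocessing** — non-wear detection (any continuous period of minimal
   movement strictly longer than 1 h), day-level inclusion (≥ 5 h of wear),
   and recording-level inclusion (the ≤ 7-consecutive-day window maximizing
   wear time must contain ≥ 3 valid days).
2. **Segmentation** — an unsupervised six-state **explicit-duration hidden
   semi-Markov model (HSMM)** fitted to the pooled wear-time counts and
   decoded per child.
3. **Activity metrics** — proportions of wear time by intensity, hours per
   day, conventional cut-point minutes (40 counts per 5-s epoch), and
   compliance with the 180 min/day guideline.
4. **Association models** — Spearman screening at p ≤ 0.2, standardized
   multivariable OLS with structural coefficients and the design condition
   number, and a pre-specified model for health-related quality of life.

## The model

Counts in epoch *t* are emitted by a latent intensity state
*s(t)* ∈ {0, …, 5} (ordered by emission mean). State *k* emits

&nbsp;&nbsp;&nbsp;&nbsp;*x(t) | s(t)=k* ~ N(μ<sub>k</sub>, σ<sub>k</sub>²)

and persists for an explicitly modelled dwell

&nbsp;&nbsp;&nbsp;&nbsp;*d* ~ 1 + Poisson(λ<sub>k</sub>),

truncated and renormalized at D<sub>max</sub> for inference; self-transitions
are disallowed, and the matrix **A** (zero diagonal) governs which state
follows when a dwell ends. The final dwell of every wear segment is
right-censored. Fitting is by EM with the explicit-duration forward–backward
recursions; decoding by duration-constrained Viterbi. States 0–1 are
grouped as *inactive*, 2–5 as *active*, and 4–5 as *intense* activity, and
the headline outcomes are the proportions of wear time spent active and
intense.

Association models standardize every variable to unit variance, so
coefficients are standardized β; each predictor also gets a structural
coefficient r<sub>s</sub>² (squared correlation with the fitted outcome).

## Worked example

One command simulates a small cohort, runs every stage, and prints the
report:

```bash
actikid demo --seed 1 --out demo --children 60
```

Output (abridged):

```
children analysed: 60
wear time, h/day:          9.56 (SD 0.58)
active (states 2-5), h/day: 5.83 (SD 1.11)
intense (states 4-5), h/day: 2.72 (SD 0.46)
proportion of wear active:  0.609 (SD 0.110)
proportion of wear intense: 0.285 (SD 0.046)
meeting guideline:          1

model: prop_intense  (n = 44, R^2 = 0.60, adj = 0.50, condition number = 3.49)
term                      beta   ci_low  ci_high       p    rs2
mobility                  0.60     0.21     1.00   0.004   0.69
social_cognitive          0.16    -0.23     0.54   0.414   0.47
...
```

Reading this: the 60 simulated children wore the device ~9.6 h/day and
spent ~61% of that wear time in states 2–5 (about 5.8 h), including ~29% in
the two highest-intensity states; every child's mean daily cut-point
minutes cleared the 180-min guideline. In the intense-activity model the
standardized mobility coefficient 0.60 (95% CI 0.21–1.00) recovers the
effect the generator planted (0.76) within its CI at this small n; its
structural coefficient says mobility carries ~69% of the model's explained
variation. The correlated social-cognitive score shows a large r<sub>s</sub>²
but no independent contribution — the expected signature of two covariates
correlated at ρ = 0.8.

The same stages are available as library functions
(`generate_cohort`, `detect_non_wear`, `hsmm_fit`, `decode_epoch_series`,
`summarize_activity`, `fit_multivariable`, …) and as individual CLI
subcommands (`simulate`, `prep`, `fit`, `decode`, `associate`, `run`).

## Layout

```
src/actikid/
  synthetic.py    # cohort generator with planted ground truth
  prep.py         # trace I/O, non-wear detection, inclusion rules
  hsmm.py         # explicit-duration HSMM: forward, EM, Viterbi, grouping
  metrics.py      # activity summaries, cut-points, compliance, diurnal profile
  association.py  # screening, standardized OLS, structural coefficients, HRQoL
  pipeline.py     # orchestration, manifest, report
  cli.py          # command-line interface
docs/methods.md   # modelling and design notes
```
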