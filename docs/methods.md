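# Methods

## The task model

The IGT payoff engine is deterministic. Each deck is a `DeckSchedule`: a
fixed gain per card ($100 for A/B, $50 for C/D) and a 10-entry loss cycle
applied by within-deck draw position (1-based, cyclic). The shipped program
uses the canonical ABCD schedule — A loses 150/300/200/250/350 at positions
3/5/7/9/10, B loses 1250 at position 9, C loses 50 at positions 3/5/7/9/10,
D loses 250 at position 10 — which satisfies the published constraints
(total loss per 10 cards $1250 for A/B and $250 for C/D; five punishments
per cycle for A/C, one for B/D; net −$250/+$250 per 10 cards). The exact
within-cycle placement is not published; any program meeting the
constraints can be loaded from JSON. Losses are stored as positive
magnitudes, so a card's net outcome is `win − loss`.

## The rEV model

Three parameters, all estimated per subject:

| parameter | range | meaning |
|---|---|---|
| `w` | [0, 1] | attention to gains vs losses in the valence `v = w·win − (1−w)·loss` |
| `φ` | [0, 1] | recency (learning rate) of the expectancy update |
| `c` | [0, 5] | choice consistency, via sensitivity `θ = 3^c − 1` |

Expectancies start at zero for all four decks, so the first choice is
uniform. Only the chosen deck's expectancy is updated. Outcomes enter the
valence in raw task dollars. Two sensitivity conventions circulate in the
rEV literature; the printed formula in the source material (`c^5 − 1`) is
typeset ambiguously and matches neither, so the package defaults to the
trial-independent `θ = 3^c − 1` and offers the trial-dependent
`θ(t) = (t/10)^c` under `theta_variant="trial_pow"`. `c_max = 5` follows
the standard bound for the `3^c − 1` form and is configurable up to 10.

With dollar-scale expectancies, `θ·E` spans hundreds even at moderate `c`,
so choice probabilities saturate quickly: the likelihood is nearly flat in
`c` above a data-dependent threshold, and `w` (which decides *which* decks
look good) is the best-identified parameter. This matches the empirical
pattern that `w` carries the predictive signal.

### Likelihood and fitting

The one-step-ahead log-likelihood accumulates `log p(choice_t | history)`
with probabilities computed by max-subtracted softmax and floored at
`prob_floor = 1e-10` before the log (bounds the surface when `θ·E` is
extreme; inactive otherwise). The baseline model predicts each choice from
the subject's overall choice proportions; its maximized log-likelihood is
`Σ_j n_j log(n_j/T)`. The comparison statistic is
`2·(llf_model − llf_baseline) − (k_model − k_baseline)·ln T`; with both
models carrying three free parameters (four proportions, one constraint)
the penalty cancels.

Fitting is screened multi-start: a 4×4×4 interior lattice over the box
(with a small seed-controlled jitter of at most a quarter grid-spacing) is
scored, and bounded Nelder-Mead (xatol = ftol = 1e-6, ≤ 400 iterations)
refines the 6 best starts. Bounded Powell was rejected after it measurably
*worsened* from good starts on this spiky surface. Ties within tolerance
break toward lexicographically smaller `(w, φ, c)`, making the fit
deterministic given settings. The likelihood inner loop is JIT-compiled
(numba); a straight-line pure-Python enumeration of the same equations
serves as the independent oracle in the tests.

## Synthetic cohort generator

The generator emulates a two-wave cohort of 181 adolescents:

- age ~ N(16.2, 0.55); gender 50/50; vocational school 82/181;
  working memory ~ N(61.8, 6.8) truncated to [0, 72] and rounded;
  academic performance on 1–5 with probabilities (.05, .10, .30, .35, .20)
  (mean 3.55, SD 1.07).
- Baseline smoking: logistic in gender and school type with log-odds
  2.161 (male) and 1.498 (vocational) — the odds ratios implied by the
  published composition tables — and an intercept solved numerically so the
  marginal prevalence is 9.4%.
- rEV parameters: truncated normals; `w` mean 0.40 (baseline non-smokers)
  or 0.37 (baseline smokers), SD 0.36; `φ` ~ (0.23, 0.33) on [0, 1];
  `c` ~ (4.0, 4.0) on [0, 5]. Means/SDs are the parent-normal parameters;
  truncation shifts realized moments, documented as approximate.
- Each subject's session is simulated from their true parameters
  (100 trials) on an independent RNG stream, so analyses that need no
  sessions reuse the identical subject stream.
- Wave-2 smoking: Bernoulli with
  `logit p = β0 + 3.075·smoker_t1 − 2.673·w` (the published structural
  coefficients), `β0` solved by quadrature over the `w` mixture so the
  marginal prevalence is 12.2%. Smoking levels (ordinal 1–6) follow the
  published per-wave level distributions conditional on smoking.

Deliberately not modelled: attrition, school-level clustering, self-report
measurement error, and any covariate dependence beyond the
gender/school → baseline-smoking and `w` → wave-2-smoking links (the
published tables give margins and two-group contrasts, not a joint
distribution). Passing tests therefore validate the machinery and the
injected structure, not distributional realism of real cohorts.

## Statistical battery

Pearson chi-square on 2×2 tables uses no continuity correction — this
reproduces all five published statistics exactly, which fixes the
convention. T-tests are Student (pooled variance) by default, Welch by
flag. With exactly two blocks, the between-within (split-plot) ANCOVA
group×block interaction is algebraically the ANCOVA on within-subject
difference scores (block2 − block1), and the group main effect the ANCOVA
on subject means; both are F(1, n−p) tests computed from restricted-vs-full
sums of squares (degenerate zero-residual designs return F = 0 rather than
0/0). Logistic models report Wald 95% CIs on `exp(B)`; separation is
raised, and inside the battery flagged, never silently returned. Linear
models report raw `B`, its CI, and the standardized beta
`B·sd(x)/sd(y)`. The four focal predictors (net score, `w`, `φ`, `c`) are
examined one at a time, each adjusted for age, gender, school type,
working memory, academic performance and the wave-1 outcome.

## Numerical and design choices

- Sessions are validated strictly (contiguous 1..T trial indices, known
  deck labels); parse errors cite file line numbers.
- The pipeline fans a single global seed into per-stage seeds via SHA-256
  of the stage name, all below 2^31; a full run is byte-identical across
  reruns except for `timings.json` (wall-clock bookkeeping only).
- Scalar truncated-normal draws use the inverse-CDF through `ndtr`/`ndtri`
  directly (truncation, not clipping).
- Default problem sizes: 181 subjects × 100 trials for the pipeline; 200
  agents for recovery experiments; 5000 subjects (no sessions) for
  effect-direction checks — sizes chosen so each experiment's Monte-Carlo
  error is small relative to the effects examined.

## Known limitations

- `c` is weakly identified on dollar-scale expectancies (likelihood
  plateaus once choices saturate); recovery diagnostics for `c` are
  reported but expected to be poor. `φ` recovery is intermediate.
- RMSE of recovered `w` improves with horizon only modestly and noisily:
  agents with `c ≈ 0` choose nearly at random, and their `w` is
  unidentifiable at any horizon, putting a floor under aggregate RMSE.
  Horizon comparisons hold the agent population fixed (split RNG streams)
  to make them meaningful.
- The wave-2 outcome conditions on *true* `w`; analyses run on fitted
  parameters show the expected attenuation from estimation noise.
- The trial-dependent sensitivity variant is implemented and tested for
  correctness but the shipped defaults use the trial-independent form; no
  claim is made about which the original analyses used.
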