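# Methods

## The RLWM agent

The agent holds two stimulus × action value tables per block, both initialised
to `Q0 = 1/3` (three response keys).  On a trial with stimulus `s`:

1. Two softmax policies are computed over the WM and RL rows for `s`, with a
   shared inverse temperature `beta` (max-subtraction keeps the exponentials
   finite at any `beta`).
2. They are mixed with weight `P_WM = rho * min(1, K / ns)`: working memory
   carries at most its prior weight `rho`, scaled down once the block's set
   size `ns` exceeds the capacity `K`.
3. The mixed policy is blended with the uniform policy at the lapse rate
   `epsilon`; this floor (`epsilon / 3` per action) is what keeps every
   realized choice in the likelihood's support.
4. After feedback `r ∈ {0, 1}` (deterministic: 1 iff the chosen key is the
   stimulus's assigned key): the RL row updates by the delta rule at rate
   `alpha`; the WM entry is set to `r` exactly (one-shot learning); then every
   WM entry of the block decays toward `Q0` by the fraction `phi`.

Conventions that the model family leaves open, fixed here and used
consistently by the simulator and the likelihood:

- **Decay timing.** Decay is applied once per trial, after feedback and the
  WM store, to *all* WM entries including the just-stored one.  Applying it
  before the store instead only re-scales the effective per-lag decay; the
  two conventions are related by a reparameterisation of `phi`.
- **Shared beta.** One inverse temperature serves both policies (the
  configuration accepts a fixed `beta` or fits it; capacity `K` is handled by
  exhaustive scan because it is discrete).
- **Lapse placement.** The uniform blend applies to the mixed policy, not to
  each subsystem separately.
- **Block independence.** Both tables re-initialise at every block start;
  stimuli never repeat across blocks, so there is no cross-block transfer.
- **Timeouts.** Invalid trials (no response within the 7 s window) contribute
  neither a likelihood term nor any update or decay.  The simulator never
  generates them; real logs may contain them.

The forward pass is implemented once, as a numba-compiled kernel shared by
the simulator and the likelihood; a pure-Python step-by-step `AgentState`
API mirrors it exactly and is cross-checked against it in the test suite.

## Task schedules

Default session: one training block (`ns = 3`, 12 presentations, excluded
from all analyses) plus ten learning blocks with set sizes
`[2, 3, 4, 5, 2, 3, 4, 5, 3, 4]`.  Blocks with `ns = 4` use 13 presentations
per stimulus and all others 12, which lands the session on 468 total trials;
this composition is one feasible instantiation of the published session
layout (the per-block breakdown is not printed anywhere) and is an ordinary
config constant.  Interleaving is a seeded shuffle re-drawn until no stimulus
repeats more than `max_run_length = 3` times consecutively (bounded retries,
then a constraint-infeasible error).

## Maximum-likelihood fitting

`RLWMEstimator` minimises the trial-wise negative log-likelihood with
multi-start L-BFGS-B inside the box `alpha, phi, rho, epsilon ∈ [0, 1]`,
`beta ∈ [0.1, 50]`; `K` is scanned over `{2, 3, 4, 5}` unless fixed.  Start
points are uniform draws from the box, seeded, so fits are deterministic
given `(data, config, seed)`.  The library default is 20 starts per `K`
value; the cohort pipeline and the validation experiments use 2–5 starts
with `beta = 8` and `K = 3` fixed, which our start-count sweeps show reach
the same optima on this likelihood while keeping hundreds-of-subjects runs
in the minutes range.  Two numerical guards:

- per-trial probabilities are clamped at `1e-12` inside the log only, so
  `epsilon = 0` fits cannot produce infinities;
- whenever `epsilon` is free, the uniform policy (`epsilon = 1`) is evaluated
  as an explicit candidate, so a fitted NLL can never exceed `T ln 3` — the
  uniform model is nested and the estimator must not lose to it.

Reporting follows the four analysed parameters (`alpha`, `phi`,
`rho`/"prior", `epsilon`); `beta` and `K` are treated as structural.

### Identifiability

Parameter recovery (simulate → refit → correlate) is the package's
validation standard, and its results should be read with the model's genuine
degeneracies in mind.  Two matter in practice:

- whenever `K >= ns`, a no-decay WM agent (`rho → 1`, `phi → 0`) is
  likelihood-equivalent to a fast RL agent (`alpha` high): `alpha` and `rho`
  trade off;
- at large `epsilon` the data approach uniform responding and carry little
  information about anything else.

Consequently, with parameters sampled uniformly over the full `[0, 1]` box
on the default 432-trial session, recovery correlations are moderate
(`epsilon` ~0.7, the others ~0.3–0.5) *even though the optimizer reaches an
NLL at or below the generating parameters' in ~97% of fits* — the loss is in
the likelihood, not the optimization.  In the behaviorally plausible regime
(high WM prior, lapse below ~0.4) `phi` and `epsilon` recover well
(r > 0.6–0.8) and recovery degrades gracefully with fewer blocks.  The same
estimation noise attenuates group contrasts computed on *fitted* parameters:
a standardized mean difference `d` on generating parameters realizes as
roughly `r_recovery × d` on fitted ones.  Group-level conclusions from
fitted RLWM parameters therefore need substantially larger samples than the
generating effect sizes alone would suggest; the acceptance report exposes
this directly (per-effect detection rates alongside the joint pattern rate).

## Learning curves

Curves are the mean of `reward` at each presentation index (per stimulus),
pooled over stimuli and subjects, optionally split by set size, and truncated
at the minimum per-stimulus presentation count (12 under the default task) so
every iteration cell is balanced.  The logistic growth model
`P(t) = A / (1 + B exp(-k t))` is fitted by bounded least squares
(`A ∈ (0, 1]`, `B ∈ (0, 1e3]`, `k ∈ (0, 10]`) with a fixed initialisation
(`A0 = max(curve)`, `k0 = 0.5`, `B0` solved from the first point), so fits
are deterministic.  Curves with a range below `1e-3` are flagged degenerate
and returned with `B` and `k` pinned at their lower bounds rather than
mis-fit.  Both pooled-curve fits and per-subject fits are supported; reports
label which was used.

**Learning initiation** is the first integer iteration at which the fitted
curve's rise clears a fraction (default 10%) of its total attainable rise,
`(P(t) - P(0)) / (A - P(0)) >= fraction`, with `P(0)` the curve's
pre-learning baseline.  A literal threshold on `P(t) >= fraction * A` is
available via `rule="literal"`, but is typically satisfied at `t = 1` for
any curve whose baseline exceeds a tenth of its asymptote, which makes it
uninformative; the baseline-normalised rule is the default for that reason.

## Synthetic cohort

Three groups mirror an aging study design: young (ages 25–40, MoCA 26–30,
n = 22), normal middle-aged (41–65, MoCA 26–30, n = 11) and middle-aged MCI
(41–65, MoCA 18–25, n = 15).  Parameters are truncated normals on [0, 1]
with common SD 0.15 and group means

| group        | alpha | phi   | rho  | epsilon |
|--------------|-------|-------|------|---------|
| young        | 0.400 | 0.250 | 0.85 | 0.2500  |
| normal_mid   | 0.316 | 0.331 | 0.85 | 0.3160  |
| mci_mid      | 0.316 | 0.331 | 0.85 | 0.3955  |

The mean gaps equal the target standardized separations (0.56 for `alpha`,
−0.54 for `phi`, −0.44 for `epsilon` young vs. normal middle-aged; −0.53 for
`epsilon` normal vs. MCI; 0 for the prior) times the common SD; the absolute
levels are placed far enough from the [0, 1] boundaries that truncation
changes the realized moments only slightly — the sampler test verifies the
realized d of 10,000 draws stays within ±0.1 of each target.  `beta = 8` and
`K = 3` are structural constants for all groups.  Within the middle-aged
groups, the `phi` and `epsilon` means drift by +0.002 per year of age
(centred on the range midpoint), so age-trend analyses have a small true
monotone signal to find.  Within-group SDs are free constants of the
generator (no published value exists); they are echoed into the cohort's
provenance files.

**Reaction times** are generated at the subject level,
`mean RT = intercept + c_phi * phi + c_prior * rho`, with per-trial Gaussian
noise (SD 150 ms), a +100 ms increment on error trials, and clipping to the
(0, 7000] ms response window.  Coefficients: young `c_phi = 722.22`,
`c_prior = 137.07`, intercept 700 ms; middle-aged `c_phi = 2355.98`,
`c_prior = 156.34`, intercept 750 ms (MCI 900 ms, emulating the reported MCI
slowing).  This is a descriptive linear model chosen because those are
exactly the predictors the downstream RT regression uses; no response-time
process model (e.g. drift diffusion) is attempted, and the agent has no RT
likelihood.

What the generator does *not* emulate: real stimulus confusability,
within-session fatigue or attention drift, RT distributions' right skew,
MoCA psychometrics (scores are uniform in the group's range), or the
demographics of excluded participants.  Tests passing on this cohort
therefore certify the pipeline's statistical machinery and the model's
internal consistency, not the behavior of any human population.

## Statistical battery

- **Exclusion**: overall accuracy strictly below 33% (chance-level
  responding) excludes a subject, with the reason recorded.
- **Two-group comparisons**: Shapiro–Wilk on each group; if either deviates
  (p < 0.05) the test is Mann–Whitney U, else Welch's t.  Cohen's d (pooled
  SD, first minus second group) is always reported.  Bonferroni families are
  explicit: one family per analysis table (e.g. the four parameters of a
  group-contrast table), with the family size logged next to every adjusted
  p.
- **Age trends**: Spearman's rho and a linear regression (r², slope) are
  reported together, since a monotone association and a linear fit can
  disagree.
- **Classifier**: logistic regression (standardised features, 75/25
  stratified seeded split) predicting `age > cutoff` from per-set-size RT
  and accuracy, for cutoffs 35–44; cutoffs whose minority class is too small
  to stratify are skipped and flagged.
- **IES**: mean RT divided by proportion correct, per subject.
- **Speed–accuracy**: per group, mean RT on correct vs. error trials (all
  trials and restricted to iterations at or past the group's learning
  initiation), plus a regression of subject accuracy on subject mean RT.
- Per-set-size RT summaries pool correct and error trials; RT summaries use
  valid trials only.

## Validation protocol (what `scripts/acceptance.py` runs)

| experiment | size | what it measures |
|---|---|---|
| simulation/likelihood consistency | 10,000 agents, 2 blocks (ns 2 and 5) | max |z| between per-trial choice frequencies and mean forward-pass policies; the SE accounts for each agent's own history.  With ~168 trial × action cells, a max just above 3 occurs at roughly a third of seeds by chance. |
| full-lapse limits | 84 trials | NLL − T ln 3 at `epsilon = 1` (analytically 0) and the largest deviation of fresh-block policies from 1/3 (exactly 0). |
| parameter recovery | 100 subjects, uniform in bounds, 5 starts | per-parameter Pearson r and mean bias; see Identifiability above for why r is moderate for `alpha`, `phi`, `rho` under full-range sampling. |
| set-size effect | 500 agents, `rho=0.95, K=2, phi=0.05, alpha=0.05, beta=25, eps=0.02` | late-phase accuracy (mean over iterations 7–12, the second half of the balanced domain) per set size; strictly decreasing 2→5. |
| growth exactness | 13 points | max relative error on noiseless in-class data; flat-curve degeneracy flag. |
| cohort pattern | 20 replicates × 300 subjects, 2 starts | rate at which the full configured significance pattern appears on fitted parameters, plus per-effect rates. |
| RT regression | 500 young subjects, noise SD 20 ms, no error increment | recovered `c_phi` and `c_prior` and whether each is within 2 SE of the generating value. |
| determinism | 12 artifacts | whether two pipeline runs with identical config and seed are byte-identical. |

Problem sizes are the package's validation protocol constants; the whole
script completes in a few minutes on one CPU.

## Known limitations

- Maximum likelihood only: no hierarchical or Bayesian estimation, no
  model-comparison table, no regularisation — boundary estimates
  (`epsilon = 0`, `rho = 1`) are common at the single-subject level.
- `alpha` is weakly identified whenever working memory can explain the data
  (see Identifiability); group contrasts on fitted `alpha` are strongly
  attenuated.
- The growth model's `B` is barely constrained when curves start near their
  asymptote; interpret `B` only jointly with `k`.
- The logistic classifier reports raw test-split accuracy on small samples;
  it is a descriptive device, not a validated diagnostic.
- Dynamic WM/RL arbitration models, negative-feedback-specific learning
  rates, and RT process models are out of scope.
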