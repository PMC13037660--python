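# Methods

This note documents the models and procedures implemented in `cravemod`,
the assumptions behind them, the synthetic-data generators used to exercise
them, and the numerical and design choices a maintainer would want spelled
out.

## Study design being emulated

The package re-implements the computational analyses of a within-participant
pre/post intervention in which participants train response inhibition to
sugary-drink pictures (Go/NoGo training), with four outcome families:

1. **Explicit liking** (0–100 analogue ratings) tested with a 2 (session:
   pre/post) × 2 (item category: trained-Go / trained-NoGo) within-subject
   ANOVA; the registered hypothesis is a larger pre→post drop for NoGo items
   (the session × category interaction).
2. **Event-related potentials** during correct response withholding,
   analysed as global features of the scalp field: global field power (GFP)
   and topography (via global map dissimilarity, GMD), time-frame-wise, with
   randomization statistics.
3. **Implicit wanting** from a stimulus–response compatibility (SRC) task:
   IW = RT(away) − RT(toward), same 2×2 ANOVA.
4. **Moderation of the devaluation** by individual learning biases: a
   Pavlovian sign-tracking index (gaze) and the model-based weight *w* of a
   hybrid reinforcement-learning model of the two-step task.

No real data are used anywhere: every analysis runs on seeded synthetic
data with known ground truth, so that the code's claims are testable.

## Electrical neuroimaging

### Field measures

For an average-referenced scalp map $u \in \mathbb{R}^{C}$ ($C$ electrodes):

$$\mathrm{GFP}(u) = \sqrt{\tfrac{1}{C}\sum_i (u_i - \bar u)^2}$$

(population SD; the Lehmann–Skrandies convention). For two maps $a, b$
scaled to unit GFP,

$$\mathrm{GMD}(a,b) = \sqrt{\tfrac{1}{C}\sum_i (\hat a_i - \hat b_i)^2}
 = \sqrt{2\,(1 - r(a,b))},$$

where $r$ is the spatial Pearson correlation. GMD lives in $[0, 2]$: 0 for
identical topographies, 2 for polarity-inverted ones. The identity with
$r$ is verified numerically to 1e-9 in the tests; GFP is invariant to a
common offset, GMD to separate positive rescaling of either map.

### Pre-processing

The module starts from epoched data (−100…700 ms around stimulus onset);
continuous-data cleaning (filtering, line noise, artifact subspace
reconstruction, blink removal, bad-channel interpolation) is out of scope.
Steps, in order: per-channel baseline subtraction over [−100, 0] ms (the
pre-stimulus segment is the only candidate window); rejection of epochs
with a time-frame-to-time-frame step exceeding 30 µV or any absolute
voltage exceeding 80 µV on any electrode (both strict); per-condition
averaging; common-average re-referencing. If every epoch of a condition is
rejected, an explicit empty-ERP error is raised, mirroring the exclusion
of participants without a visually identifiable ERP.

### Microstate segmentation

Grand-average maps from all conditions are pooled and clustered with an
atomise-and-agglomerate hierarchy: starting from singleton clusters, the
worst cluster (lowest mean member–centroid correlation) is repeatedly
dissolved and its members reassigned, recording a clustering at every k;
each candidate k is then polished by modified k-means iterations.
Clustering is **polarity-sensitive** (signed spatial correlation): unlike
spontaneous-EEG microstate analysis, ERP components carry meaningful
polarity.

Model selection: the Krzanowski–Lai criterion
$\mathrm{KL}(k) = |\mathrm{DIFF}(k)| / |\mathrm{DIFF}(k{+}1)|$ with
$\mathrm{DIFF}(k) = (k{-}1)^{2/C} W_{k-1} - k^{2/C} W_k$ on the
within-cluster dispersion $W_k$ of the normalised maps, screened by the
predictive-residual cross-validation criterion
$\mathrm{CV}(k) = \hat\sigma^2 \left(\tfrac{C-1}{C-1-k}\right)^2$:
candidate k must not worsen CV relative to k−1; ties resolve to the
smaller k. Two degenerate rules: if a single template explains the pooled
maps to numerical precision, k = 1 is returned; if KL is undefined (range
endpoints), the CV minimum decides. Segments shorter than 20 ms (the lower
edge of quasi-stable component duration) are absorbed into the
better-correlated neighbour. Non-convergence of the k-means polish is
reported with a flag, returning the best clustering found.

For inference, each component window is re-centred on the time frame of
maximal grand-average GFP per condition (ties break to the earliest frame)
with a common pre/post extent across conditions — the minimum, so no
condition's window leaves its segment.

### Randomization statistics

At each time frame, per effect (session, category, interaction) and
measure:

* **GFP**: the within-subject ANOVA F(1, n−1) of per-subject GFP values,
  computed exactly as the squared one-sample t of the ±1 effect contrast.
* **Topography**: the GFP of the same ±1 contrast applied to the
  GFP-normalised condition-mean maps — the generalised topographic
  dissimilarity statistic (for two conditions it reduces to a monotone
  function of the GMD between the mean maps).

The null distribution permutes the condition labels independently within
each subject (exact exchangeability under H0 for a within design);
p = (1 + #{perm ≥ obs}) / (1 + n_perm), the add-one Monte-Carlo estimator,
with the seed recorded in the result. A two-condition variant (per-subject
label swaps) serves the registered fallback contrast. Guard rails: at
least 100 permutations, complete cells per subject.

An effect is interpreted only if at least 12 consecutive time frames are
significant at α = .01 within a component window (both constants are
parameters). The registered fallback branch is explicit: if the session
effect on trained-Go items shows a qualifying run inside the window on
either measure, the 2×2 interaction is replaced by the pre/post contrast
on NoGo items only.

Note a structural consequence of injecting a *pure* interaction in the
generator: the four cell amplitudes move by ±¼ of the interaction
contrast, so trained-Go items necessarily differ between sessions too, and
the fallback branch fires. This mirrors the registered logic's behaviour
on the real N2 finding rather than contradicting it.

## Hybrid reinforcement learning (two-step task)

Seven parameters: learning rates $\alpha_1, \alpha_2 \in [0,1]$, inverse
temperatures $\beta_1, \beta_2 \ge 0$, eligibility trace $\lambda \in
[0,1]$, model-based weight $w \in [0,1]$, perseveration $\pi$ (unbounded).

Per trial $(c_1, s_2, c_2, r)$, with pre-update values:

* $\delta_2 = r - Q_2(s_2, c_2)$, $\delta_1 = Q_2(s_2, c_2) - Q_{MF}(c_1)$;
* $Q_2(s_2,c_2) \mathrel{+}= \alpha_2 \delta_2$;
* $Q_{MF}(c_1) \mathrel{+}= \alpha_1(\delta_1 + \lambda\,\delta_2)$;
* $Q_{MB}(a) = \sum_s P(s\mid a)\,\max_c Q_2(s,c)$, recomputed at choice
  time from the transition matrix (common transition .7, assumed known and
  fixed — participants receive extensive instructions — rather than
  learned);
* stage-1 softmax over $\beta_1\,[w\,Q_{MB} + (1-w)\,Q_{MF}] +
  \pi\,\mathrm{rep}$, where rep indicates repeating the previous stage-1
  choice; stage-2 softmax over $\beta_2 Q_2(s_2,\cdot)$.

Q values initialise at 0.5, the midpoint of the reward-probability range
(unbiased start). Reward probabilities follow independent Gaussian walks
(step SD 0.025) **reflected** at 0.25/0.75 — reflection rather than
truncation preserves the nominal step SD away from the bounds. Low *w*
indexes model-free reliance; the walk is generated once per cohort and
shared across agents, as in the task itself.

### Fitting

Maximum a-posteriori by default, with weakly informative priors chosen to
stabilise boundary estimates: Beta(1.1, 1.1) on unit-interval parameters,
Gamma(shape 2, scale 5) on the $\beta$s, Normal(0, 1) on $\pi$; plain
maximum likelihood via `method="mle"`. Optimisation runs on unconstrained
scales (logit / log) with L-BFGS-B from `n_starts` random start points,
and the best optimum is re-polished so that restarting from it cannot
improve the objective by more than 1e-6. Approximate standard errors come
from the diagonal of a finite-difference Hessian on the transformed scale,
delta-mapped to the natural scale — adequate for diagnostics, not for
formal inference.

Identifiability of *w* is screened with a true profile likelihood: the
remaining six parameters are re-optimised at w ∈ {.02, .5, .98}; if the
profiled NLL spans less than 3.32 log-units (half the 99% χ²₁ quantile),
the whole unit interval lies inside the confidence region and the fit is
flagged `w_identifiable=False`. The 99% level was chosen because a
3-point profile of a 7-parameter model re-fit to pure noise spans ~2
log-units by overfitting alone, while genuinely informative sessions span
tens; the screen separates those regimes with a wide margin.

Parameter recovery simulates agents from configurable generating
distributions (defaults: α, λ ~ U(0.2, 0.8); β = 5, the plausible
mid-temperature regime; w ~ U(0, 1); π ~ N(0, 0.3)), refits each agent,
and reports per-parameter Pearson correlations. With 201 trials — the
session length — the recovery correlation for w is around 0.7; recovery
is the binding test of the whole likelihood machinery.

## Sign-tracking (Pavlovian gaze)

Gaze index per trial: (fixation time on CS location − fixation time on US
location) / 1000 ms, over the last second of cue presentation. The
denominator is the full window, not total on-AOI time — the simplest
reading of a "proportion of fixation time" — so background fixation
dilutes both proportions equally; this choice is recorded because the
alternative normalisation is defensible too. The per-subject
sign-tracking index is the OLS slope of the gaze index on CS reward value
(−2…+2 CHF): positive slopes mean orienting to reward-predictive cues.
Validity of conditioning is gated by the forced-choice task: error rate
strictly above 10% excludes the subject (exactly 10% keeps).

## Behavioural statistics

* **Filters**: trials with RT < 200 ms are dropped everywhere; rating
  items answered in < 300 ms are dropped. Filters are idempotent.
* **Outliers**: |x − median| > 2.5 × MAD, with MAD the *raw* median
  absolute deviation (no 1.4826 consistency factor) — the registered rule
  names the raw statistic. Under normality this trims beyond ±1.69σ,
  i.e. ~9% of a clean sample per variable; consequences for moderation
  power are discussed below. Zero MAD flags nothing and warns.
* **2×2 within ANOVA**: each 1-df effect F equals the squared one-sample t
  of the corresponding within-subject contrast — an exact closed form,
  verified against both a textbook sums-of-squares oracle and pingouin.
  Partial Cohen's f = √(F·df1/df2). Homoscedasticity is checked with the
  median-centred (Brown–Forsythe) Levene test across the four cells; the
  Greenhouse–Geisser ε is identically 1 for two-level factors and is
  reported for transparency only.
* **Bayes factors**: BF01 = exp((BIC₁ − BIC₀)/2) from two nested OLS
  models (subject fixed effects, with/without the interaction). This is
  the standard BIC approximation to the default-prior Bayes factor, not a
  numerical JZS integration; treat magnitudes as approximate.
* **Effect-size gate**: the moderation analyses run only when the paired
  Cohen's d of the NoGo pre→post drop, mean(pre−post)/SD(pre−post), is at
  least 0.4. d is undefined (error) when the differences have zero
  variance but are nonzero.
* **Moderation**: OLS of the liking delta on the learning bias with
  baseline liking as covariate (df = n − 3). The registered description
  mentions a mixed model but fits with `lm`; OLS with the covariate
  matches the reported degrees of freedom.
* **Power**: smallest n with noncentral-F power ≥ target, with
  λ = (n−1)·m·f²·ε/(1−ρ), df1 = (m−1)ε, df2 = (n−1)(m−1)ε. The error-df
  (n−1) scaling matches the convention of the standard a-priori calculator
  for this design (the λ ∝ n variant returns one participant fewer at the
  planned settings); at f = .25, α = .02, power = .90, m = 2, ρ = .5 the
  calculator returns n = 56.

## Synthetic-data generators

All generators are pure functions of (config, seed) and return a
ground-truth sidecar.

* **Task sessions** carry the design constants: 70% Go in training; 4 × 200
  ERP trials (120 Go / 80 NoGo cues per block); 50 SRC trials per
  cue × category cell; 80 Pavlovian trials balanced 16 per CS with uniform
  left/right CS side; all C(5,2) forced-choice pairs × 3; 201 two-step
  trials in blocks of 67 with p = .5 side permutations. The 57-item
  catalogue reproduces the nine drink-type counts; the top-60% selection
  rounds to the nearest even count (34) so conditions can be equal, and the
  type partition (types are never split) minimises the mean-liking gap by
  exhaustive enumeration. In the ERP task the printed 60/40 cue ratio and
  exact per-item cue balance are jointly infeasible with 34 items, so items
  are balanced as evenly as possible within each cue colour (counts differ
  by ≤ 1); a strict mode raises instead.
* **ERP epochs**: sum of components (fixed unit-GFP topography × Gaussian
  temporal kernel × condition amplitude) plus spatially correlated Gaussian
  noise (squared-exponential kernel over a deterministic Fibonacci-lattice
  montage). Effects are parameterised directly as the 2×2 contrasts of the
  four condition amplitudes; the session × category interaction is injected
  only into the N2-like component (85 ms occipital P1-like, 222 ms
  frontocentral N2-like defaults). Noise is Gaussian-smoothed along time
  (8 ms scale, variance-renormalised) to emulate band-limited recordings —
  strictly white-in-time noise at realistic amplitudes would trip the 30 µV
  jump-rejection rule on every epoch; setting the smoothing scale to 0
  recovers the white model, which the permutation-calibration runs use so
  time frames are independent. Simulations default to 512 Hz (the analyses
  are rate-agnostic; this halves memory relative to the 1024 Hz recording
  rate while keeping the 12-TF rule meaningful for an ~80 ms component).
  What the generator does **not** emulate: ocular/muscle artifacts,
  channel drift, 1/f spectra, latency jitter across trials, or realistic
  electrode geometry — so passing tests demonstrate correctness of the
  statistics, not robustness to real-world artifacts.
* **Behaviour**: per-subject 2×2 rating cell means with baseline
  69.1 ± 14.0 (the cohort it emulates), a general session drop, and a
  devaluation injected as the interaction contrast parameterised by its
  within-subject Cohen's d (default 0.8, the observed-scale effect);
  lognormal rating/SRC reaction times with configurable fast-response
  contamination below the registered floors; Beta-distributed FA/Miss
  rates.
* **Gaze**: per-subject true slope from a configurable distribution;
  per-trial index = slope × CS value + noise, inverted into CS/US/background
  times with a fixed total on-AOI share (0.8) and validity-preserving
  clipping (warned and counted).
* **Cohort simulator** draws per-subject traits (sign-tracking slope, w)
  and couples them to the devaluation delta with configurable moderation
  slopes, then emits every table plus two-step sessions simulated from the
  hybrid model and (optionally) ERP epochs.

## End-to-end demonstration sizes

The pipeline demonstration uses 56 behavioural subjects (the planned
sample), 16 EEG subjects × 24 epochs/cell at 512 Hz, 499 permutations at
α = .01, and 3 fitting starts per subject for the H3b weight. Injected
effects are deliberately large: a 4 µV N2 interaction, devaluation
d = 1.2, and a sign-tracking moderation of 400 liking-points per slope
unit. Note an interaction between the two injected effects: the moderation
coupling adds ~12 liking-points of between-subject devaluation spread
(400 × slope SD 0.03), which dilutes the *within*-design interaction — a
nominal d parameter of 0.8 realises an effective interaction d near 0.5
once the coupling is on, so the demo uses 1.2 to keep the realised
devaluation comfortably detectable alongside the moderation.
The moderation coupling was sized by a Monte-Carlo design analysis
*including the registered 2.5-MAD trimming of both delta and bias*:
trimming restricts the range of a correlated pair and attenuates the
moderation far below what an untrimmed power calculation suggests (a naive
calculation ignoring trimming sized the coupling near 220; with trimming in
the loop, couplings of 300–400 were needed before every replicate cohort in
the design analysis detected the moderation at α = .02). This attenuation is a
property of the registered analysis itself and is worth knowing when
interpreting moderation results under MAD exclusion rules.

## Known limitations

* The BIC Bayes factor approximates the default-prior Bayes factor only up
  to O(1) factors.
* Fitting SEs are diagonal-Hessian approximations; correlations between
  parameters (notably β₁ and w) are ignored.
* The microstate CV criterion is used only as a screen; its absolute
  values depend on the (synthetic) noise model.
* Between-subject heterogeneity in ERP component latency/topography is not
  modelled; randomization tests on real data face harder conditions.
* The two-step model fixes the transition matrix; transition learning and
  hierarchical (group-level) estimation are out of scope.
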