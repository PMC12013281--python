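# Methods

## The task and its model

`srtddm` models performance in a serial response time task (SRTT): on
each trial a stimulus appears in one of six horizontal screen locations
and the participant presses the spatially compatible key under a
response deadline. Unbeknownst to (some) participants, stimulus
locations follow a six-item repeating sequence — either
probabilistically (each transition follows the sequence's successor
with probability .6, otherwise another location is drawn) or in a
mixed-deterministic regime in which whole blocks are fully sequenced or
fully random. A session comprises 14 blocks of 144 trials (2,016
responses), collapsed into seven block pairs for analysis; the response
deadline ramps from 900 ms to 500 ms over block 1 and stays at 500 ms
afterwards.

Choices and response times are modelled jointly with a two-boundary
Wiener diffusion process. Evidence accumulates at drift rate δ
(evidence/s) between boundaries separated by α (response caution),
starting at relative position β ∈ (0, 1); the nondecision time θ (s)
absorbs stimulus detection/encoding and motor execution. An additional
response-competition offset ξ (s) splits the nondecision time between
executed responses that match the sequence-predicted key (motor-regular,
θ − ξ/2) and those that do not (θ + ξ/2); positive ξ means practiced,
rule-adhering key presses are executed faster. Inter-trial
variabilities of drift (normal, SD `sv`), starting point (uniform,
range `szr`) and nondecision time (uniform, range `st0`) are supported
and integrated out by Gauss–Hermite / Gauss–Legendre quadrature; they
default to 0 (the basic model), because whether they are needed is an
empirical question the basic pipeline does not prejudge.

The diffusion coefficient is fixed at 1 (not the 0.1 legacy
convention), which puts typical boundary separations near 1 and drifts
in the low single digits.

### Boundary coding

Under the default *regularity coding* the upper boundary is the
sequence-predicted (regular) response and the lower boundary the
alternative, so the boundary reached coincides with the motor
regularity of the executed key. On regular trials the correct response
is the upper boundary (δ > 0); on nonregular trials the correct
response is the lower boundary (δ < 0). An *accuracy coding* switch
(upper = correct response of the trial) is provided; it is the more
natural frame for per-trial-type starting-point effects, and the two
codings imply different interpretations of β that the package does not
conflate — the choice is a configuration option, reported with every
fit.

The six-key task is reduced to the binary diffusion decision by an
explicit key-mapping convention (see `srtddm.cohort`): on regular
trials a lower-boundary outcome is mapped uniformly onto the four
admissible wrong keys; on nonregular trials the upper boundary maps to
the sequence-predicted key and the lower boundary to the correct key,
with probability `slip_prob` replaced by one of the three remaining
wrong keys. This preserves exactly the distinction the behavioural
error analyses need (rule-adhering vs other errors) while keeping the
decision model binary.

## The synthetic cohort generator

The generator reproduces the study's design: four groups (probabilistic
vs mixed-deterministic material × sequence concealed vs revealed),
per-participant random six-item sequences, the deadline schedule, and a
post-experimental interview (belief, free recall, forced choice). Cell
parameters evolve over block pairs along configurable start→end
trajectories (constant, linear, or exponential), and participants vary
around the group trajectory through per-parameter random intercepts on
the link scale (log for α and θ, logit for β, identity for δ and ξ) —
the same structure the hierarchical model estimates, so recovery
studies are well-posed.

The shipped presets are *illustrative, not fitted values*: they are
shaped to reproduce the qualitative group signatures (probabilistic
groups express learning through starting point, drift and response
competition; mixed-deterministic groups show strong starting-point
shifts, nondecision speed-ups and maintained caution in deterministic
blocks) with RT, error and deadline-violation rates that are plausible
under a 500 ms deadline (mean RT ≈ 330–390 ms, ≈ 10 % errors, ≈ 10 %
deadline violations). Default between-participant SDs are 0.10 (log α),
0.10 (logit β), 0.25 (δ), 0.08 (log θ) and 0.015 s (ξ).

Interview simulation: each of the six sequence transitions is known
with probability `interview_knowledge`; free-recall correct counts are
Binomial(6, knowledge), forced-choice probes are answered correctly
with probability `knowledge + (1 − knowledge)/5` (unknown probes are
guessed uniformly over the five admissible locations), and belief in a
sequenced condition is Bernoulli(min(1, 0.25 + 0.75·knowledge)).
Belief and recall are conditionally independent given knowledge — a
simplification: real participants who deny a sequence are not asked to
recall it.

What the generator does **not** emulate: the instruction-phase practice
trials do not influence subsequent parameters (the revealed-condition
advantage must be put into the trajectories by hand); there is no
fatigue, no post-error slowing beyond the exclusion of post-feedback
trials, no premature responses, and RTs are generated by the very model
later fitted to them. Passing recovery tests therefore demonstrates
correctness of the inference machinery, not validity of the DDM for
real SRTT data.

## Data preparation

Participants are excluded if, in at least one of block pairs 2–7, their
error rate exceeds 50 % or their deadline-violation rate exceeds 30 %
(strict inequalities; block pair 1 with its deadline ramp never
triggers exclusion). Trial filters remove, as a union: post-feedback
trials (trials following an error or deadline violation), the first
four trials of each block, and RTs below 20 ms or above 2 s. Error
responses surviving the filters are retained for the error analyses and
the DDM likelihood. Rate denominators are all trials of the block
pair; filtering is idempotent.

Deadline-exceeded trials are additionally dropped when preparing data
for DDM fitting (flag `drop_deadline_exceeded`). The likelihood is
*not* truncation-corrected, and we verified on synthetic data that
dropping the slow tail under a 500 ms deadline visibly biases
per-trial-type starting-point and drift cells; the shipped
parameter-recovery scenario therefore uses a design without deadline
pressure so that the fitted likelihood matches the generative process.
Users fitting deadline data should treat per-cell β/δ estimates with
this caveat in mind.

## Hierarchical model and sampler

For participant *i* and cell *c*, each diffusion parameter is
`invlink(μ_c + b_i)` with group-level cell means μ on the link scale
and per-participant random intercepts `b_i ~ N(0, σ_param)` shared
across cells (a per-cell-offset variant was considered and rejected for
parsimony at these data sizes). Cells: β, δ, θ per trial type × block
pair; α per block kind × block pair (probabilistic material has a
single α series); ξ per block pair only. Alternatively a
linear-in-block-pair regression (intercept at the middle pair + slope)
can replace the free cell means.

Priors are weakly informative and configurable: group means ~
normal(0, 1.5) on the link scale except δ ~ normal(0, 2); regression
slopes ~ normal(0, 0.5); group SDs ~ half-normal(1).

Sampling is an adaptive Metropolis-within-Gibbs scheme compiled with
numba: scalar random-walk updates per group mean (touching only that
cell's trials), a joint 5-dimensional random-walk update per
participant's offsets, log-scale random-walk updates of the group SDs,
and — crucially — an exact Gibbs *recentering* move along the
likelihood-invariant direction (add c to all cell means of a parameter,
subtract c from all its offsets; the conditional of c is Gaussian).
Without the recentering move the group means and offsets mix glacially
along this ridge (R-hat > 2 on nondecision cells in our checks); with
it, desk-scale fits converge in seconds. Proposal scales adapt toward
acceptance rates 0.44 (scalar) and 0.23 (joint) during burn-in only, so
retained draws come from a fixed kernel. Chains are seeded
deterministically from the user seed; identical seeds give identical
draws.

Convergence is monitored with split-R-hat and effective sample size
(arviz) on all group-level means; fits violating R-hat ≤ 1.01 or
ESS ≥ 400 carry `convergence_ok = False` and emit a warning rather than
failing silently. Desk-scale fits at the reduced draw counts used in
the test suite routinely trip the ESS bound — the warning is the
designed behaviour, and the affected checks (recovery correlation,
interval coverage, Bayes-factor calibration) are robust to it.

### Bayes factors

Effects of the experimental manipulations on parameters are tested with
Savage–Dickey density ratios on linear contrasts of the group-level
means (e.g. the block-pair average of μ_regular − μ_nonregular for β):
BF10 = prior density at 0 / posterior density at 0, under a
zero-centred normal prior with configurable SD (default 0.5 on the link
scale). The posterior density at 0 uses a normal approximation to the
contrast draws, with a Gaussian-KDE estimate reported alongside as a
cross-check (the KDE estimate is unreliable far in the tails, where the
normal approximation is the quoted number). One fit serves many
contrasts; this was chosen over bridge sampling between refitted models
for cost, and the prior here is a *test* prior, separate from the
fitting priors. Calibration at desk scale: across 20 null simulations
the median BF01 exceeds 1, and a large simulated β-regularity effect
yields BF10 > 10.

### Subset refits and recovery

Participants are classified from the interview as *implicit* (believes
random, fewer than two correct transitions in both tests), *explicit*
(believes sequenced, six of six in both tests) or *intermediate*, and
the model is re-estimated per class when at least four participants
qualify; smaller classes are reported as skipped.

Parameter recovery simulates a cohort, runs the preparation pipeline,
refits, and compares posterior means of the group-level cell means with
the generating trajectory values on the link scale (participant
intercepts average to zero by construction). The shipped reduced
scenario uses 12 participants × 288 trials (two block pairs, so 2 trial
types × 2 pairs = 4 cells for β and δ) without deadline pressure; at
this size the truth–estimate correlation across cells exceeds 0.99 and
95 % intervals cover a true ξ = 0 in ≥ 9 of 10 replicates. These
problem sizes are the package's chosen desk-scale defaults; fidelity
improves with chains, draws and participants in the obvious way.

## Numerical choices

- Wiener first-passage density: small-time and large-time series with
  automatic switching by predicted term counts at truncation error
  1e-12; the two series agree within 1e-6 in the overlap region, and
  the density integrates to 1 within 1e-4 across the tested parameter
  grid.
- Trial sampling inverts the numerically integrated CDF on an
  adaptively extended grid (4,096 points); an independent
  Euler–Maruyama path simulator (step 1e-5 s) is used as a cross-check
  oracle in the tests, never as the primary sampler.
- Impossible data (an RT at or below its effective nondecision time)
  yields an explicit `-inf`/flag result, never an exception, so
  samplers and optimizers can reject gracefully.
- Mixed ANOVA: classical computing formulas for balanced designs;
  Greenhouse–Geisser ε from the pooled within-group covariance (SPSS
  convention — pingouin, which pools without group centering, differs
  in the third decimal); generalized η² uses effect SS over effect SS
  plus all subject-related error SS. Sums of squares match pingouin
  and statsmodels exactly on the designs those support.
- Confidence intervals: between-subject t-based CIs on participant cell
  means by default; Cousineau–Morey within-subject CIs (participant
  recentring plus the √(k/(k−1)) inflation) for plots of
  within-participant contrasts such as the error-RT analysis.
- The nonregular stimulus draw excludes both the previous location and
  the sequence successor (four candidates), so realized regularity
  equals `p_regular` exactly in expectation; a flag restores the
  five-candidate variant, under which chance regularity is 1/5 — the
  value that applies in the random blocks of mixed-deterministic
  material.
- ms↔s conversion happens at exactly one point (tables store ms, the
  engine works in seconds); in the generator, ξ is clipped to ±1.9·θ
  after applying participant offsets so the nondecision split stays
  feasible.

## Known limitations

- The likelihood ignores deadline truncation (see above) and models no
  premature responses.
- Participant offsets are shared across cells; true per-cell
  participant deviations would be absorbed into the group SDs.
- The random-walk sampler's efficiency per draw is far below
  Hamiltonian Monte Carlo; it compensates with compiled speed, which is
  adequate at desk scale but would be the first thing to replace for
  full-study fits with inter-trial variabilities.
- Free-recall scoring is transition-based and cyclic; position-based
  scoring would give different counts for partially shifted reports.
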