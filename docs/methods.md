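# Methods

`sepsisrl` implements an offline reinforcement-learning pipeline for
IV-fluid and vasopressor dosing in sepsis: a synthetic ICU cohort
simulator, feature preparation with an autoencoder state expansion, a
clinically shaped reward over a discretized 5×5 dose grid, a
reward-weighted experience pool, a discrete-action DDPG-style agent, and
outcome-association evaluation (U-curves, dose-difference heatmaps,
region summaries). This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The decision problem

Each patient stay is a trajectory of 4-hour bins over a 72-hour horizon
(at most 18 bins). At every bin the clinician administers intravenous
fluids (ml/h) and vasopressors (µg/kg/min); each rate is discretized to
one of five dosing levels (level 0 = none), so the joint action space is
the 5×5 grid, flattened IV-major to indices 0–24. Level thresholds are
left-closed: IV breaks at 50, 180, 530 ml/h; VP at 0.08, 0.22,
0.45 µg/kg/min, with any positive rate below the first break mapping to
level 1.

The per-transition reward combines organ failure (SOFA, 0–24) and
cellular hypoxia (lactate, mmol/L):

    r(s_t, s_{t+1}) = c0·1[SOFA_{t+1} = SOFA_t and SOFA_{t+1} > 0]
                    + c1·(SOFA_{t+1} − SOFA_t)
                    + c2·tanh(lactate_{t+1} − lactate_t)

with c0 = −0.025, c1 = −0.125, c2 = −2. A persistent positive SOFA is
mildly penalized, SOFA increases and lactate rises are penalized
(improvements symmetrically rewarded), and the lactate term saturates
through tanh. At the final transition the reward is additionally
increased by 15 if the patient survived to discharge and decreased by 15
otherwise; the bonus is added to, not substituted for, the shaped term.
The terminal transition is evaluated on the final snapshot against
itself (no later observation exists), so its shaped term reduces to the
c0 indicator.

## Synthetic cohort

Real ICU data of this kind is access-restricted, so the package ships a
simulator that reproduces the statistical structure the pipeline needs
rather than physiology:

- A latent severity in [0, 1] follows
  `severity' = clip(severity + drift − dose_effect·match + N(0, noise_sd))`,
  where `match` is 1 iff both administered levels equal the latent
  optimal level `min(4, floor(5·severity))` — a staircase in severity.
  Defaults: drift 0.04/bin, dose_effect 0.08/bin, noise_sd 0.05.
- Death occurs when severity reaches `mortality_threshold` (default
  0.92); recovery (severity 0) or surviving the horizon means discharge.
  Initial severity is uniform on [0.25, 0.70]: ill enough that dosing
  matters, never terminal at admission. Under the defaults this yields
  roughly 10–15% cohort mortality and a strong dose–outcome link
  (mortality ≈ 0 under a perfectly matching clinician with
  dose_effect 0.12, ≈ 0.85 under a never-matching one).
- Observables: SOFA = round(24·severity + N(0, 1)) clipped to [0, 24];
  lactate = exp(0.2 + 2.2·severity + N(0, 0.15)), spanning ≈1–12 mmol/L.
  The 48-dimensional feature vector is a fixed random linear map — drawn
  once per cohort from the seed — of (severity, SOFA/24, log lactate,
  elapsed-stay fraction), plus independent N(0, 0.3) noise per feature.
  The elapsed-stay input mirrors the time-anchored charting of real ICU
  records; it is also what makes end-of-stay states identifiable.
  Without it, a discharged survivor's last state is indistinguishable
  from a mid-stay state, the +15 discharge bonus becomes an irreducible
  target ambiguity for any value estimator, and the large persistent
  residuals — amplified by the reward-weighted sampler, which
  concentrates on terminal transitions — leak into the critic's
  advantage stream and corrupt its action ranking.
- The behavior ("clinician") policy picks the optimal level with a
  per-stay probability and otherwise uniformly among the other four
  levels, independently per drug. The per-stay skill is drawn once per
  patient, uniform on `clinician_skill` ± `skill_spread` (defaults
  0.7 ± 0.25, clipped to [0, 1]); `skill_spread = 0` recovers a single
  homogeneous knob. The spread matters for evaluation realism: in real
  cohorts, how well dosing tracks the optimum varies between stays, and
  that between-patient variation is the main channel through which
  dose-difference bins acquire an outcome association. With a fully
  homogeneous clinician, bins differ only through within-patient match
  luck — a far weaker signal than any real cohort exhibits — which
  makes U-curve evaluation unrealistically hard rather than
  conservative. The continuous rate is drawn uniformly inside the
  chosen level's band, so discretization recovers the level exactly.

What the simulator does **not** emulate: pharmacokinetics,
measurement-missingness patterns, correlated multi-organ dynamics, or
any real cohort's absolute mortality. Tests passing on this simulator show the pipeline recovers a
known dose–outcome structure; they do not certify performance on real
ICU data.

## Feature preparation

Timestamped measurements are aggregated into half-open 4-hour bins
[4k, 4k+4) (a reading at exactly 4.0 h belongs to bin 1); variables are
averaged or summed per an aggregation map (means for vitals/labs, sums
for fluid volumes). Values outside closed clinical-limit intervals are
set missing and re-imputed. Missing cells are filled by K-nearest
neighbors (k = 5): distances are Euclidean over mutually observed
columns after per-column standardization, and the imputed value is the
column mean over the k nearest rows (delegated to scikit-learn's
KNNImputer inside that standardization wrapper). Complete rows are then
z-scored per column (population σ; constant columns map to 0), with
train-set statistics reapplied to held-out data.

A small autoencoder (48 → 64 → 200 encoder with mirrored decoder,
leaky-ReLU hidden layers, linear code and output, mean-squared
reconstruction loss, mini-batch training with momentum SGD) expands the
normalized features into the 200-dimensional state the agent consumes.
Training/evaluation split is 80/20 by patient.

## The agent

Four networks: online/target actor and online/target critic, each with
two hidden layers and leaky-ReLU activations (slope 0.01). The actor
maps the 200-dim state to a softmax over the 25 joint actions; its
greedy action (lowest index on ties) is the recommendation. The critic
is dueling: a shared first hidden layer feeds separate state-value and
advantage streams, combined as

    Q(s, a_vec) = V(s) + a_vec·A(s,·) − mean_a A(s, a).

The separate streams matter here: the value signal spans ±15 while the
advantage structure is of order 1, and with a fully shared trunk the
value fit dominates the features the advantage stream can use. Because Q
is linear in the action vector, ∂Q/∂a_vec = A(s,·), which makes the
policy-gradient step cheap and exact.

Training is purely offline. Each step draws a batch from the experience
pool with probability ∝ |reward| + ε (ε = 10⁻³ keeps zero-reward
transitions reachable; weights are static). The critic regresses
Q(s, onehot(a)) onto y = r + γ(1 − done)·Q_target(s′, a′), where a′ is
by default the *recorded* next clinician action (the package's central
modification of classical DDPG — the logged next action is stored in
every transition) or, optionally, the target actor's greedy action
(`target_mode="target_actor_action"`, the classical flow; also the mode
under which the critic converges to the optimal Q of a toy MDP, since a
SARSA-style target converges to the behavior policy's Q instead). The
actor ascends mean Q(s, π(s)) using the full probability vector as a
differentiable relaxation of a deterministic policy. Both targets track
their online networks by Polyak updates with rate τ.

Two regularizers proved necessary for offline stability, both exposed in
`AgentConfig`:

- `entropy_coef` (default 0.5): an entropy bonus on the actor objective.
  Without it the softmax saturates numerically onto a single
  state-independent action in the first few hundred steps — before the
  critic differentiates actions — after which the softmax gradient is
  identically zero and the policy is frozen forever. At equilibrium the
  actor approximates softmax(A(s,·)/entropy_coef), whose argmax is the
  greedy action of the critic.
- `adv_decay` (default 0.3): L2 shrinkage applied to the advantage
  stream's output layer. Actions rarely present in the offline pool keep
  near-zero advantage instead of arbitrary extrapolations; this is the
  same conservatism motivation as behavior-regularized offline RL, in
  its simplest form.

Defaults: hidden sizes (128, 128), γ = 0.99, τ = 0.001, batch 64, Adam
with critic lr 10⁻³ and actor lr 10⁻³. Plain mini-batch SGD with
momentum is available (`optimizer="sgd"`) but diverges or underfits on
realistic pools at these rates; Adam is the default for that reason. The
critic loss (squared TD error) is averaged per 50-step episode and
stored in the policy artifact as the TD-error history; training aborts
with the step index if the loss becomes non-finite.

## Evaluation

For every held-out transition the signed per-drug difference
d = clinician_level − model_level is computed (model = greedy actor on
the encoded state), and each transition inherits its patient's final
outcome. The U-curve reports mortality per difference value for one
drug; the 9×9 heatmap crosses both drugs and removes cells with fewer
than 50 transitions as too sparse to interpret; region summaries pool
cells by Chebyshev distance from exact agreement (brown = {(0,0)},
red = ring 1, white = ring 2 — the boxes are configurable since their
exact extent is a presentation choice); and the IV-difference marginal
is reported among transitions with zero VP difference. A mortality
minimum at d = 0 is the qualitative signature that the learned policy's
recommendations align with good outcomes — with the usual caveat that
such curves are confounded by severity (sicker patients both receive
extreme doses and die more), which is why the synthetic-cohort ground
truth matters for testing.

## Numerical choices and degenerate inputs

- All randomness flows from integer seeds through numpy Generators; the
  pipeline's global seed fans out to per-stage seeds (an explicitly set
  stage seed wins), so changing only the evaluation seed leaves training
  artifacts untouched. Identical configs produce byte-identical reports.
- Ties: greedy actions break to the lowest index; KNN neighbor ties
  follow scikit-learn's partition order.
- Terminal transitions carry an all-zero next state and a sentinel next
  action (−1); the TD target masks them by `done`, so the sentinel is
  never consumed.
- Cohort CSVs are written with %.17g floats and read with pandas'
  round-trip parser, so write → read is exact.
- Empty cohort → empty pool; `train_steps=0` → the initial (random)
  policy with an empty TD history; an empty input file parses to an
  empty cohort.

## Problem sizes used in tests

The test suite and the reproduction script run the full method at desk
scale, chosen so the statistical claims are testable rather than to
match any real cohort's size: 2,000 simulated patients (~27k
transitions) for the U-curve property, a 10-transition pool with 10⁵
draws for the sampling chi-square, a 2-state/2-action MDP trained for
6,000 steps for the critic-vs-value-iteration check (tolerance 0.1,
majority of 3 seeds), and a ~30-patient cohort for pipeline determinism.

## Known limitations

- The simulator's single latent severity makes SOFA and lactate
  redundant signals; real data has richer, partially conflicting
  markers.
- The |reward|-weighted sampler concentrates heavily on terminal
  transitions (they carry |r| ≈ 15 versus ≈ 0.1–2 elsewhere); this is
  faithful to the method but is the main obstacle to sharp advantage
  estimates, and is the regime where `adv_decay` matters most.
- Reward-weighted sampling, the recorded-next-action target, and
  transition-level outcome attribution are design commitments of the
  method being implemented, not claims of optimality; no off-policy
  evaluation estimator (WIS, doubly robust) is included.
- U-curve minima are association, not causation; confounding by severity
  is acknowledged, not adjusted for.
- Sparse far bins of the per-drug U-curve (tens of transitions out of
  thousands) are composed non-randomly: a rare large policy error paired
  with a correct clinician dose fills such a bin with survivors. The
  aggregate comparison (zero-difference mortality versus all pooled
  far transitions) is robust at desk scale; per-bin minima at every
  single far bin demand a policy error-tail thinner than this method
  reaches at these sample sizes.
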