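# sepsisrl

Offline reinforcement learning for sepsis dosing: given logged ICU
trajectories of vital signs, SOFA scores, lactate, and the intravenous
fluid (IV) and vasopressor (VP) rates clinicians actually administered,
learn a policy that recommends a joint (IV, VP) dose every 4 hours, and
evaluate it by how patient outcomes relate to the difference between the
clinician's dose and the policy's recommendation.

The package is aimed at researchers studying RL-based clinical decision
support who need a complete, testable implementation of this pipeline —
including a synthetic ICU cohort simulator, since the real cohorts this
method targets are credential-restricted.

## The method

**Actions.** Each drug's rate is discretized into five levels (0 = no
drug; IV breaks at 50, 180, 530 ml/h; VP at 0.08, 0.22,
0.45 µg/kg/min), giving a 5×5 joint action grid, flattened to indices
0–24.

**Reward.** Per transition between consecutive 4-h bins,

  r(s_t, s_{t+1}) = C₀·1[SOFAₜ₊₁ = SOFAₜ ∧ SOFAₜ₊₁ > 0]
                  + C₁·(SOFAₜ₊₁ − SOFAₜ) + C₂·tanh(Lacₜ₊₁ − Lacₜ)

with C₀ = −0.025, C₁ = −0.125, C₂ = −2; ±15 is added at the final
transition for survival/death.

**Agent.** A modified DDPG operating on a discrete action space, trained
purely offline: an actor emitting a softmax over the 25 actions, a
dueling critic Q(s,a) = V(s) + A(s,a) − mean A(s,·), target copies of
both updated by Polyak averaging, and experience drawn from the logged
pool with probability ∝ |reward| + ε. The TD target bootstraps by
default on the *recorded* next clinician action,
y = r + γ(1−done)·Q'(s′, a′).

**Evaluation.** On held-out patients, the per-transition signed
difference d = clinician level − model level (per drug) is related to
in-hospital outcome: U-curves (mortality vs d), a 9×9 dose-difference
histogram with a minimum-count filter of 50, region summaries around
exact agreement, and the IV-difference marginal at zero VP difference.
A mortality minimum at d = 0 indicates the policy's recommendations
align with good outcomes.

States are 200-dimensional autoencoder expansions of 48 per-bin
features (after binning, clinical-limit removal, KNN imputation, and
z-scoring). See `docs/methods.md` for assumptions, parameters, and
design rationale.

## Worked example

```python
from sepsisrl import (SimParams, PreprocessConfig, AgentConfig,
                      generate_cohort, split_by_patient, fit_state_encoder,
                      build_pool, train, dose_differences, ucurve)

cohort = generate_cohort(SimParams(n_patients=600, seed=11))
train_c, test_c = split_by_patient(cohort, 0.2, seed=11)
enc = fit_state_encoder(train_c, PreprocessConfig(encoder_epochs=5, seed=11))
pool = build_pool(train_c, enc)
art = train(pool, AgentConfig(train_steps=6000, batch_size=128, seed=11))
d_iv, d_vp, died = dose_differences(build_pool(test_c, enc), art)
for d, cell in sorted(ucurve(d_iv, died, min_count=20).items()):
    print(f"{d:+d}: mortality {cell['mortality']:.3f} (n={cell['n']})")
```

prints:

```
-4: mortality 0.217 (n=46)
-3: mortality 0.160 (n=94)
-2: mortality 0.146 (n=157)
-1: mortality 0.115 (n=244)
+0: mortality 0.097 (n=607)
+1: mortality 0.099 (n=557)
+2: mortality 0.093 (n=162)
+3: mortality 0.086 (n=81)
+4: mortality 0.054 (n=37)
```

Each row is mortality among held-out transitions with IV dose difference
d = clinician level − policy level. Mortality falls steadily as the
clinician's dose approaches the policy's recommendation from above
(−4 → 0); at this small training scale (600 patients, 6k steps) the
positive arm is still flat — the full-scale experiment in
`scripts/acceptance.py` (2,000 patients, 25k steps) is where the
two-sided shape is assessed. The same scripts live in `examples/`
(simulation, reward arithmetic, training diagnostics, full evaluation),
each printing what its numbers mean.

A thin CLI wraps the same calls:

```
sepsisrl simulate --n-patients 500 --seed 1 --out cohort.csv
sepsisrl run-all --seed 1 --out runs/demo     # full pipeline + report.json
sepsisrl validate-config config.yaml
```

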