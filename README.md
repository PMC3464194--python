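# rewardctl

Reward- and effort-based optimal decision making and motor control in one
package: a single discounted utility — expected reward minus foreseeable
motor effort,

```
J(T) = rho * r * exp(-T / gamma)  -  eps * ∫ exp(-s/gamma) ||u(s)||^2 ds
```

— simultaneously yields choices among actions (utility maximisation),
emergent movement durations (golden-section search over the reward/effort
trade-off), and online feedback control of noisy, delayed, perturbable
plants.

Three controlled objects are provided:

| object | description | use |
|---|---|---|
| point mass | 1-D force-driven point (closed-form solutions) | cost/benefit decisions |
| filtered point | point mass behind a 2nd-order muscle filter | speed/accuracy trade-off under noise |
| planar arm | two-joint arm, two antagonist muscle pairs | realistic reaching, target jumps, force fields |

## Layout

- `rewardctl.plants` — plant specs, dynamics, kinematics, analytic Jacobians
- `rewardctl.ocp_linear` — discounted finite-horizon optimal control for
  linear plants (stable Gramian closed forms), 1-D point-mass closed forms,
  two-condition (vigor, discount) identification
- `rewardctl.ocp_nonlinear` — adjoint-gradient trajectory optimiser for the arm
- `rewardctl.horizon` — the discounted objective over prospective durations
  and the emergent optimal duration (pre-scan + golden section)
- `rewardctl.feedback` / `feedback_arm` — closed loop: receding-horizon
  controller, delayed Kalman estimator, signal-dependent motor noise,
  target-jump and force-field perturbations, movement-end detection
- `rewardctl.decision` — option utilities, indifference points, softmax
  choice, synthetic-cohort spatial-discounting pipeline
- `rewardctl.experiments` / `cli` — config-driven experiment reproductions

## CLI

```bash
rewardctl <subcommand> --config FILE --out DIR --seed INT
```

Subcommands: `stevens` (cohort decision pipeline), `scaling`
(amplitude/direction reaching), `jump` (target jumps), `forcefield`,
`fitts` (duration vs index of difficulty under motor noise), plus small
calculators `utility`, `duration`, `choose`. Configs are JSON or YAML
mappings overriding the documented defaults in `rewardctl.experiments`;
outputs are CSV tables, a JSON summary, and a run manifest.

Examples:

```bash
rewardctl duration -A 0.35 -r 1 --vigor 21.5 --gamma 0.885
rewardctl stevens --out results/stevens --seed 1
rewardctl fitts --out results/fitts --seed 1        # N=200 trials/condition
```

## Notes

- All randomness flows through explicit seeds; identical seeds give
  bit-identical traces.
- Units are SI throughout (m, s, kg, N); configs accept degrees for arm
  postures and directions.
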