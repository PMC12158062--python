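# rtee

Real-time personalized energy-expenditure (EE) estimation from heart rate.

The estimator couples the modified MET predictor

```
EE_pred(kcal/s) = RMR_sec * (1 + a)
```

with a deep Q-network that infers the activity-intensity coefficient
`a ∈ {0, 0.1, …, 20}` (201 discrete actions) from a five-component state —
weight, height, age, gender and the current heart rate — sampled once per
second. `RMR_sec` is the Mifflin-St Jeor resting metabolic rate divided down
to seconds. Also included:

- the classical baselines: indirect calorimetry from VO₂ (the ground-truth
  generator), the MET product formula, and the Keytel heart-rate regression,
  with explicit unit conversions (`rtee.formulas`);
- a synthetic per-second session generator emulating a 30-minute
  sit/stand/cycle/run wearable protocol (six 5-minute segments, 1 Hz), with a
  first-order VO₂ lag and AR(1) heart-rate noise (`rtee.synth`);
- a sliding-window episodic environment with the GT-normalized reward
  `-|gt - pred| / (1 + gt)` (`rtee.env`);
- the DQN agent — a numpy MLP (5-64-64-201, ReLU) with Adam, experience
  replay (capacity 50,000), ε-greedy exploration and a target network
  (`rtee.agent`); no deep-learning framework is required;
- an MAE evaluation protocol reporting overall and per-activity-segment
  errors for the agent and both baselines, plus a scenario-length (300 s vs
  60 s) ablation (`rtee.evaluation`);
- a CLI and YAML/override configuration layer (`rtee.cli`, `rtee.config`).

## CLI

All commands share `--config <yaml>`, `--set key=value` (repeatable),
`--seed <int>` and `--out <dir>`; precedence is CLI > file > defaults, and
each run writes its resolved config, hash and log into the output directory.

```sh
# 17 synthetic 30-minute sessions (CSV + profile sidecar JSON + manifest)
rtee simulate --seed 1 --out runs/sim

# train (leave-out split: one male + one female); writes checkpoint.npz,
# loss_history.csv, split.json
rtee train --seed 1 --out runs/train --sessions runs/sim \
    --set training.epochs=10 --set training.train_stride_s=30

# MAE report (rows: ours/keytel/met; columns: Total + six segments)
rtee evaluate --seed 1 --out runs/eval --checkpoint runs/train/checkpoint.npz \
    --sessions runs/sim --split runs/train/split.json \
    --set training.epochs=10 --set training.train_stride_s=30

# per-second predictions for one session
rtee predict --out runs/pred --checkpoint runs/train/checkpoint.npz \
    --session runs/sim/session_P01.csv
```

Session CSV schema: `time_s, hr_bpm, vo2_ml_kg_min, activity, met_true`,
with a `.json` sidecar carrying the participant profile and generator
parameters.

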