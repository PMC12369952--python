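# processgan

Conditional adversarial generation of privacy-preserving process traces —
activity sequences with per-activity timestamps — from event logs, together
with a multi-task context generator and a three-part evaluation suite.

The generator is a conditional transformer encoder: it maps a random
activity sequence plus a case duration (sampled from authentic durations and
min-max normalized) to per-position activity probability rows and timestamp
differentials, generated in parallel (non-autoregressive). Discrete samples
reach the discriminator through a straight-through Gumbel-softmax bridge.
The discriminator is a time-aware multi-head self-attention network that
scores cases from the interactions among activity one-hots, timestamp
differentials, and the antisymmetric pairwise time-interval matrix. Training
alternates generator updates every epoch with discriminator updates every
k-th epoch, adds activity-frequency and timestamp-mean divergence losses
with auto-calibrated weights, and checkpoints periodically so the run closest
to discriminator-accuracy 0.5 can be selected.

All neural models run on a small NumPy reverse-mode autograd contained in
the package (`processgan/_autograd.py`, `processgan/_nn.py`) — no deep
learning framework is required.

## Layout

| module | role |
| --- | --- |
| `processgan.event_log_io` | CSV/XES event-log reading, validation, writing; activity vocabulary with a reserved pad token |
| `processgan.encoding` | padded one-hots, timestamp differentials, normalized durations, time-interval matrices |
| `processgan.generator` | conditional transformer generator + Gumbel straight-through sampling |
| `processgan.time_aware_discriminator` | time-aware attention discriminator (+ vanilla-encoder ablation) |
| `processgan.adversarial_training` | losses, auxiliary-weight calibration, training schedule, checkpoints, decoding to a synthetic log |
| `processgan.context_generator` | shared-encoder multi-task context model with homoscedastic-uncertainty loss weighting |
| `processgan.evaluation` | length/SPE/ActError/TimeError statistics, negative-sampling supervised scorer (FPR), consensus-workflow summary |
| `processgan.fixture_simulator` | ground-truth workflow simulator (branches, parallel block, delay models, context rules) |

## CLI

```sh
processgan simulate --n 250 --seed 1 --out fixture.csv          # built-in clinic-small workflow
processgan train --log fixture.csv --config cfg.yaml --out runs/demo
processgan generate --checkpoint runs/demo/ckpt_00300.npz --log fixture.csv \
    --n 250 --seed 1 --out synth.csv
processgan evaluate --authentic fixture.csv --synthetic synth.csv --out report.json
processgan context train --log fixture.csv --schema schema.yaml --out ctx/
processgan context infer --model ctx/ --log synth.csv --out synth_ctx.csv
processgan encode --log fixture.csv --case case_00000             # debug dump
```

Training config YAML keys mirror the model tables: `batch_size`, `embedding`,
`hidden_g`, `hidden_d`, `heads_g`, `heads_d`, `layers_g`, `layers_d`,
`dropout_g`, `dropout_d`, `lr_g`, `lr_d`, plus `k`, `epochs`, `seed`,
`aux_weights` (pair or omit for auto-calibration) and `no_time_attention`
(ablation). A context schema YAML lists tasks:

```yaml
tasks:
  - {name: context_specialist, kind: categorical, levels: ["no", "yes"]}
  - {name: context_delay, kind: numerical}
```

## Notes

- Everything is reproducible from explicit seeds: same seed + config gives
  byte-identical simulated logs, synthetic logs, loss reports and evaluation
  JSON.
- `generate` decodes by Gumbel-max sampling of the activity rows by default
  (`decode="argmax"` is available); sampling matches the discrete draws the
  discriminator was trained against.
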