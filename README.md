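# recarch

A simulator of the **recommendation architecture**: a brain-inspired
learning model in which a columnar cortex learns its feature detectors from
*temporal correlations alone* — Hebbian potentiation with reversal,
miss-driven depression and homeostatic scaling, but no reward and no error
signal — while a minimal basal-ganglia readout learns *only* from
consequence feedback how strongly each column's output recommends each
behaviour (here: one of 30 category labels).

The package is for computational-neuroscience and continual-learning
researchers who want a reproducible, numpy-vectorised testbed for two
questions:

1. **Novelty learning** — how accurately can consequence-free condition
   definition plus a thin recommendation readout learn 30 categories of
   never-identical spiking stimuli?
2. **Knowledge retention** — how much does training a second set of
   categories damage the first set, and how much of the damage can be
   repaired with *correct/incorrect-only* feedback that never reveals the
   right answer?

## Model in brief

Stimuli: each category is a propensity profile `P_c ∈ {0..200}^400`; at
each 1/3 ms timeslot afferent `i` spikes iff `P[i]·m(t) > r` with
`r ~ U{1..10⁴}` and `m(t)` a 40 Hz gamma duty-cycle envelope (50 high / 5
low, 8 slots per period).  Three categories are interleaved per 200 ms
working-memory window (75 periods, 25 per category).

Cortex: columns of 10 layer-1 (10 branches × 120 synapses each), 10
layer-2 and 1 layer-3 neuron; branch-then-neuron threshold integration;
initial wiring biased toward per-column groups of inputs that co-spiked in
an unprocessed sample (the simulated hippocampal "dream sleep" role).

Readout: recommendation weights `W[col, c]` start uniform; a decision for
a segment with column spike counts `n` ranks categories by
`total[c] = Σ_col n_col W[col, c]`.  Teacher feedback adds
`α·n_col` toward the correct category and shrinks a wrong top choice by a
small proportion; correct/incorrect-only feedback can only shrink wrong
top choices.

See `docs/methods.md` for the full rules, the frozen constants and their
rationale.

## Worked example

```python
from recarch import ExperimentConfig, run_experiment_one

cfg = ExperimentConfig(seed=0)          # 15 columns, 30 categories,
metrics = run_experiment_one(cfg)       # 300/600/300-instance curriculum
s = metrics.stage("test")
print(f"top1={s.top1:.3f} top2={s.top2:.3f} top3={s.top3:.3f}")
```

prints

```
top1=0.760 top2=0.850 top3=0.913
```

i.e. on 300 never-seen test instances the readout's first choice is
correct 76.0 % of the time, and the correct category is within the top two
ranked recommendations 85.0 % and top three 91.3 % of the time — the
benefit of a readout that ranks *all* categories instead of emitting a
single label.  The same run from the shell, with CSV/JSONL outputs:

```bash
ra-sim -v run-exp1 --out results/exp1 --seed 0
ra-sim -v run-exp2 --out results/exp2 --seed 0     # split training + recovery
ra-sim gen-stimuli --out stimuli --limit 10        # export rendered windows
```

`run-exp2` reports per-stage metrics (`after_split`,
`after_feedback_pass`, `after_relearn`) including per-set accuracies and
the set-balance ratio (first-set accuracy / second-set accuracy; 1 means
balanced retention).

## Layout

```
src/recarch/
  stimgen.py        stimulus profiles, chance draw, envelopes, curricula
  hippocampus.py    co-activation grouping (wiring bias)
  cortex.py         columnar integration + window plasticity + checkpoints
  basal_ganglia.py  recommendation weights, decisions, feedback rules
  experiments.py    experiment orchestration, metrics, result files
  cli.py            ra-sim command-line interface
tests/              pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md
```
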