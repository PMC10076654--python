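# Methods

## The model

`recarch` simulates a *recommendation architecture*: a learning system in
which feature definition and behaviour selection are learned by different
mechanisms.  A columnar cortex clusters its inputs using only temporal
correlations (no reward, no error signal); a minimal basal-ganglia readout
learns, from consequence feedback alone, how strongly each cortical
column's output *recommends* each of 30 category labels.  The task is a
30-way categorisation of spiking stimuli in which no stimulus instance is
ever repeated.

### Stimuli

Each category `c` is a fixed *propensity profile* `P_c ∈ {0..200}^400`,
drawn once per model instantiation.  Components are sampled uniformly from
a level pool in which the multiplicity of level `v` decays linearly from 5
at `v = 0` to 1 at `v = 200` (pool mean ≈ 76.8), so high-propensity
components are deliberately rare.  At timeslot `t` (a notional 1/3 ms),
afferent `i` spikes iff

    P_active(t)[i] · m(t)  >  r,     r ~ Uniform{1, …, 10000},

giving spike probability `clamp(⌈P·m⌉ − 1, 0, 10⁴)/10⁴`.  The modulation
envelope `m(t)` models 40 Hz thalamic gamma: 8-timeslot periods, `m = 50`
in the first four slots of a period and `m = 5` in the last four, so the
peak product is `200 × 50 = 10⁴` (spike probability ≈ 1) and the duty
cycle separates a strong-drive phase from a near-silent phase.  A working
memory window interleaves three categories round-robin over 75 gamma
periods (25 each), 600 timeslots = 200 ms in total.

Phase sizes throughout are counted in category *instances*; one window
carries three instances.  "1,200 presentations (40 of each category)"
therefore means 400 windows.

### Cortex

Each column has 10 layer-1 neurons, 10 layer-2 neurons and one layer-3
neuron.  A layer-1 neuron carries 10 dendritic branches × 120 synapses
(≈1,200 synapses); each synapse's source is drawn i.i.d. — with
probability `p_bias = 0.6` uniformly from the column's co-activation group
(below), otherwise uniformly from all 400 afferents.  Repeated
(branch, source) pairs are collapsed into an integer multiplicity.
Layer-2 neurons carry 2 branches × 5 synapses that partition the column's
layer-1 population; the layer-3 neuron does the same over layer 2.
Integration is two-stage: a branch fires when its weighted input sum
reaches `θ_branch`; the neuron fires when at least `θ_neuron` branches
fire.  Spikes cross layers with a one-timeslot delay, so layer-3 output
lags the stimulus by two timeslots (respected when attributing layer-3
spikes to category segments).

Weights are constant within a 200 ms window; all plasticity commits at the
window end:

* **Potentiation with reversal** — a synapse whose afferent was active in
  the same or the immediately preceding timeslot of ≥3 fires of its neuron
  within the window gains `Δ_pot`; with fewer pairings the tentative
  increase is reversed exactly.
* **Miss-driven depression** — a synapse whose branch fired ≥ `m_miss`
  times without that synapse contributing loses `Δ_dep`, floored at 0.
* **Homeostatic scaling** — a neuron firing more than `ρ_max` times in the
  window has all weights multiplied by `s_homeo`, preserving ratios.
* Weights are capped at `w_max` per synapse.

Because within-window dynamics are feed-forward and time-invariant, each
layer's firing over a whole window is evaluated with one matrix product,
and the plasticity counters reduce to window-level matrix products over
the stored spike histories.  The incremental `step_timeslot` path computes
the same quantities slot by slot and is held equal to both the batched
path and a per-synapse loop oracle in the tests.

### Hippocampus

The only hippocampal function simulated is a wiring bias derived before
learning ("dream sleep"): from 30 unprocessed sample windows, a 400×400
co-occurrence matrix counts timeslots in which each input pair co-spiked.
Inputs are clustered into `n_columns` groups by greedy size-capped
average-linkage agglomeration on the cosine-normalised co-occurrence
(cap = ⌈1.5·400/n_columns⌉; ties to the lowest index; inputs with no
co-occurrence join the smallest group).  Each column's layer-1 wiring is
biased toward one group.  This bias is the dominant source of category
selectivity: with `p_bias = 0`, test accuracy collapses to chance.

### Basal ganglia

A weight matrix `W ∈ R^(n_columns × 30)` starts uniform at `w0`.  For each
category segment of a window, the decision totals are
`total[c] = Σ_col n_col · W[col, c]` where `n_col` is the column's layer-3
spike count in that segment; categories are ranked by total (ties to the
lowest index), so 2nd and 3rd choices are defined.  Feedback updates:

* **teacher** (correct label given): `W[col, correct] += α_up · n_col`; if
  the top choice was wrong, `W[col, chosen] *= (1 − δ_teacher)` for every
  column with output;
* **correct/incorrect only**: a wrong choice is punished the same way with
  `δ_feedback`; nothing is potentiated (the correct label is unknown).
  Correct feedback is a no-op by default (`correct_boost = 0`).

Feedback never touches cortical synapses, so one cortex run can be
replayed against different readout settings via the checkpoint API.

## Frozen constants

The published description fixes the architecture and rules but not the
numerical constants, which were calibrated once against the headline
accuracy bands and then frozen:

| constant | value | role |
|---|---|---|
| θ_branch | (75, 3, 3) | branch thresholds per layer |
| θ_neuron | (2, 2, 2) | branches needed per neuron |
| w_init / w_max | 1.0 / (4, 3, 3) | initial and maximal synaptic weight |
| Δ_pot / Δ_dep | (0.10, 0.10, 0.10) / (0.04, 0.05, 0.05) | plasticity steps |
| pair_min / m_miss | 3 / (6, 6, 6) | pairing and miss thresholds |
| ρ_max / s_homeo | (60, 60, 60) / 0.9 | homeostasis |
| p_bias | 0.6 | wiring-bias strength |
| w0 / α_up | 1.0 / 1.0 | readout init and teacher step |
| δ_teacher / δ_feedback | 0.006 / 0.42 | punishment proportions |

Two punishment regimes are deliberate.  The teacher-mode proportion must
be small: wrong choices during training of the *second* category set
repeatedly punish first-set weights, and the compounded multiplicative
erosion is the sole driver of catastrophic forgetting in the readout (the
cortical representations themselves stay comparatively stable).  The
correct/incorrect-only proportion must be large: this low-information
signal works by demoting over-dominant wrong winners until buried earlier
learning resurfaces, and a strong proportion reproduces the observed
*partial* recovery that rebalances the two sets rather than restoring
peak accuracy.

## Experiments

**Experiment one (novelty)** — fixed repeating category order; 300
cortex-only instances, 600 teacher instances, 300 test instances (100/200/
100 windows).  Decisions in the test phase update no weights, but cortical
plasticity never pauses.  Reported: top-1/2/3 accuracy over the 300 test
decisions; medians over 5 seeds.

**Experiment two (interference and recovery)** — 300 cortex-only
instances, then teacher training on categories 1–15 (300 instances),
then 16–30 (300 instances), then a 300-instance test of all 30
("after_split"); a correct/incorrect-only pass of 10 instances per
category and a retest ("after_feedback_pass"); one teacher instance per
category and a final retest ("after_relearn").  The per-set teacher count
mirrors experiment one's 20 teacher instances per category.  Reported:
per-set and overall top-k accuracies and the set-balance ratio (first-set
accuracy / second-set accuracy).

## What the generator does and does not emulate

The synthetic stimuli reproduce the statistical structure of the task:
never-identical instances, propensity-defined categories, gamma-modulated
sparseness, working-memory interleaving.  They do not model natural-image
or sensory correlations (within a category, components are independent
given the profile), receptor adaptation, or any temporal structure beyond
the gamma envelope.  Passing tests therefore demonstrate the learning
dynamics on this task family, not performance on natural data.

## Numerical choices and degenerate inputs

* All randomness flows from one `numpy` `SeedSequence`; child streams for
  profiles, hippocampal sampling, wiring and per-window rendering keep the
  cortex replayable against different readout settings.  Runs are
  byte-reproducible for a fixed config.
* Plasticity order within a window end: potentiation, depression,
  homeostasis, cap.  Firing comparisons use `>=` on float32 sums.
* Ranking ties break to the lowest category index; an all-zero count
  vector yields index order.
* A zero second-set accuracy makes the set-balance ratio `inf` with a
  warning rather than an exception.
* Degenerate stimuli (all-zero profiles) render all-zero spike matrices
  and propagate to zero counts without error.

## Known limitations

* The constants above are one calibrated point, not a fitted posterior;
  accuracy bands have seed-to-seed spread of several percentage points.
* Top-3 metrics around the split-training stages run several points above
  the published values: with the small teacher punishment required for
  top-1 retention, a beaten first-set category almost always survives
  inside the top 3, so the top-3/top-1 retention gap is wider here than in
  the original model.  Recovery quality is likewise sensitive to
  `δ_feedback`; see the acceptance suite for the exact checks.
* Indirect activation, action sequencing and richer hippocampal/amygdala
  roles are out of scope, as is any claim about wall-clock or memory
  efficiency relative to deep-learning baselines.
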