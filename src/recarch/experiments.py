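"""Experiment orchestration: novelty learning and split-training recovery.

Experiment one (novelty): a fixed-order curriculum over all 30 categories —
a cortex-only warm-up, a teacher-feedback phase, and a no-weight-update test
phase (cortical plasticity never stops).  Experiment two (interference):
teacher-train the first 15 categories, then the second 15, test all 30
("after_split"), optionally run a correct/incorrect-only recovery pass and
retest ("after_feedback_pass"), and optionally a one-instance-per-category
teacher relearn pass and retest ("after_relearn").

Metrics are top-k accuracies (k = 1, 2, 3) overall and per category set,
and the set-balance ratio — first-set accuracy divided by second-set
accuracy, 1 meaning balanced retention.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .basal_ganglia import (Decision, decide, init_weights, learn_feedback_only,
                            learn_teacher)
from .config import ExperimentConfig
from .cortex import init_cortex, run_presentation
from .errors import ConfigError
from .hippocampus import derive_coactivation_groups
from .stimgen import (Curriculum, build_curriculum, make_envelope,
                      make_profiles, render_presentation, _windows)

__all__ = ["StageMetrics", "ExperimentMetrics", "run_experiment_one",
           "run_experiment_two", "topk_accuracy", "set_balance_ratio",
           "write_results"]

log = logging.getLogger("recarch")


@dataclass(frozen=True)
class StageMetrics:
    top1: float
    top2: float
    top3: float
    n_decisions: int
    set_a: Optional[Dict[str, float]] = None   # top1/top3 over first half
    set_b: Optional[Dict[str, float]] = None
    set_balance_ratio: Optional[float] = None


@dataclass
class ExperimentMetrics:
    stages: Dict[str, StageMetrics]
    learning_curve: List[Tuple[int, int]]      # (teacher decision idx, correct)
    decision_log: List[dict]
    config_hash: str

    def stage(self, name: str) -> StageMetrics:
        return self.stages[name]


# ---------------------------------------------------------------------------
# metric helpers

def topk_accuracy(rankings: Sequence[Sequence[int]],
                  labels: Sequence[int], k: int) -> float:
    """Fraction of decisions whose top-k ranking contains the true label."""
    if len(rankings) == 0:
        raise ConfigError("empty decision log")
    if len(rankings) != len(labels):
        raise ConfigError("rankings and labels must align")
    if k < 1 or k > len(rankings[0]):
        raise ConfigError("k must lie in [1, n_categories]")
    hits = sum(1 for r, lab in zip(rankings, labels) if lab in list(r)[:k])
    return hits / len(rankings)


def set_balance_ratio(acc_first: float, acc_second: float) -> float:
    """First-set accuracy over second-set accuracy; inf if the latter is 0."""
    if acc_second == 0:
        warnings.warn("second-set accuracy is zero; ratio undefined",
                      RuntimeWarning)
        return math.inf
    return acc_first / acc_second


def _stage_metrics(rankings: List[np.ndarray], labels: List[int],
                   n_categories: int, split: bool) -> StageMetrics:
    accs = [topk_accuracy(rankings, labels, k) for k in (1, 2, 3)]
    set_a = set_b = None
    ratio = None
    if split:
        half = n_categories // 2
        ia = [i for i, lab in enumerate(labels) if lab < half]
        ib = [i for i, lab in enumerate(labels) if lab >= half]
        if ia and ib:
            ra, la = [rankings[i] for i in ia], [labels[i] for i in ia]
            rb, lb = [rankings[i] for i in ib], [labels[i] for i in ib]
            set_a = {f"top{k}": topk_accuracy(ra, la, k) for k in (1, 2, 3)}
            set_b = {f"top{k}": topk_accuracy(rb, lb, k) for k in (1, 2, 3)}
            ratio = set_balance_ratio(set_a["top1"], set_b["top1"])
    return StageMetrics(top1=accs[0], top2=accs[1], top3=accs[2],
                        n_decisions=len(labels), set_a=set_a, set_b=set_b,
                        set_balance_ratio=ratio)


# ---------------------------------------------------------------------------
# runner

class _Runner:
    """Holds the model state shared across the phases of one run."""

    def __init__(self, cfg: ExperimentConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        s_prof, s_hippo, s_wiring, self._s_stim = ss.spawn(4)
        self.profiles = make_profiles(cfg.stimulus,
                                      np.random.default_rng(s_prof))
        self._env_cache: dict = {}

        # hippocampal "dream sleep" pass over unprocessed instances
        cats = list(range(cfg.stimulus.n_categories))
        sample_specs = _windows(cats, 3 * cfg.hippocampus_sample, "cortex_only")
        hippo_rng = np.random.default_rng(s_hippo)
        sample = [self._render(spec.labels, hippo_rng) for spec in sample_specs]
        self.groups = derive_coactivation_groups(sample, cfg.cortex.n_columns)
        log.info("hippocampal groups derived from %d presentations",
                 len(sample))

        self.cortex = init_cortex(cfg.cortex, self.groups.groups,
                                  np.random.default_rng(s_wiring),
                                  n_inputs=cfg.stimulus.n_inputs)
        self.rm = init_weights(cfg.cortex.n_columns,
                               cfg.stimulus.n_categories, cfg.readout.w0)
        self.curve: List[Tuple[int, int]] = []
        self.decision_log: List[dict] = []
        self._teacher_i = 0

    def _render(self, labels: Tuple[int, ...], rng: np.random.Generator):
        stim = self.cfg.stimulus
        n_per = stim.triple_periods if len(labels) == 3 else stim.single_periods
        if n_per not in self._env_cache:
            self._env_cache[n_per] = make_envelope(stim, n_per)
        return render_presentation([self.profiles[c] for c in labels],
                                   self._env_cache[n_per], rng, stim)

    def run(self, curriculum: Curriculum,
            test_stage_names: List[str]) -> Dict[str, List]:
        """Drive the curriculum; returns per-test-stage (rankings, labels)."""
        cfg = self.cfg
        specs = curriculum.entries
        seeds = self._s_stim.spawn(len(specs))
        stages: Dict[str, List] = {name: ([], []) for name in test_stage_names}
        test_block = -1
        prev_phase = None
        for i, spec in enumerate(specs):
            pres = self._render(spec.labels, np.random.default_rng(seeds[i]))
            counts = run_presentation(self.cortex, pres)
            if spec.phase == "test" and prev_phase != "test":
                test_block += 1
            prev_phase = spec.phase
            if spec.phase == "cortex_only":
                continue
            stage = test_stage_names[test_block] if spec.phase == "test" else None
            for k, lab in enumerate(spec.labels):
                c_k = counts[:, k]
                d = decide(self.rm, c_k)
                feedback = "none"
                if spec.phase == "teacher":
                    learn_teacher(self.rm, c_k, d, lab,
                                  cfg.readout.alpha_up, cfg.readout.delta_down)
                    self.curve.append((self._teacher_i,
                                       int(d.chosen == lab)))
                    self._teacher_i += 1
                    feedback = "teacher"
                elif spec.phase == "feedback_only":
                    learn_feedback_only(self.rm, c_k, d, d.chosen == lab,
                                        cfg.readout.delta_down_feedback,
                                        cfg.readout.correct_boost)
                    feedback = "correct" if d.chosen == lab else "incorrect"
                else:  # test
                    stages[stage][0].append(d.ranking)
                    stages[stage][1].append(lab)
                self.decision_log.append({
                    "presentation": i, "segment": k, "phase": spec.phase,
                    "stage": stage, "label": int(lab), "chosen": d.chosen,
                    "ranking": [int(c) for c in d.ranking],
                    "totals": [round(float(t), 4) for t in d.totals],
                    "feedback": feedback,
                })
        return stages


def _metrics_from_stages(runner: _Runner, stages: Dict[str, List],
                         split: bool) -> ExperimentMetrics:
    n_cat = runner.cfg.stimulus.n_categories
    out = {}
    for name, (rankings, labels) in stages.items():
        out[name] = _stage_metrics(rankings, labels, n_cat, split)
        log.info("stage %-20s top1=%.3f top2=%.3f top3=%.3f (n=%d)",
                 name, out[name].top1, out[name].top2, out[name].top3,
                 out[name].n_decisions)
    return ExperimentMetrics(stages=out, learning_curve=runner.curve,
                             decision_log=runner.decision_log,
                             config_hash=runner.cfg.config_hash())


def run_experiment_one(cfg: ExperimentConfig) -> ExperimentMetrics:
    """Novelty learning: warm-up / teacher / no-feedback test over 30 categories."""
    if cfg.experiment != "one":
        raise ConfigError("config does not describe experiment one")
    runner = _Runner(cfg)
    curriculum = build_curriculum(cfg)
    stages = runner.run(curriculum, ["test"])
    return _metrics_from_stages(runner, stages, split=False)


def run_experiment_two(cfg: ExperimentConfig) -> ExperimentMetrics:
    """Split training, interference measurement, and recovery passes."""
    if cfg.experiment != "two":
        raise ConfigError("config does not describe experiment two")
    runner = _Runner(cfg)
    curriculum = build_curriculum(cfg)
    names = ["after_split"]
    if cfg.feedback_pass:
        names.append("after_feedback_pass")
    if cfg.relearn:
        names.append("after_relearn")
    stages = runner.run(curriculum, names)
    return _metrics_from_stages(runner, stages, split=True)


# ---------------------------------------------------------------------------
# output

def write_results(metrics: ExperimentMetrics, cfg: ExperimentConfig,
                  out_dir: str | Path) -> Path:
    """Write summary CSV, decision log (JSONL), learning curve and config."""
    import pandas as pd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = metrics.config_hash

    rows = []
    for name, m in metrics.stages.items():
        row = {"stage": name, "acc1": m.top1, "acc2": m.top2, "acc3": m.top3,
               "n": m.n_decisions}
        if m.set_a:
            row.update({"acc1_setA": m.set_a["top1"], "acc3_setA": m.set_a["top3"],
                        "acc1_setB": m.set_b["top1"], "acc3_setB": m.set_b["top3"],
                        "set_balance_ratio": m.set_balance_ratio})
        rows.append(row)
    with open(out / "summary.csv", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)

    with open(out / "decisions.jsonl", "w") as fh:
        fh.write(json.dumps({"config_hash": h}) + "\n")
        for entry in metrics.decision_log:
            fh.write(json.dumps(entry) + "\n")

    with open(out / "learning_curve.csv", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        pd.DataFrame(metrics.learning_curve,
                     columns=["teacher_decision", "correct"]).to_csv(
            fh, index=False)

    cfg.to_yaml(out / "config.yaml")
    log.info("results written to %s (config %s)", out, h)
    return out / "summary.csv"
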