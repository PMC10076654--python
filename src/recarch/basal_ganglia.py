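"""Basal-ganglia readout: recommendation weights, decisions and feedback.

Every cortical column's layer-3 neuron carries one recommendation weight per
category.  A decision sums, for each category, the column spike counts of a
200 ms segment weighted by those recommendations, and ranks categories by
total — so 2nd and 3rd choices exist alongside the top choice.

Two consequence-feedback modes adjust the weights (never the cortex):

* teacher — the correct category is named: its weights grow in proportion to
  each column's spike count; if the top-ranked category was wrong, the
  weights toward that wrong category of every column that produced output
  shrink by a fixed proportion;
* correct/incorrect only — a single bit: a wrong choice is punished exactly
  as above, but nothing is potentiated because the correct category is
  unknown (an optional small boost on correct feedback is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np

from .errors import ConfigError

__all__ = ["RecommendationMatrix", "Decision", "init_weights", "decide",
           "learn_teacher", "learn_feedback_only", "save_weights",
           "load_weights"]


@dataclass
class RecommendationMatrix:
    weights: np.ndarray           # (n_columns, n_categories) >= 0
    w0: float

    @property
    def n_columns(self) -> int:
        return self.weights.shape[0]

    @property
    def n_categories(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class Decision:
    totals: np.ndarray            # (n_categories,)
    ranking: np.ndarray           # categories, best first; ties -> lowest index
    chosen: int

    def topk(self, k: int) -> np.ndarray:
        return self.ranking[:k]


def init_weights(n_columns: int, n_categories: int,
                 w0: float) -> RecommendationMatrix:
    """All recommendation weights start at the same low positive value."""
    if n_columns < 1 or n_categories < 1:
        raise ConfigError("dimensions must be >= 1")
    if w0 <= 0:
        raise ConfigError("w0 must be positive")
    return RecommendationMatrix(
        weights=np.full((n_columns, n_categories), float(w0)), w0=float(w0))


def decide(rm: RecommendationMatrix, counts: np.ndarray) -> Decision:
    """Rank categories by spike-count-weighted recommendation totals."""
    counts = np.asarray(counts)
    if counts.shape != (rm.n_columns,):
        raise ConfigError("counts length must equal the number of columns")
    if np.any(counts < 0):
        raise ConfigError("spike counts must be non-negative")
    totals = counts.astype(float) @ rm.weights
    ranking = np.argsort(-totals, kind="stable")   # stable => lowest index wins ties
    return Decision(totals=totals, ranking=ranking, chosen=int(ranking[0]))


def learn_teacher(rm: RecommendationMatrix, counts: np.ndarray,
                  decision: Decision, correct: int,
                  alpha_up: float, delta_down: float) -> RecommendationMatrix:
    """Teacher-signal update (in place; the matrix is also returned).

    Weights toward the correct category grow by ``alpha_up`` per spike the
    column produced; if the top choice was wrong, weights toward that choice
    shrink by the proportion ``delta_down`` for every column with output.
    """
    if not 0.0 <= delta_down < 1.0:
        raise ConfigError("delta_down must lie in [0, 1)")
    counts = np.asarray(counts, dtype=float)
    rm.weights[:, correct] += alpha_up * counts
    if decision.chosen != correct:
        active = counts > 0
        rm.weights[active, decision.chosen] *= (1.0 - delta_down)
    return rm


def learn_feedback_only(rm: RecommendationMatrix, counts: np.ndarray,
                        decision: Decision, is_correct: bool,
                        delta_down: float,
                        correct_boost: float = 0.0) -> RecommendationMatrix:
    """Correct/incorrect-only update: punish a wrong choice, add nothing.

    The correct category is never identified, so no weight can be singled
    out for potentiation; recovery relies on demoting wrong top choices so
    the (often correct) 2nd or 3rd choice surfaces.
    """
    if not 0.0 <= delta_down < 1.0:
        raise ConfigError("delta_down must lie in [0, 1)")
    counts = np.asarray(counts, dtype=float)
    active = counts > 0
    if is_correct:
        if correct_boost > 0.0:
            rm.weights[:, decision.chosen] += correct_boost * counts
    else:
        rm.weights[active, decision.chosen] *= (1.0 - delta_down)
    return rm


def save_weights(rm: RecommendationMatrix, path: str | Path,
                 header: str = "") -> None:
    """CSV dump (one row per column) with an optional comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# w0={rm.w0}\n")
        np.savetxt(fh, rm.weights, delimiter=",")


def load_weights(path: str | Path) -> RecommendationMatrix:
    path = Path(path)
    w0 = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# w0="):
                w0 = float(line.split("=", 1)[1])
    weights = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return RecommendationMatrix(weights=weights,
                                w0=w0 if w0 is not None else float(weights.min()))
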