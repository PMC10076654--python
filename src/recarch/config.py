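"""Configuration dataclasses and YAML (de)serialisation.

Every tunable of the simulator lives here.  Parameters are grouped by the
brain component they belong to; per-layer parameters are length-3 tuples
ordered (layer 1, layer 2, layer 3).  All defaults are the frozen values
used for the headline experiments; see docs/methods.md for the rationale
behind each.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

from .errors import ConfigError

Triple = Tuple[float, float, float]
ITriple = Tuple[int, int, int]


@dataclass(frozen=True)
class StimulusParams:
    """Parameters of the never-identical categorical stimulus generator.

    An input presentation is a binary spike matrix over ``n_inputs`` afferents.
    Spike probability for one afferent at one timeslot is
    ``(ceil(propensity * modulation) - 1) / chance_range`` clamped to [0, 1]:
    a spike occurs when the propensity-modulation product exceeds an integer
    drawn uniformly from ``1..chance_range``.
    """

    n_inputs: int = 400
    n_categories: int = 30
    max_level: int = 200          # largest propensity level in the pool
    max_repeat: int = 5           # multiplicity of level 0 in the pool
    chance_range: int = 10_000    # spike lottery draws r in 1..chance_range
    period_timeslots: int = 8     # timeslots per 40 Hz gamma period
    duty_timeslots: int = 4       # high-phase timeslots per period
    f_hi: float = 50.0            # modulation factor, high phase
    f_lo: float = 5.0             # modulation factor, low phase
    triple_periods: int = 75      # gamma periods per working-memory window
    single_periods: int = 25      # gamma periods per single-category window

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_categories < 1:
            raise ConfigError("n_inputs and n_categories must be positive")
        if self.max_level < 1 or self.max_repeat < 1:
            raise ConfigError("max_level and max_repeat must be >= 1")
        if self.duty_timeslots > self.period_timeslots:
            raise ConfigError("duty_timeslots cannot exceed period_timeslots")
        if self.f_hi < 0 or self.f_lo < 0:
            raise ConfigError("modulation factors must be non-negative")
        if self.triple_periods % 3 != 0:
            raise ConfigError("triple_periods must be divisible by 3")

    @property
    def triple_timeslots(self) -> int:
        return self.triple_periods * self.period_timeslots

    @property
    def single_timeslots(self) -> int:
        return self.single_periods * self.period_timeslots


@dataclass(frozen=True)
class CortexParams:
    """Columnar cortex topology, thresholds and plasticity constants.

    Each column holds ``l1_neurons`` layer-1, ``l2_neurons`` layer-2 neurons
    and a single layer-3 neuron.  A neuron integrates per branch (weighted
    sum of afferent spikes, fires if >= theta_branch) and then across
    branches (fires if the number of firing branches >= theta_neuron).
    Plasticity constants are applied once per 200 ms window; see
    cortex.end_window_plasticity.
    """

    n_columns: int = 15
    l1_neurons: int = 10
    l1_branches: int = 10
    l1_branch_synapses: int = 120
    l2_neurons: int = 10
    l2_branches: int = 2
    l2_branch_synapses: int = 5
    l3_branches: int = 2
    l3_branch_synapses: int = 5
    p_bias: float = 0.6           # per-synapse probability of a bias-group source
    w_init: Triple = (1.0, 1.0, 1.0)
    w_max: Triple = (4.0, 3.0, 3.0)
    theta_branch: Triple = (75.0, 3.0, 3.0)
    theta_neuron: ITriple = (2, 2, 2)
    pair_min: int = 3             # pairings per window needed to keep a potentiation
    delta_pot: Triple = (0.10, 0.10, 0.10)
    delta_dep: Triple = (0.04, 0.05, 0.05)
    miss_min: ITriple = (6, 6, 6)
    rho_max: ITriple = (60, 60, 60)  # per-layer window fire count triggering homeostasis
    s_homeo: float = 0.9          # proportional weight reduction factor
    l3_gate_min_l2: int = 0       # forward L3 output only if column L2 fired this often (0 = off)
    l3_gate_min_count: int = 0    # forward a segment's L3 count only if it reaches this (0 = off)
    output_latency: int = 2       # timeslots between input and layer-3 response

    def __post_init__(self):
        if self.n_columns < 1:
            raise ConfigError("n_columns must be >= 1")
        if not 0.0 <= self.p_bias <= 1.0:
            raise ConfigError("p_bias must lie in [0, 1]")
        if self.pair_min < 1:
            raise ConfigError("pair_min must be >= 1")
        if not 0.0 < self.s_homeo <= 1.0:
            raise ConfigError("s_homeo must lie in (0, 1]")
        for name in ("w_init", "w_max", "delta_pot", "delta_dep"):
            if any(v < 0 for v in getattr(self, name)):
                raise ConfigError(f"{name} entries must be non-negative")

    @property
    def neurons_per_column(self) -> int:
        return self.l1_neurons + self.l2_neurons + 1


@dataclass(frozen=True)
class ReadoutParams:
    """Basal-ganglia recommendation-weight learning constants."""

    w0: float = 1.0               # shared initial recommendation weight
    alpha_up: float = 1.0         # teacher potentiation per layer-3 spike
    delta_down: float = 0.006     # wrong-choice punishment proportion (teacher)
    delta_down_feedback: float = 0.42  # punishment proportion, correct/incorrect mode
    correct_boost: float = 0.0    # optional boost on correct-only feedback (off)

    def __post_init__(self):
        if self.w0 <= 0:
            raise ConfigError("w0 must be positive")
        for name in ("delta_down", "delta_down_feedback"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one simulation run.

    Phase sizes are counted in category *instances*; a 200 ms working-memory
    window carries three instances, so e.g. 1,200 instances = 400 windows.
    """

    experiment: str = "one"       # "one" (novelty) or "two" (split training)
    seed: int = 0
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    cortex: CortexParams = field(default_factory=CortexParams)
    readout: ReadoutParams = field(default_factory=ReadoutParams)
    hippocampus_sample: int = 30  # presentations used to derive the wiring bias
    # experiment one phase sizes (instances)
    n_cortex_only: int = 300
    n_teacher: int = 600
    n_test: int = 300
    # experiment two phase sizes (instances)
    n_warmup: int = 300
    n_teacher_per_set: int = 300  # 20 teacher instances per category, per set
    n_feedback_per_category: int = 10
    n_relearn_per_category: int = 1
    feedback_pass: bool = True
    relearn: bool = True

    def __post_init__(self):
        if self.experiment not in ("one", "two"):
            raise ConfigError("experiment must be 'one' or 'two'")
        for name in ("n_cortex_only", "n_teacher", "n_test", "n_warmup",
                     "n_teacher_per_set"):
            v = getattr(self, name)
            if v < 0 or v % 3 != 0:
                raise ConfigError(f"{name} must be a non-negative multiple of 3 "
                                  "(three instances per window)")
        if self.n_test <= 0:
            raise ConfigError("n_test must be positive")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        try:
            for key, sub in (("stimulus", StimulusParams),
                             ("cortex", CortexParams),
                             ("readout", ReadoutParams)):
                if key in d and isinstance(d[key], dict):
                    sub_d = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in d[key].items()
                    }
                    d[key] = sub(**sub_d)
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]
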