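"""Never-identical categorical stimulus generation.

Each of the 30 categories is a fixed *propensity profile*: 400 integer levels
in [0, 200] drawn from a pool in which small levels are over-represented
(multiplicity decays linearly from 5 at level 0 to 1 at level 200), so
spiking is made deliberately sparse.  A stimulus instance is a binary spike
matrix: at every timeslot, afferent ``i`` spikes iff

    propensity[i] * modulation(t)  >  r,    r ~ Uniform{1, ..., 10000},

so no two instances of a category are ever identical.  A 40 Hz gamma
envelope (8 timeslots per period, high factor for the first half of each
period) modulates the product; in working-memory mode three categories are
interleaved period-by-period, 25 periods each, across a 600-timeslot
(200 ms) window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ExperimentConfig, StimulusParams
from .errors import ConfigError

__all__ = [
    "LevelPool", "CategoryProfile", "ModulationEnvelope", "Presentation",
    "PresentationSpec", "Curriculum",
    "make_level_pool", "make_category_profile", "spike_probability",
    "spike_draw", "make_envelope", "render_presentation", "make_profiles",
    "build_curriculum", "export_curriculum",
]

PHASES = ("cortex_only", "teacher", "feedback_only", "test")


@dataclass(frozen=True)
class LevelPool:
    """Multiset of propensity levels from which profile components are drawn."""

    levels: np.ndarray            # expanded multiset, sorted ascending

    @property
    def multiplicities(self) -> np.ndarray:
        """Per-level repeat count, index = level."""
        counts = np.bincount(self.levels, minlength=int(self.levels.max()) + 1)
        return counts

    def mean(self) -> float:
        return float(self.levels.mean())


@dataclass(frozen=True)
class CategoryProfile:
    category_id: int
    propensity: np.ndarray        # (n_inputs,) int levels

    def __post_init__(self):
        object.__setattr__(self, "propensity",
                           np.ascontiguousarray(self.propensity, dtype=np.int64))


@dataclass(frozen=True)
class ModulationEnvelope:
    factor: np.ndarray            # (n_timeslots,) non-negative multipliers
    period_timeslots: int
    n_periods: int


@dataclass(frozen=True)
class Presentation:
    """One rendered 200 ms stimulus window."""

    spikes: np.ndarray            # (n_timeslots, n_inputs) uint8 in {0,1}
    labels: Tuple[int, ...]       # 1 (single) or 3 (working-memory) category ids
    segments: np.ndarray          # (n_timeslots,) index into labels
    seed_record: Tuple[int, ...] = ()

    @property
    def n_timeslots(self) -> int:
        return self.spikes.shape[0]


@dataclass(frozen=True)
class PresentationSpec:
    """Curriculum entry: which categories a window shows and in which phase."""

    labels: Tuple[int, ...]
    phase: str


@dataclass(frozen=True)
class Curriculum:
    entries: Tuple[PresentationSpec, ...]

    def phase_slice(self, phase: str) -> List[PresentationSpec]:
        return [e for e in self.entries if e.phase == phase]

    def label_counts(self) -> dict:
        counts: dict = {}
        for e in self.entries:
            for lab in e.labels:
                counts[lab] = counts.get(lab, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# construction

def make_level_pool(max_level: int, max_repeat: int) -> LevelPool:
    """Build the decaying-multiplicity level pool.

    Multiplicity interpolates linearly from ``max_repeat`` at level 0 down to
    1 at ``max_level``, rounded to the nearest integer, so drawing uniformly
    from the pool favours small propensities.
    """
    if max_level < 1 or max_repeat < 1:
        raise ConfigError("max_level and max_repeat must be >= 1")
    levels = np.arange(max_level + 1)
    mult = np.rint(max_repeat + (1 - max_repeat) * levels / max_level).astype(int)
    mult = np.maximum(mult, 1)
    return LevelPool(levels=np.repeat(levels, mult))


def make_category_profile(pool: LevelPool, rng: np.random.Generator,
                          category_id: int = 0,
                          n_inputs: int = 400) -> CategoryProfile:
    """Draw a fresh propensity profile: i.i.d. uniform picks from the pool."""
    prop = rng.choice(pool.levels, size=n_inputs, replace=True)
    return CategoryProfile(category_id=category_id, propensity=prop)


def make_profiles(params: StimulusParams,
                  rng: np.random.Generator) -> List[CategoryProfile]:
    """One fixed profile per category for the lifetime of a model run."""
    pool = make_level_pool(params.max_level, params.max_repeat)
    return [make_category_profile(pool, rng, category_id=c,
                                  n_inputs=params.n_inputs)
            for c in range(params.n_categories)]


def spike_probability(product: float, chance_range: int = 10_000) -> float:
    """Exact spike probability of the chance lottery for a given product.

    P(product > r), r uniform on {1..chance_range} =
    clamp(ceil(product) - 1, 0, chance_range) / chance_range.
    """
    if product < 0:
        raise ValueError("product must be non-negative")
    wins = min(max(math.ceil(product) - 1, 0), chance_range)
    return wins / chance_range


def spike_draw(product: float, rng: np.random.Generator,
               chance_range: int = 10_000) -> int:
    """One chance-lottery draw: spike iff product exceeds a uniform integer."""
    if product < 0:
        raise ValueError("product must be non-negative")
    r = int(rng.integers(1, chance_range + 1))
    return int(product > r)


def make_envelope(params: StimulusParams, n_periods: int) -> ModulationEnvelope:
    """Gamma duty-cycle envelope: f_hi for the first half of each period."""
    period = np.full(params.period_timeslots, params.f_lo)
    period[:params.duty_timeslots] = params.f_hi
    return ModulationEnvelope(factor=np.tile(period, n_periods),
                              period_timeslots=params.period_timeslots,
                              n_periods=n_periods)


def render_presentation(profiles: Sequence[CategoryProfile],
                        envelope: ModulationEnvelope,
                        rng: np.random.Generator,
                        params: Optional[StimulusParams] = None) -> Presentation:
    """Render one stimulus window from 1 (single) or 3 (triple) profiles.

    In triple mode the three categories occupy gamma periods round-robin
    (A, B, C, A, B, C, ...), one third of the periods each; at every timeslot
    all afferents are driven by the profile of the currently active category.
    """
    params = params or StimulusParams()
    n_prof = len(profiles)
    if n_prof not in (1, 3):
        raise ConfigError("render_presentation takes exactly 1 or 3 profiles")
    n_slots = envelope.factor.shape[0]
    if n_slots != envelope.period_timeslots * envelope.n_periods:
        raise ConfigError("envelope factor length inconsistent with periods")
    if n_prof == 3 and envelope.n_periods % 3 != 0:
        raise ConfigError("triple mode needs a period count divisible by 3")

    period_idx = np.arange(n_slots) // envelope.period_timeslots
    segments = (period_idx % n_prof).astype(np.int64)
    prop = np.stack([p.propensity for p in profiles])          # (n_prof, n_in)
    active = prop[segments]                                    # (T, n_in)
    products = active * envelope.factor[:, None]
    r = rng.integers(1, params.chance_range + 1, size=products.shape)
    spikes = (products > r).astype(np.uint8)
    return Presentation(spikes=spikes,
                        labels=tuple(p.category_id for p in profiles),
                        segments=segments)


# ---------------------------------------------------------------------------
# curricula

def _windows(categories: Sequence[int], n_instances: int,
             phase: str) -> List[PresentationSpec]:
    """Chunk a fixed repeating category order into triple windows.

    The order never changes: the category list is tiled as often as needed
    and consecutive non-overlapping triples become windows.
    """
    if n_instances % 3 != 0:
        raise ConfigError("instance counts must be multiples of 3")
    reps = -(-n_instances // len(categories))
    stream = np.tile(np.asarray(categories), reps)[:n_instances]
    return [PresentationSpec(labels=tuple(int(c) for c in stream[i:i + 3]),
                             phase=phase)
            for i in range(0, n_instances, 3)]


def build_curriculum(config: ExperimentConfig,
                     rng: Optional[np.random.Generator] = None) -> Curriculum:
    """Lay out the presentation order and phase tags for an experiment.

    Experiment one: cortex-only warm-up, teacher training, then a no-feedback
    test, over all categories in a fixed repeating order.  Experiment two:
    warm-up, teacher training on the first half of the categories, teacher
    training on the second half, a full test, an optional correct/incorrect
    recovery pass, a retest, an optional one-instance-per-category teacher
    relearn pass, and a final retest.
    """
    n_cat = config.stimulus.n_categories
    cats = list(range(n_cat))
    entries: List[PresentationSpec] = []
    if config.experiment == "one":
        entries += _windows(cats, config.n_cortex_only, "cortex_only")
        entries += _windows(cats, config.n_teacher, "teacher")
        entries += _windows(cats, config.n_test, "test")
    else:
        half = n_cat // 2
        set_a, set_b = cats[:half], cats[half:]
        entries += _windows(cats, config.n_warmup, "cortex_only")
        entries += _windows(set_a, config.n_teacher_per_set, "teacher")
        entries += _windows(set_b, config.n_teacher_per_set, "teacher")
        entries += _windows(cats, config.n_test, "test")
        if config.feedback_pass:
            n_fb = config.n_feedback_per_category * n_cat
            entries += _windows(cats, n_fb, "feedback_only")
            entries += _windows(cats, config.n_test, "test")
        if config.relearn:
            n_rl = config.n_relearn_per_category * n_cat
            entries += _windows(cats, n_rl, "teacher")
            entries += _windows(cats, config.n_test, "test")
    return Curriculum(entries=tuple(entries))


def export_curriculum(curriculum: Curriculum,
                      profiles: Sequence[CategoryProfile],
                      params: StimulusParams,
                      seed: int,
                      out_dir: str | Path,
                      n_render: Optional[int] = None) -> Path:
    """Render and export a curriculum to disk.

    Writes one ``presentations.npz`` (spike matrices, labels, segments), a
    ``profiles.csv`` table of the propensity profiles and a JSON manifest
    with the seed and layout.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_render = len(curriculum.entries) if n_render is None else n_render
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_render)
    arrays = {}
    labels = []
    for i, spec in enumerate(curriculum.entries[:n_render]):
        n_per = params.triple_periods if len(spec.labels) == 3 else params.single_periods
        env = make_envelope(params, n_per)
        pres = render_presentation([profiles[c] for c in spec.labels], env,
                                   np.random.default_rng(child[i]), params)
        arrays[f"spikes_{i:05d}"] = pres.spikes
        arrays[f"segments_{i:05d}"] = pres.segments
        labels.append(list(spec.labels))
    np.savez_compressed(out / "presentations.npz", **arrays)

    import pandas as pd
    prof_df = pd.DataFrame(
        {f"cat_{p.category_id}": p.propensity for p in profiles})
    prof_df.to_csv(out / "profiles.csv", index_label="component")
    manifest = {
        "seed": seed,
        "n_presentations": n_render,
        "labels": labels,
        "phases": [s.phase for s in curriculum.entries[:n_render]],
        "stimulus_params": {k: getattr(params, k)
                            for k in params.__dataclass_fields__},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
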