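"""Co-activation grouping of afferent inputs ("dream sleep" wiring bias).

The only hippocampal role simulated is the derivation, from an unprocessed
sample of stimuli, of per-column groups of inputs that tend to spike in the
same timeslots.  The groups bias the initial layer-1 wiring of each cortical
column; they are computed once before learning and never updated.

Grouping is a greedy size-capped average-linkage agglomeration on the
cosine-normalised co-occurrence matrix: merge the pair of groups with the
highest average similarity whose combined size stays below a balance cap,
until exactly ``n_columns`` groups remain.  Ties resolve to the lowest pair
index, so the procedure is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .stimgen import Presentation

__all__ = ["CoactivationGroups", "derive_coactivation_groups", "export_groups"]


@dataclass(frozen=True)
class CoactivationGroups:
    groups: Tuple[Tuple[int, ...], ...]   # n_columns groups of input indices
    cooccurrence: np.ndarray              # (n_inputs, n_inputs) symmetric counts

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _cosine_similarity(cooc: np.ndarray) -> np.ndarray:
    diag = np.sqrt(np.diag(cooc).astype(float))
    denom = np.outer(diag, diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, cooc / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sim, 0.0)
    return sim


def derive_coactivation_groups(sample: Sequence[Presentation],
                               n_columns: int,
                               rng: Optional[np.random.Generator] = None,
                               balance: float = 1.5) -> CoactivationGroups:
    """Cluster inputs by pooled same-timeslot co-spiking into n_columns groups.

    ``cooccurrence[i, j]`` counts timeslots, pooled over the sample, in which
    inputs i and j both spiked.  ``rng`` is accepted for interface symmetry;
    the procedure itself is deterministic.  Inputs that never co-spike with
    anything are appended to the smallest group at the end.
    """
    if len(sample) == 0:
        raise ConfigError("sample must contain at least one presentation")
    if n_columns < 1:
        raise ConfigError("n_columns must be >= 1")

    n_inputs = sample[0].spikes.shape[1]
    cooc = np.zeros((n_inputs, n_inputs), dtype=np.int64)
    for pres in sample:
        x = pres.spikes.astype(np.int64)
        cooc += x.T @ x
    sim = _cosine_similarity(cooc)

    off_diag = cooc - np.diag(np.diag(cooc))
    dead = np.where(off_diag.sum(axis=1) == 0)[0]
    alive = [i for i in range(n_inputs) if i not in set(dead.tolist())]
    if len(alive) < n_columns:
        raise ConfigError("fewer co-active inputs than requested groups")

    cap = math.ceil(balance * n_inputs / n_columns)

    # Greedy average-linkage with a size cap.  A (G, G) matrix of average
    # inter-group similarities is maintained and updated on each merge.
    members: List[List[int]] = [[i] for i in alive]
    sizes = np.ones(len(alive))
    avg = sim[np.ix_(alive, alive)].astype(float)
    np.fill_diagonal(avg, -np.inf)

    while len(members) > n_columns:
        g = len(members)
        allowed = (sizes[:, None] + sizes[None, :]) <= cap
        np.fill_diagonal(allowed, False)
        cand = np.where(allowed, avg, -np.inf)
        if not np.isfinite(cand).any():
            # cap blocks every merge: fall back to joining the two smallest
            order = np.argsort(sizes, kind="stable")
            i, j = sorted((int(order[0]), int(order[1])))
        else:
            flat = int(np.argmax(cand))        # lowest index wins ties
            i, j = divmod(flat, g)
            i, j = min(i, j), max(i, j)
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * avg[i] + nj * avg[j]) / (ni + nj)
        avg[i] = new_row
        avg[:, i] = new_row
        avg[i, i] = -np.inf
        members[i] = members[i] + members[j]
        sizes[i] = ni + nj
        keep = [k for k in range(g) if k != j]
        members = [members[k] for k in keep]
        sizes = sizes[keep]
        avg = avg[np.ix_(keep, keep)]

    groups = [sorted(m) for m in members]
    for d in dead.tolist():                    # degenerate inputs: smallest group
        smallest = min(range(len(groups)), key=lambda k: (len(groups[k]), k))
        groups[smallest] = sorted(groups[smallest] + [int(d)])
    return CoactivationGroups(
        groups=tuple(tuple(g) for g in groups),
        cooccurrence=cooc,
    )


def export_groups(groups: CoactivationGroups, out_dir: str | Path) -> None:
    """Write group membership and the co-occurrence matrix as CSV."""
    import pandas as pd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [(g, i) for g, grp in enumerate(groups.groups) for i in grp]
    pd.DataFrame(rows, columns=["group", "input"]).to_csv(
        out / "groups.csv", index=False)
    pd.DataFrame(groups.cooccurrence).to_csv(out / "cooccurrence.csv",
                                             index=False)
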