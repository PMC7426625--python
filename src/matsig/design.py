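"""Combinatorial layout of the rating study.

The study rates segments of 15 material classes, cut from paintings, on 10
perceptual attributes with a 0-100 slider.  The 450 stimuli (30 segments per
material) are split into 5 balanced sets of 90; every set x attribute cell is
rated by 10 independent raters, each seeing 3 shuffled repetitions of the set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Canonical material labels, order-stable; used as row order of signature tables.
MATERIALS = [
    "animal", "ceramic", "fabric", "flora", "food",
    "gem", "glass", "ground", "liquid", "metal",
    "paper", "skin", "sky", "stone", "wood",
]

#: Canonical perceptual attribute labels, order-stable; used as column order.
ATTRIBUTES = [
    "bendable", "cold", "fragile", "glossy", "hairy",
    "hard", "multicolored", "rough", "transparent/translucent", "vivid",
]


@dataclass(frozen=True)
class StudyDesign:
    """The experiment's combinatorial layout.

    Parameters
    ----------
    materials, attributes
        Ordered label lists (lowercase).
    segments_per_material
        Number of stimuli per material class; must be divisible by ``n_sets``.
    n_sets
        Number of balanced stimulus sets; each rater task covers one set.
    raters_per_cell
        Independent raters per set x attribute cell.
    repetitions
        Shuffled repetitions of the set within a task.
    slider_min, slider_max
        Bounds of the rating slider.
    """

    materials: tuple[str, ...] = tuple(MATERIALS)
    attributes: tuple[str, ...] = tuple(ATTRIBUTES)
    segments_per_material: int = 30
    n_sets: int = 5
    raters_per_cell: int = 10
    repetitions: int = 3
    slider_min: float = 0.0
    slider_max: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "materials", tuple(m.lower() for m in self.materials))
        object.__setattr__(self, "attributes", tuple(a.lower() for a in self.attributes))
        if len(set(self.materials)) != len(self.materials):
            raise ValueError("duplicate material labels")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("duplicate attribute labels")
        if self.segments_per_material % self.n_sets:
            raise ValueError(
                f"segments_per_material ({self.segments_per_material}) must be "
                f"divisible by n_sets ({self.n_sets})"
            )
        if not self.slider_min < self.slider_max:
            raise ValueError("slider_min must be < slider_max")
        for name in ("segments_per_material", "n_sets", "raters_per_cell", "repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- derived sizes -------------------------------------------------

    @property
    def n_materials(self) -> int:
        return len(self.materials)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def n_stimuli(self) -> int:
        return self.n_materials * self.segments_per_material

    @property
    def set_size(self) -> int:
        """Stimuli per set (materials x segments_per_material / n_sets)."""
        return self.n_stimuli // self.n_sets

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        d["materials"] = list(d["materials"])
        d["attributes"] = list(d["attributes"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyDesign":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class DesignCounts:
    """Summary of the design arithmetic."""

    n_stimuli: int
    n_cells: int           # set x attribute combinations
    trials_per_task: int   # set size x repetitions
    total_tasks: int       # n_cells x raters_per_cell
    total_judgments: int   # total_tasks x trials_per_task


def default_design(**overrides) -> StudyDesign:
    """The study's design: 15 materials x 30 segments in 5 sets of 90,
    10 attributes, 10 raters per set/attribute cell, 3 repetitions, 0-100 slider.

    Keyword overrides replace individual fields (e.g. ``n_sets=1`` yields the
    unpartitioned 1350-trial task).
    """
    return StudyDesign(**overrides)


def design_counts(design: StudyDesign) -> DesignCounts:
    """Derive all trial/judgment counts from a design.

    For the default design: 450 stimuli, 50 cells, 270 trials per task,
    500 tasks, 135,000 judgments.
    """
    n_cells = design.n_sets * design.n_attributes
    trials_per_task = design.set_size * design.repetitions
    total_tasks = n_cells * design.raters_per_cell
    return DesignCounts(
        n_stimuli=design.n_stimuli,
        n_cells=n_cells,
        trials_per_task=trials_per_task,
        total_tasks=total_tasks,
        total_judgments=total_tasks * trials_per_task,
    )


def mean_tasks_per_participant(n_tasks: int, n_participants: int) -> float:
    """Average number of tasks completed per participant (e.g. 500/198 ~ 2.5)."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    return n_tasks / n_participants


def stimulus_ids(design: StudyDesign) -> list[str]:
    """Stable stimulus identifiers, ``<material>_<k>`` with k zero-padded."""
    width = len(str(design.segments_per_material))
    return [
        f"{m}_{k:0{width}d}"
        for m in design.materials
        for k in range(1, design.segments_per_material + 1)
    ]


def partition_sets(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Randomly assign stimuli to sets, stratified by material.

    Every set receives exactly ``segments_per_material / n_sets`` stimuli of
    each material.  Deterministic given ``seed``.

    Returns
    -------
    DataFrame with columns ``stimulus_id, material, set_id`` (set_id in 1..n_sets).
    """
    if design.segments_per_material % design.n_sets:
        raise ValueError("segments_per_material not divisible by n_sets")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5]))
    per_set = design.segments_per_material // design.n_sets
    rows = []
    for m in design.materials:
        sets = np.repeat(np.arange(1, design.n_sets + 1), per_set)
        rng.shuffle(sets)
        width = len(str(design.segments_per_material))
        for k, s in enumerate(sets, start=1):
            rows.append((f"{m}_{k:0{width}d}", m, int(s)))
    return pd.DataFrame(rows, columns=["stimulus_id", "material", "set_id"])
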