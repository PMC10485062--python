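"""Category assignment and grouped cross-validation planning.

Stations are grouped into nine categories along four axes: landscape
(Wetland / Cropland / Grassland / Forest, collapsed from IGBP land-cover
classes), continent (Asia / Europe), aridity (arid iff aridity index < 0.65)
and an Overall category holding every station. Each station therefore
belongs to exactly four categories.

Cross-validation is grouped at the station level: whole stations, never
individual days, are dealt into k folds, repeated over p independent
shuffles ("splits"). With n stations per category this yields k x p models
and n x p per-station test evaluations per (category, scenario, target).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import CATEGORIES, SCENARIOS, TARGETS
from .synthetic import StationMeta

#: IGBP land-cover classes collapsed to the four landscape groups.
IGBP_TO_LANDSCAPE = {
    "permanent wetlands": "Wetland",
    "croplands": "Cropland",
    "cropland/natural vegetation mosaics": "Cropland",
    "grasslands": "Grassland",
    "savannas": "Grassland",
    "woody savannas": "Grassland",
    "evergreen needleleaf forests": "Forest",
    "evergreen broadleaf forests": "Forest",
    "deciduous needleleaf forests": "Forest",
    "deciduous broadleaf forests": "Forest",
    "mixed forests": "Forest",
}

ARID_THRESHOLD = 0.65


def landscape_from_igbp(igbp_class: str) -> str:
    """Map an IGBP land-cover class name to its landscape group."""
    key = igbp_class.strip().lower()
    if key not in IGBP_TO_LANDSCAPE:
        raise KeyError(f"unknown IGBP class: {igbp_class!r}")
    return IGBP_TO_LANDSCAPE[key]


def aridity_class(aridity_index: float) -> str:
    """Arid iff AI < 0.65; AI exactly 0.65 is non-arid."""
    return "Arid" if aridity_index < ARID_THRESHOLD else "NonArid"


def assign_categories(meta: StationMeta) -> set[str]:
    """The four categories a station belongs to."""
    if meta.landscape not in ("Wetland", "Cropland", "Grassland", "Forest"):
        # tolerate raw IGBP labels in metadata
        landscape = landscape_from_igbp(meta.landscape)
    else:
        landscape = meta.landscape
    return {landscape, meta.continent, aridity_class(meta.aridity_index), "Overall"}


@dataclass(frozen=True)
class CategoryPartition:
    """Member stations of one category."""

    category: str
    station_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.station_ids)


def build_partitions(metas: list[StationMeta], role: str = "flux") -> list[CategoryPartition]:
    """Nine category partitions over the stations of one role, in canonical
    category order. Categories with no members are returned empty."""
    members: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for m in metas:
        if m.role != role:
            continue
        for c in assign_categories(m):
            members[c].append(m.station_id)
    return [CategoryPartition(c, tuple(members[c])) for c in CATEGORIES]


@dataclass(frozen=True)
class CVPlan:
    """Grouped k-fold plan for one category, repeated over p splits.

    ``assignment[s]`` maps station_id -> fold index (0..k-1) for split s.
    """

    category: str
    k: int
    p: int
    assignment: tuple[dict[str, int], ...]

    @property
    def n(self) -> int:
        return len(self.assignment[0])

    def test_stations(self, split: int, fold: int) -> tuple[str, ...]:
        return tuple(s for s, f in self.assignment[split].items() if f == fold)

    def train_stations(self, split: int, fold: int) -> tuple[str, ...]:
        return tuple(s for s, f in self.assignment[split].items() if f != fold)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": self.category, "split": s + 1, "fold": f + 1, "station_id": sid}
            for s, amap in enumerate(self.assignment)
            for sid, f in sorted(amap.items())
        ]
        return pd.DataFrame(rows)


def make_cv_plan(station_ids, k: int, p: int, seed: int = 0) -> CVPlan:
    """Shuffle stations into k near-equal folds, independently p times.

    Fold sizes differ by at most one (sizes floor(n/k) or ceil(n/k)); the
    nominal fold size n/k is exact only when k divides n. Whole stations are
    assigned, so all of a station's days share its fold.
    """
    ids = list(station_ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} stations, got {n}")
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    assignment = []
    for _ in range(p):
        order = np.array(ids, dtype=object)
        rng.shuffle(order)
        folds = np.array_split(order, k)
        amap = {str(sid): f for f, chunk in enumerate(folds) for sid in chunk}
        assignment.append(amap)
    return CVPlan(category="", k=k, p=p, assignment=tuple(assignment))


def make_category_plans(
    partitions: list[CategoryPartition], k: int, p: int, seed: int = 0
) -> dict[str, CVPlan]:
    """One independently shuffled CV plan per non-empty category.

    Per-category seeds are derived from ``seed`` so plans are reproducible
    and categories are shuffled independently of one another.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(partitions))
    plans: dict[str, CVPlan] = {}
    for part, child in zip(partitions, children):
        if part.n == 0:
            continue
        sub_seed = int(np.random.default_rng(child).integers(2**31))
        plan = make_cv_plan(part.station_ids, k=k, p=p, seed=sub_seed)
        plans[part.category] = CVPlan(part.category, plan.k, plan.p, plan.assignment)
    return plans


@dataclass(frozen=True)
class TrainingTask:
    """One model-training unit: a (category, split, fold, scenario, target)."""

    category: str
    split: int
    fold: int
    scenario: str
    target: str


def enumerate_training_plan(
    partitions: list[CategoryPartition],
    scenarios=SCENARIOS,
    targets=TARGETS,
    k: int = 10,
    p: int = 10,
) -> list[TrainingTask]:
    """All training tasks over the categories: |tasks| = n_cat * p * k *
    |scenarios| * |targets| (900 per scenario-target and 3,600 total for the
    canonical nine categories with k = p = 10 and two scenarios x two
    targets)."""
    tasks = []
    for part in partitions:
        for scenario in scenarios:
            for target in targets:
                for split in range(p):
                    for fold in range(k):
                        tasks.append(
                            TrainingTask(part.category, split, fold, scenario, target)
                        )
    return tasks


def write_cv_plans(plans: dict[str, CVPlan], path: str | Path) -> None:
    """Serialize plans as CSV (category, split, fold, station_id)."""
    frames = [plans[c].to_frame() for c in CATEGORIES if c in plans]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
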