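"""Activity classes, project stages, and alpha/beta/gamma regions.

Region semantics:

* ``alpha`` — early-stage compounds at middle activity or better; the
  fine-tuning (focus) pool.
* ``beta`` — middle/late-stage compounds with low or middle activity.
* ``gamma`` — middle/late-stage compounds with high or ultra-high activity;
  the rediscovery reference.
* ``none`` — early-stage, low-activity compounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord
from .pseudotime import PseudoTimeMap

ACTIVITY_CLASSES = ("low", "middle", "high", "ultra_high")
STAGES = ("early", "middle", "late")
REGIONS = ("alpha", "beta", "gamma", "none")


@dataclass(frozen=True)
class ActivityThresholds:
    """pXC50 cut points between the four activity classes.

    Binning is half-open: low = (-inf, t_low_mid), middle =
    [t_low_mid, t_mid_high), high = [t_mid_high, t_high_ultra),
    ultra_high = [t_high_ultra, inf) — a boundary value lands in the class
    above it.
    """

    t_low_mid: float = 6.0
    t_mid_high: float = 7.0
    t_high_ultra: float = 8.0

    def __post_init__(self) -> None:
        if not (self.t_low_mid < self.t_mid_high < self.t_high_ultra):
            raise ValueError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class StageConfig:
    """How to cut a project into early / middle / late stages.

    ``pseudo_time`` mode cuts at cumulative fractions of the pseudo-time
    ordering (default 50/25/25). ``dated`` mode cuts the date-sorted record
    list after given compound counts (e.g. ``(500, 1000)``) or at date
    boundaries.
    """

    mode: str = "pseudo_time"
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    cutpoints: tuple = ()

    def __post_init__(self) -> None:
        if self.mode not in ("pseudo_time", "dated"):
            raise ValueError(f"unknown stage mode {self.mode!r}")
        if self.mode == "pseudo_time":
            if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
                raise ValueError("stage fractions must sum to 1")
        else:
            if len(self.cutpoints) != 2:
                raise ValueError("dated mode needs exactly 2 cutpoints")
            if not self.cutpoints[0] < self.cutpoints[1]:
                raise ValueError("cutpoints must be strictly increasing")


@dataclass
class LabelledDataset:
    """Records plus aligned stage / activity-class / region labels."""

    records: list[MoleculeRecord]
    stage: list[str]
    activity_class: list[str]
    region: list[str]
    thresholds: ActivityThresholds = field(default_factory=ActivityThresholds)
    stage_config: StageConfig = field(default_factory=StageConfig)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask: Sequence[bool]) -> list[MoleculeRecord]:
        return [r for r, m in zip(self.records, mask) if m]

    def region_records(self, region: str) -> list[MoleculeRecord]:
        return [r for r, g in zip(self.records, self.region) if g == region]

    def region_smiles(self, region: str) -> list[str]:
        return [r.smiles_canonical for r in self.region_records(region)]

    def stage_class_records(
        self, stage: str, activity_class: str
    ) -> list[MoleculeRecord]:
        return [
            r
            for r, s, c in zip(self.records, self.stage, self.activity_class)
            if s == stage and c == activity_class
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles_canonical": [r.smiles_canonical for r in self.records],
                "pxc50": [r.pxc50 for r in self.records],
                "date": [r.date for r in self.records],
                "source_row": [r.source_row for r in self.records],
                "stage": self.stage,
                "activity_class": self.activity_class,
                "region": self.region,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def assign_activity_class(
    pxc50: float, thresholds: ActivityThresholds
) -> str:
    """Half-open binning of a potency value into the four classes."""
    if pxc50 is None or not np.isfinite(pxc50):
        raise ValueError(f"pXC50 must be finite, got {pxc50!r}")
    if pxc50 < thresholds.t_low_mid:
        return "low"
    if pxc50 < thresholds.t_mid_high:
        return "middle"
    if pxc50 < thresholds.t_high_ultra:
        return "high"
    return "ultra_high"


def stage_sizes(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    """Floor-based cumulative stage sizes for n records.

    early = floor(f1*n), middle = floor((f1+f2)*n) - floor(f1*n), late =
    the remainder — so counts always sum to n and are reproducible.
    """
    c1 = math.floor(fractions[0] * n)
    c2 = math.floor((fractions[0] + fractions[1]) * n)
    return c1, c2 - c1, n - c2


def assign_stages(
    records: Sequence[MoleculeRecord],
    stage_config: StageConfig,
    pseudo_time_map: PseudoTimeMap | None = None,
) -> list[str]:
    """Per-record stage labels in original record order."""
    n = len(records)
    if stage_config.mode == "pseudo_time":
        if pseudo_time_map is None:
            raise ValueError("pseudo_time mode requires a PseudoTimeMap")
        order = pseudo_time_map.order
        n_early, n_middle, _ = stage_sizes(n, stage_config.fractions)
        labels = [""] * n
        for rank, idx in enumerate(order):
            if rank < n_early:
                labels[idx] = "early"
            elif rank < n_early + n_middle:
                labels[idx] = "middle"
            else:
                labels[idx] = "late"
        return labels

    # dated mode
    dates = [r.date for r in records]
    if any(d is None for d in dates):
        missing = [r.id for r, d in zip(records, dates) if d is None][:5]
        raise ValueError(f"dated mode requires dates on all records: {missing}")
    order = sorted(range(n), key=lambda i: (dates[i], records[i].source_row))
    cp = stage_config.cutpoints
    if all(isinstance(c, (int, np.integer)) for c in cp):
        c1, c2 = int(cp[0]), int(cp[1])
        if not (0 < c1 < c2 < n):
            raise ValueError(
                f"count cutpoints {cp} outside data range (n={n})"
            )
    else:  # date boundaries
        sorted_dates = [dates[i] for i in order]
        if cp[0] < sorted_dates[0] or cp[1] > sorted_dates[-1]:
            raise ValueError(f"date cutpoints {cp} outside data range")
        c1 = sum(1 for d in sorted_dates if d <= cp[0])
        c2 = sum(1 for d in sorted_dates if d <= cp[1])
    labels = [""] * n
    for rank, idx in enumerate(order):
        if rank < c1:
            labels[idx] = "early"
        elif rank < c2:
            labels[idx] = "middle"
        else:
            labels[idx] = "late"
    return labels


def assign_regions(
    stage: Sequence[str], activity_class: Sequence[str]
) -> list[str]:
    """Map (stage, activity class) pairs to alpha/beta/gamma/none."""
    if len(stage) != len(activity_class):
        raise ValueError("stage and activity_class must be aligned")
    out = []
    for s, c in zip(stage, activity_class):
        if s == "early":
            out.append("alpha" if c != "low" else "none")
        else:
            out.append("beta" if c in ("low", "middle") else "gamma")
    return out


def label_dataset(
    records: Sequence[MoleculeRecord],
    thresholds: ActivityThresholds | None = None,
    stage_config: StageConfig | None = None,
    pseudo_time_map: PseudoTimeMap | None = None,
) -> LabelledDataset:
    """Assign activity classes, stages and regions in one pass."""
    thresholds = thresholds or ActivityThresholds()
    stage_config = stage_config or StageConfig()
    classes = [assign_activity_class(r.pxc50, thresholds) for r in records]
    stages = assign_stages(records, stage_config, pseudo_time_map)
    regions = assign_regions(stages, classes)
    return LabelledDataset(
        records=list(records),
        stage=stages,
        activity_class=classes,
        region=regions,
        thresholds=thresholds,
        stage_config=stage_config,
    )


def focus_set(
    dataset: LabelledDataset, rule: str = "above_mean_early"
) -> list[MoleculeRecord]:
    """Select the fine-tuning pool from the early stage.

    ``region_alpha`` takes all alpha records; ``above_mean_early`` takes
    early-stage records strictly above the early-stage mean pXC50.
    """
    if rule == "region_alpha":
        selected = dataset.region_records("alpha")
    elif rule == "above_mean_early":
        early = [
            r for r, s in zip(dataset.records, dataset.stage) if s == "early"
        ]
        if not early:
            raise ValueError("no early-stage records")
        mean = float(np.mean([r.pxc50 for r in early]))
        selected = [r for r in early if r.pxc50 > mean]
    else:
        raise ValueError(f"unknown focus rule {rule!r}")
    if not selected:
        raise ValueError(
            f"focus rule {rule!r} selected no compounds; review activity "
            "thresholds / stage configuration"
        )
    return selected


def region_asnn(
    dataset: LabelledDataset,
    region_a: str,
    region_b: str,
    **fp_config,
) -> float:
    """Directional aSNN from region_a records to region_b records."""
    from .metrics import asnn

    qa = dataset.region_smiles(region_a)
    qb = dataset.region_smiles(region_b)
    if not qa or not qb:
        raise ValueError(f"empty region in pair ({region_a}, {region_b})")
    return asnn(qa, qb, **fp_config)
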