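"""Land-use/land-cover accounting.

Per-class areas and composition, the single land-use dynamic degree K,
inter-epoch transition matrices (cross-tabulation), and Markov-chain
projection of class areas — the quantitative backbone behind the
business-as-usual scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CLASS_NAMES, GeometryError, LULCGrid


@dataclass
class AreaTable:
    """Per-class areas (hm²) for one epoch, with composition shares.

    ``total`` defaults to the sum of the listed areas; pass it explicitly
    when shares should be taken over a fixed basin total instead.
    """

    epoch: str
    areas: dict[int, float]
    total: float | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("areas must be non-negative")
        if self.total is None:
            self.total = float(sum(self.areas.values()))

    @property
    def classes(self) -> list[int]:
        return sorted(self.areas)

    def area(self, code: int) -> float:
        return self.areas.get(code, 0.0)

    def share(self, code: int) -> float:
        """Composition share in percent."""
        return 100.0 * self.areas.get(code, 0.0) / self.total

    def as_vector(self, classes: list[int] | None = None) -> np.ndarray:
        classes = classes or self.classes
        return np.array([self.areas.get(c, 0.0) for c in classes])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class_code": c,
                "class_name": CLASS_NAMES.get(c, str(c)),
                "area_hm2": self.areas[c],
                "share_pct": self.share(c),
            }
            for c in self.classes
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "epoch", self.epoch)
        return df


@dataclass
class TransitionMatrix:
    """Inter-epoch cross-tabulation of class areas (hm²)."""

    from_epoch: str
    to_epoch: str
    classes: list[int]
    areas: np.ndarray  # n×n, rows = from-class

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, float)
        n = len(self.classes)
        if self.areas.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.areas < -1e-9):
            raise ValueError("transition areas must be non-negative")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def row_areas(self) -> np.ndarray:
        return self.areas.sum(axis=1)

    def probabilities(self) -> np.ndarray:
        """Row-stochastic form; rows with zero area become identity rows."""
        rows = self.row_areas()
        P = np.where(rows[:, None] > 0, self.areas / np.where(rows == 0, 1, rows)[:, None], 0.0)
        for i, r in enumerate(rows):
            if r == 0:
                P[i, i] = 1.0
        return P

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.classes, columns=self.classes)


def class_areas(grid: LULCGrid, epoch: str | int,
                classes: list[int] | None = None) -> AreaTable:
    """Count cells per class and convert to hectares; nodata excluded."""
    mask = grid.valid_mask
    if not mask.any():
        raise ValueError("grid contains no data cells")
    vals = grid.values[mask]
    present = classes if classes is not None else sorted(np.unique(vals).tolist())
    areas = {
        int(c): float((vals == c).sum()) * grid.cell_area for c in present
    }
    return AreaTable(str(epoch), areas)


def dynamic_degree(area_start: float, area_end: float,
                   span_years: float) -> float:
    """Single land-use dynamic degree K, in percent per year.

    K = ((Ub − Ua) / Ua) · (1/T) · 100 — the annualized relative rate of
    change of one class's area over the period, reported to 2 decimals.
    """
    if area_start <= 0:
        raise ValueError("dynamic degree undefined for zero start area")
    if span_years <= 0:
        raise ValueError("span must be positive")
    k = (area_end - area_start) / area_start / span_years * 100.0
    return round(k, 2)


def transition_matrix(grid_a: LULCGrid, grid_b: LULCGrid,
                      from_epoch: str = "a", to_epoch: str = "b") -> TransitionMatrix:
    """Cross-tabulate aligned epochs into an area transition matrix."""
    grid_a.require_alignment(grid_b)
    mask = grid_a.valid_mask & grid_b.valid_mask
    va, vb = grid_a.values[mask], grid_b.values[mask]
    classes = sorted(set(np.unique(va).tolist()) | set(np.unique(vb).tolist()))
    index = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    counts = np.zeros((n, n))
    ia = np.vectorize(index.get)(va)
    ib = np.vectorize(index.get)(vb)
    np.add.at(counts, (ia, ib), 1.0)
    return TransitionMatrix(str(from_epoch), str(to_epoch), classes,
                            counts * grid_a.cell_area)


def markov_project(tm: TransitionMatrix, base: AreaTable,
                   n_steps: int = 1) -> AreaTable:
    """Project class areas forward: areas' = areasᵀ · Pⁿ.

    Total area is conserved because P is row-stochastic.
    """
    P = tm.probabilities()
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix is not row-stochastic")
    missing = [c for c in tm.classes if c not in base.areas]
    if missing:
        raise ValueError(f"base table lacks classes {missing}")
    v = base.as_vector(tm.classes)
    out = v @ np.linalg.matrix_power(P, n_steps)
    if abs(out.sum() - v.sum()) > 1e-6 * max(v.sum(), 1.0):
        raise AssertionError("projection failed to conserve total area")
    return AreaTable(
        f"{base.epoch}+{n_steps}",
        {c: float(a) for c, a in zip(tm.classes, out)},
    )


def sankey_export(tm: TransitionMatrix) -> pd.DataFrame:
    """Flatten the transition matrix into (source, target, area) links.

    Zero links are dropped; the result serializes the flow diagram of
    inter-class conversions.
    """
    rows = []
    for i, src in enumerate(tm.classes):
        for j, dst in enumerate(tm.classes):
            a = tm.areas[i, j]
            if a > 0:
                rows.append(
                    {
                        "source_class": src,
                        "source_name": CLASS_NAMES.get(src, str(src)),
                        "target_class": dst,
                        "target_name": CLASS_NAMES.get(dst, str(dst)),
                        "area_hm2": a,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["source_class", "source_name", "target_class",
                 "target_name", "area_hm2"],
    )


#: Printed per-class areas (hm²) of the study basin, usable as tabular
#: input anywhere an AreaTable is accepted.
STUDY_AREAS: dict[str, dict[int, float]] = {
    "1990": {1: 369_621, 2: 228_611, 3: 2_484_147, 4: 205_497,
             5: 16_232, 6: 1_729_175},
    "2000": {1: 409_343, 2: 242_211, 3: 2_435_748, 4: 225_707,
             5: 25_689, 6: 1_692_813},
    "2010": {1: 504_667, 2: 241_860, 3: 2_364_064, 4: 240_585,
             5: 29_468, 6: 1_653_245},
    "2020": {1: 725_534, 2: 113_439, 3: 2_579_527, 4: 166_058,
             5: 61_138, 6: 1_389_920},
}

STUDY_TOTAL_AREA = 5_035_616.0  # hm²


def study_area_table(epoch: str, fixed_total: bool = True) -> AreaTable:
    """AreaTable for one published epoch of the study basin."""
    areas = STUDY_AREAS[str(epoch)]
    return AreaTable(str(epoch), dict(areas),
                     total=STUDY_TOTAL_AREA if fixed_total else None)
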