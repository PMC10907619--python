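"""Equivalent-factor ecosystem-service valuation with dynamic correction.

The per-class coefficient VC_i (yuan/hm²) is the standard equivalent Ea
times the sum of the class's dimensionless per-function equivalents
EC_f, scaled by a biomass correction Q (regional vs national NPP and
fractional vegetation cover) and a social-development correction
PI = A·W (per-capita-GDP ratio times willingness-to-pay ratio, the
latter a logistic stage coefficient of the Engel coefficient):

    VC_i = Q · PI · Σ_f Ea · EC_f(i),      ESV = Σ_i A_i · VC_i

Two equivalent-table versions are bundled: the 9-function "2003"
convention and the 11-function "2015-improved" convention that adds
water supply and nutrient-cycle maintenance. Construction land is zero
throughout. The bundled numeric tables are representative of the
published convention, not authoritative transcriptions; see the CSV
headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .accounting import AreaTable
from .grids import LULCGrid
from .jenks import classify, natural_breaks
from .synthetic import SocioSeries

CATEGORIES = ("provisioning", "regulation", "support", "culture")

#: published standard equivalents of the study region, yuan/hm²
STANDARD_EQUIVALENTS = {1990: 2006.0, 2000: 2043.0, 2010: 2107.0, 2020: 2181.0}

#: table-version policy: 2003 table for the early epochs, the improved
#: 2015 table from 2020 on (including all forward scenarios)
TABLE_VERSION_BY_YEAR = {1990: "2003", 2000: "2003", 2010: "2003", 2020: "2015"}


def table_version_for_year(year: int) -> str:
    return TABLE_VERSION_BY_YEAR.get(int(year), "2015")


@dataclass
class EquivalentTable:
    """Per-class × per-function dimensionless equivalents EC_f."""

    version: str
    table: pd.DataFrame  # index class_code, columns function names
    categories: dict[str, str]  # function -> category

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValueError("equivalents must be non-negative")
        unknown = set(self.categories.values()) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown service categories: {unknown}")

    @property
    def functions(self) -> list[str]:
        return list(self.table.columns)

    @property
    def classes(self) -> list[int]:
        return list(self.table.index)


def load_equivalent_table(version: str = "2003") -> EquivalentTable:
    """Load a bundled equivalent-table version ("2003" or "2015")."""
    version = {"2015-improved": "2015"}.get(version, version)
    fname = f"equivalents_{version}_synthetic.csv"
    with resources.files("esvopt.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, comment="#")
    cats = dict(zip(df["function"], df["category"]))
    pivot = df.pivot(index="class_code", columns="function", values="equivalent")
    pivot = pivot[list(dict.fromkeys(df["function"]))]  # keep file order
    return EquivalentTable(version, pivot, cats)


@dataclass
class BiomassCorrection:
    NPP_region: float
    NPP_nation: float
    FVC_region: float
    FVC_nation: float


@dataclass
class SocialCorrection:
    GDP_region: float
    GDP_nation: float
    En_region: float
    En_nation: float


@dataclass
class ESVReport:
    """Valuation of one epoch/scenario, all internal values in yuan."""

    year: str
    per_class: dict[int, float]
    per_function: dict[str, float]
    per_category: dict[str, float]
    total: float

    def __post_init__(self) -> None:
        for margin in (self.per_class, self.per_function):
            s = sum(margin.values())
            if abs(s - self.total) > 1e-6 * max(abs(self.total), 1.0):
                raise AssertionError("report margins do not sum to the total")

    def total_billion(self) -> float:
        """Total in 10⁹ yuan (the reporting unit)."""
        return self.total / 1e9

    def to_frame(self) -> pd.DataFrame:
        rows = [{"year": self.year, "kind": "class", "key": str(k), "value_yuan": v}
                for k, v in self.per_class.items()]
        rows += [{"year": self.year, "kind": "function", "key": k, "value_yuan": v}
                 for k, v in self.per_function.items()]
        rows += [{"year": self.year, "kind": "category", "key": k, "value_yuan": v}
                 for k, v in self.per_category.items()]
        rows.append({"year": self.year, "kind": "total", "key": "total",
                     "value_yuan": self.total})
        return pd.DataFrame(rows)


def standard_equivalent(series: dict[str, SocioSeries] | None, year: int,
                        use_packaged: bool = True) -> float:
    """Standard equivalent Ea (yuan/hm²) for one year.

    The packaged constants for the four study years are authoritative
    when available; otherwise Ea is 1/7 of the mean per-hectare grain
    output value (yield × price), the conventional anchoring of one
    dimensionless equivalent.
    """
    if use_packaged and int(year) in STANDARD_EQUIVALENTS:
        return STANDARD_EQUIVALENTS[int(year)]
    if not series:
        raise ValueError(f"no packaged Ea for {year} and no series given")
    try:
        y = series["grain_yield"].value_at(int(year))
        p = series["grain_price"].value_at(int(year))
    except (KeyError, ValueError) as exc:
        raise ValueError(f"grain series do not cover {year}") from exc
    return y * p / 7.0


def engel_L(En: float) -> float:
    """Social development stage coefficient L = 1/(1+e^{−(1/En − 3)})."""
    if En <= 0:
        raise ValueError("Engel coefficient must be positive")
    if En > 1:
        raise ValueError("Engel coefficient is a fraction in (0, 1]")
    return 1.0 / (1.0 + math.exp(-(1.0 / En - 3.0)))


def biomass_factor(bc: BiomassCorrection) -> float:
    """Q = (NPP_region/NPP_nation + FVC_region/FVC_nation) / 2."""
    if bc.NPP_nation <= 0 or bc.FVC_nation <= 0:
        raise ValueError("national means must be positive")
    return (bc.NPP_region / bc.NPP_nation + bc.FVC_region / bc.FVC_nation) / 2.0


def social_coefficient(sc: SocialCorrection) -> float:
    """PI = A·W with A the GDP ratio and W the ratio of stage coefficients."""
    if sc.GDP_nation <= 0:
        raise ValueError("national GDP must be positive")
    A = sc.GDP_region / sc.GDP_nation
    W = engel_L(sc.En_region) / engel_L(sc.En_nation)
    return A * W


def corrected_coefficients(eq: EquivalentTable, Ea: float, Q: float = 1.0,
                           PI: float = 1.0) -> pd.DataFrame:
    """Per-class × per-function values in yuan/hm²: Q·PI·Ea·EC_f.

    Row sums are the per-class coefficients VC_i. With Q = PI = 1 this
    reduces to the unscaled table valuation.
    """
    if Ea <= 0 or Q <= 0 or PI <= 0:
        raise ValueError("Ea, Q and PI must be positive")
    return eq.table * (Q * PI * Ea)


def class_coefficients(vc_table: pd.DataFrame) -> dict[int, float]:
    """Collapse a corrected per-function table to per-class VC_i."""
    return {int(c): float(v) for c, v in vc_table.sum(axis=1).items()}


def esv_total(at: AreaTable, vc_table: pd.DataFrame,
              categories: dict[str, str]) -> ESVReport:
    """Aggregate ESV = Σ A_i · VC_i with both margins and category sums."""
    classes = [c for c in vc_table.index if c in at.areas]
    missing = set(at.areas) - set(vc_table.index)
    if missing:
        raise ValueError(f"no coefficients for classes {sorted(missing)}")
    areas = np.array([at.areas[c] for c in classes])
    if (areas < 0).any():
        raise ValueError("negative area")
    sub = vc_table.loc[classes]
    per_cell = sub.mul(areas, axis=0)  # class × function, yuan
    per_class = {int(c): float(v) for c, v in per_cell.sum(axis=1).items()}
    per_function = {str(f): float(v) for f, v in per_cell.sum(axis=0).items()}
    per_category = {c: 0.0 for c in CATEGORIES}
    for f, v in per_function.items():
        per_category[categories[f]] += v
    total = float(per_cell.values.sum())
    return ESVReport(at.epoch, per_class, per_function, per_category, total)


def increment(earlier: float, later: float) -> float:
    return later - earlier


def pct_change(earlier: float, later: float) -> float:
    if earlier == 0:
        raise ValueError("percent change undefined for zero baseline")
    return (later - earlier) / earlier * 100.0


def contribution_share(subset_increment: float, total_increment: float) -> float:
    if total_increment == 0:
        raise ValueError("no total change to attribute")
    return subset_increment / total_increment * 100.0


def derived_stats(totals: dict[str, float]) -> pd.DataFrame:
    """Pairwise increments and % changes between successive reports.

    ``totals`` maps labels (years or scenarios) to total values in any
    consistent unit; rounding happens only here, at the reporting layer.
    """
    labels = list(totals)
    if len(labels) < 2:
        raise ValueError("need at least two reports")
    rows = []
    for a, b in zip(labels, labels[1:]):
        rows.append(
            {
                "from": a,
                "to": b,
                "increment": round(increment(totals[a], totals[b]), 2),
                "pct_change": round(pct_change(totals[a], totals[b]), 2),
            }
        )
    return pd.DataFrame(rows)


def esv_grid(grid: LULCGrid, vc_by_class: dict[int, float]) -> np.ndarray:
    """Per-cell coefficient raster (yuan/hm²); nodata cells become NaN."""
    missing = set(grid.classes().tolist()) - set(vc_by_class)
    if missing:
        raise ValueError(f"no coefficient for classes {sorted(missing)}")
    out = np.full(grid.shape, np.nan)
    for c, vc in vc_by_class.items():
        out[grid.values == c] = vc
    return out


def jenks_levels(value_raster: np.ndarray, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Five-level value map via natural breaks; returns (levels, breaks).

    Levels are 1..k (0 = nodata); breaks are upper-inclusive bounds.
    """
    finite = value_raster[np.isfinite(value_raster)]
    breaks = natural_breaks(finite, k)
    return classify(value_raster, breaks), breaks


def fvc_from_ndvi(ndvi: np.ndarray, low_pct: float = 5.0,
                  high_pct: float = 95.0) -> np.ndarray:
    """Fractional vegetation cover by the dimidiate pixel model.

    FVC = (NDVI − NDVI_soil)/(NDVI_veg − NDVI_soil) clipped to [0, 1],
    with the soil/vegetation endpoints at the stated percentiles.
    """
    arr = np.asarray(ndvi, float)
    lo, hi = np.nanpercentile(arr, [low_pct, high_pct])
    if hi <= lo:
        raise ValueError("degenerate NDVI distribution")
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
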