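"""Synthetic study inputs with known ground truth.

The real analysis starts from multi-epoch classified land-use rasters,
stacks of driving-factor rasters and statistical-yearbook series. This
module generates all three with a known generating process so every
downstream stage — accounting, valuation, optimization, allocation —
can be tested offline against configured truth:

* a pair of categorical grids whose cell-level transitions follow a
  configured row-stochastic kernel, with change seeded in contiguous
  patches (the spatial structure a patch-based CA expects);
* continuous factor rasters, some carrying a logistic link to specific
  transitions (recoverable signal for suitability learning), the rest
  pure noise;
* socioeconomic series with exponential trend and multiplicative noise
  (the structure grey forecasting assumes).

Every operation draws from a single integer-seeded generator, so a run
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CLASS_NAMES, FactorStack, LULCGrid

#: class composition used when none is configured — an arid-basin mix
#: dominated by grassland and unused land
DEFAULT_CLASS_PROBS = (0.07, 0.05, 0.49, 0.04, 0.01, 0.34)

#: default inter-epoch kernel: persistence-dominated with the basin's
#: characteristic flows (unused → grassland/cultivated, grassland →
#: cultivated/construction, forest loss, slight water loss)
DEFAULT_KERNEL = np.array(
    [
        [0.95, 0.00, 0.02, 0.00, 0.02, 0.01],
        [0.02, 0.93, 0.05, 0.00, 0.00, 0.00],
        [0.06, 0.01, 0.91, 0.00, 0.01, 0.01],
        [0.00, 0.00, 0.02, 0.95, 0.00, 0.03],
        [0.00, 0.00, 0.00, 0.00, 1.00, 0.00],
        [0.05, 0.00, 0.08, 0.01, 0.01, 0.85],
    ]
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SeriesSpec:
    """Exponential-trend series: v(t) = v0 · (1+g)^t · exp(σ·z_t)."""

    initial: float
    growth: float
    noise_sd: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise ConfigurationError("series initial value must be >= 0")


@dataclass
class FactorSpec:
    """One driving-factor raster.

    ``transition`` names the (from, to) class pair the factor drives;
    ``slope`` is the logistic link coefficient: cells that underwent the
    transition receive a mean shift equal to ``slope`` on a unit-variance
    field, so the posterior log-odds of conversion are linear in the
    factor with that slope. ``transition=None`` gives pure noise.
    """

    name: str
    transition: tuple[int, int] | None = None
    slope: float = 0.0
    smooth_sigma: float = 2.0


@dataclass
class SocioSeries:
    """A named annual series (yearbook-style)."""

    name: str
    years: list[int]
    values: list[float]
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values length mismatch")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")

    def value_at(self, year: int) -> float:
        return self.values[self.years.index(year)]

    def asarray(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _default_series_specs() -> dict[str, SeriesSpec]:
    # Yearbook-style inputs behind the population/food constraints and
    # the valuation corrections; levels chosen to resemble an arid
    # northwest-China basin around 1990.
    return {
        "population": SeriesSpec(350_000, 0.016, 0.01, "persons"),
        "gdp_region": SeriesSpec(3_000, 0.080, 0.02, "yuan/person"),
        "gdp_nation": SeriesSpec(5_000, 0.085, 0.02, "yuan/person"),
        "engel_region": SeriesSpec(0.56, -0.010, 0.005, "fraction"),
        "engel_nation": SeriesSpec(0.52, -0.011, 0.005, "fraction"),
        "grain_yield": SeriesSpec(6_000, 0.020, 0.02, "kg/hm2"),
        "grain_area": SeriesSpec(200_000, 0.020, 0.02, "hm2"),
        "grain_price": SeriesSpec(1.0, 0.030, 0.02, "yuan/kg"),
        "npp_region": SeriesSpec(280, 0.006, 0.01, "gC/m2/yr"),
        "npp_nation": SeriesSpec(490, 0.003, 0.01, "gC/m2/yr"),
        "fvc_region": SeriesSpec(0.34, 0.004, 0.01, "fraction"),
        "fvc_nation": SeriesSpec(0.55, 0.002, 0.01, "fraction"),
    }


@dataclass
class SyntheticConfig:
    """Everything needed to generate one synthetic study region."""

    grid_rows: int = 120
    grid_cols: int = 120
    n_classes: int = 6
    cell_area: float = 1.0
    transition_kernel: np.ndarray = field(
        default_factory=lambda: DEFAULT_KERNEL.copy()
    )
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    factor_specs: list[FactorSpec] = field(default_factory=list)
    series_specs: dict[str, SeriesSpec] = field(
        default_factory=_default_series_specs
    )
    start_year: int = 1990
    n_years: int = 31
    mean_patch_cells: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be positive")
        self.transition_kernel = np.asarray(self.transition_kernel, float)
        k = self.transition_kernel
        if k.shape != (self.n_classes, self.n_classes):
            raise ConfigurationError("kernel shape must be n_classes²")
        if np.any(k < 0) or np.any(np.abs(k.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition_kernel rows must sum to 1")
        if not self.factor_specs:
            self.factor_specs = self._default_factor_specs()

    def _default_factor_specs(self) -> list[FactorSpec]:
        specs: list[FactorSpec] = []
        k = self.transition_kernel
        for i in range(self.n_classes):
            for j in range(self.n_classes):
                if i != j and k[i, j] > 0:
                    specs.append(
                        FactorSpec(f"drv_{i + 1}to{j + 1}", (i + 1, j + 1), 3.0)
                    )
        # pad with pure-noise layers up to the study's 18 drivers
        n_noise = max(0, 18 - len(specs))
        specs += [FactorSpec(f"noise_{k_}") for k_ in range(n_noise)]
        return specs

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _voronoi_classes(config: SyntheticConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Patchy base map: nearest-seed assignment of class-labelled seeds."""
    from scipy.spatial import cKDTree

    rows, cols = config.grid_rows, config.grid_cols
    n_seeds = max(config.n_classes, rows * cols // (4 * config.mean_patch_cells))
    pts = rng.uniform([0, 0], [rows, cols], size=(n_seeds, 2))
    probs = np.asarray(config.class_probs[: config.n_classes], float)
    probs = probs / probs.sum()
    labels = rng.choice(np.arange(1, config.n_classes + 1), n_seeds, p=probs)
    rr, cc = np.mgrid[0:rows, 0:cols]
    _, idx = cKDTree(pts).query(np.column_stack([rr.ravel(), cc.ravel()]))
    return labels[idx].reshape(rows, cols)


def _grow_patches(eligible: np.ndarray, quota: int, mean_patch: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Pick exactly ``quota`` cells from ``eligible`` in contiguous patches.

    BFS from random seeds with randomized frontier order; patch sizes
    are geometric with the configured mean, truncated by the quota.
    """
    rows, cols = eligible.shape
    avail = eligible.copy()
    chosen = np.zeros_like(eligible, dtype=bool)
    remaining = quota
    flat_avail = np.flatnonzero(avail)
    while remaining > 0 and flat_avail.size:
        seed_flat = int(rng.choice(flat_avail))
        size = min(remaining, 1 + int(rng.geometric(1.0 / mean_patch)))
        frontier = [seed_flat]
        grown = 0
        while frontier and grown < size:
            f = frontier.pop(rng.integers(len(frontier)))
            r, c = divmod(f, cols)
            if not avail[r, c]:
                continue
            avail[r, c] = False
            chosen[r, c] = True
            grown += 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and avail[nr, nc]:
                    frontier.append(nr * cols + nc)
        remaining -= grown
        flat_avail = np.flatnonzero(avail)
    return chosen


def generate_lulc_pair(config: SyntheticConfig) -> tuple[LULCGrid, LULCGrid]:
    """Two aligned epochs whose transitions realize the configured kernel.

    The per-class number of converted cells is the rounded expectation
    under the kernel, so empirical transition frequencies converge to the
    kernel as the grid grows; converted cells are seeded patch-wise for
    spatial autocorrelation.
    """
    rng = config.rng()
    base = _voronoi_classes(config, rng)
    second = base.copy()
    converted = np.zeros_like(base, dtype=bool)
    k = config.transition_kernel
    for i in range(config.n_classes):
        src_mask = base == i + 1
        n_src = int(src_mask.sum())
        if n_src == 0:
            continue
        targets = [j for j in range(config.n_classes) if j != i and k[i, j] > 0]
        for j in targets:
            quota = int(round(k[i, j] * n_src))
            if quota == 0:
                continue
            cells = _grow_patches(src_mask & ~converted, quota,
                                  config.mean_patch_cells, rng)
            second[cells] = j + 1
            converted |= cells
    g1 = LULCGrid(base, cell_area=config.cell_area)
    g2 = LULCGrid(second, cell_area=config.cell_area)
    return g1, g2


def generate_factor_stack(config: SyntheticConfig,
                          truth_pair: tuple[LULCGrid, LULCGrid]) -> FactorStack:
    """Driving-factor rasters with recoverable transition signal.

    Each linked factor is a smoothed unit-variance Gaussian field shifted
    by its slope on cells that underwent the linked transition; with unit
    noise variance the conversion log-odds are linear in the factor with
    exactly that slope.
    """
    from scipy.ndimage import gaussian_filter

    g1, g2 = truth_pair
    g1.require_alignment(g2)
    if (g1.shape[0], g1.shape[1]) != (config.grid_rows, config.grid_cols):
        raise ConfigurationError("truth pair geometry does not match config")
    rng = np.random.default_rng(config.seed + 1)
    layers: dict[str, np.ndarray] = {}
    for spec in config.factor_specs:
        noise = rng.standard_normal(g1.shape)
        if spec.smooth_sigma > 0:
            noise = gaussian_filter(noise, spec.smooth_sigma)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        if spec.transition is not None and spec.slope != 0.0:
            i, j = spec.transition
            changed = (g1.values == i) & (g2.values == j)
            noise = noise + spec.slope * changed
        layers[spec.name] = noise
    return FactorStack(layers)


def generate_socio_series(config: SyntheticConfig) -> dict[str, SocioSeries]:
    """Yearbook-style series with exponential trend and log-normal noise."""
    if not config.series_specs:
        raise ConfigurationError("no series_specs configured")
    rng = np.random.default_rng(config.seed + 2)
    years = list(range(config.start_year, config.start_year + config.n_years))
    out: dict[str, SocioSeries] = {}
    for name, spec in config.series_specs.items():
        t = np.arange(config.n_years)
        trend = spec.initial * (1.0 + spec.growth) ** t
        noise = (
            np.exp(spec.noise_sd * rng.standard_normal(config.n_years))
            if spec.noise_sd > 0
            else np.ones(config.n_years)
        )
        out[name] = SocioSeries(name, years, list(trend * noise), spec.units)
    return out


def class_name(code: int) -> str:
    return CLASS_NAMES.get(code, f"class_{code}")
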