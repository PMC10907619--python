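"""Grey forecasting and grey multi-objective land-structure optimization.

Two pieces:

* **GM(1,1)** — first-order one-variable grey model: accumulate the
  series (1-AGO), least-squares fit of the whitened equation
  x⁰(k) = −a·z¹(k) + b, exponential continuation. Prediction uses the
  bias-corrected discretization (growth ratio q = (2−a)/(2+a)), which
  continues a noiseless exponential exactly and degrades gracefully to
  a constant as a → 0.

* **GMOP** — a linear program over the six class areas x₁..x₆
  (cultivated, forest, grassland, water, construction, unused, hm²)
  with three objectives (economic benefit, ecosystem-service value,
  ecological capacity net of a 12 % biodiversity set-aside) and the
  study's constraint families: fixed basin total, a population row with
  interval-valued ("grey") coefficients, a food-security floor on
  cropland, a green-equivalent forest-cover floor, and per-class box
  bounds. Grey coefficients are whitened by a λ-weighted combination of
  their bounds; multi-objective modes use a weighted sum of min–max
  normalized objectives (lexicographic solving available as an
  alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .accounting import AreaTable, TransitionMatrix, markov_project

N_CLASSES = 6


class GMOPError(RuntimeError):
    """Solver-level failure (infeasible/unbounded) with diagnostics."""


# ---------------------------------------------------------------- GM(1,1)

@dataclass
class GM1Model:
    """Fitted GM(1,1): development coefficient a, grey action b."""

    a: float
    b: float
    x0_first: float
    n: int

    @property
    def growth_ratio(self) -> float:
        """Per-step ratio of the fitted response, q = (2−a)/(2+a)."""
        return (2.0 - self.a) / (2.0 + self.a)

    def response(self, k: int) -> float:
        """Fitted/extrapolated original-scale value at position k (1-based)."""
        if k == 1:
            return self.x0_first
        c = 2.0 * self.b / (2.0 + self.a)
        return c * self.growth_ratio ** (k - 1)


def gm11_fit(series: Sequence[float]) -> GM1Model:
    """Fit GM(1,1) to a positive series of length ≥ 4."""
    x0 = np.asarray(series, float)
    if x0.size < 4:
        raise ValueError("GM(1,1) needs at least 4 observations")
    if np.any(x0 <= 0):
        raise ValueError("GM(1,1) requires strictly positive values")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z, np.ones(z.size)])
    (a, b), *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    return GM1Model(float(a), float(b), float(x0[0]), int(x0.size))


def gm11_predict(model: GM1Model, horizon: int = 1) -> float:
    """Continue the fitted series ``horizon`` steps past its end."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return model.response(model.n + horizon)


# ------------------------------------------------------------- LP pieces

@dataclass
class ObjectiveSpec:
    """Per-class objective coefficients (printed model inputs).

    ``C`` already includes the (100−12)% biodiversity deduction.
    """

    E: np.ndarray = field(default_factory=lambda: np.array(
        [4.5, 2.37, 1.02, 0.02, 443.72, 0.0]))
    V: np.ndarray = field(default_factory=lambda: np.array(
        [0.64, 2.88, 1.93, 14.6, 0.0, 0.12]))
    C: np.ndarray = field(default_factory=lambda: np.array(
        [4.64, 0.59, 0.50, 0.18, 4.64, 0.0]))
    deduction: float = 0.88

    def __post_init__(self) -> None:
        for v in (self.E, self.V, self.C):
            if np.asarray(v).shape != (N_CLASSES,):
                raise ValueError("objective coefficient vectors must have length 6")

    def vector(self, name: str) -> np.ndarray:
        return {"f1": self.E, "f2": self.V, "f3": self.C}[name]


@dataclass
class ConstraintSet:
    """All constraint constants of the 2035 optimization."""

    total_area: float = 5_035_616.0
    # population row: grey coefficients on (x1+x2+x3) and x5
    a21: tuple[float, float] = (0.05, 0.07)
    a22: tuple[float, float] = (4.31, 6.73)
    population: float = 563_578.0
    # food security
    S: float = 538.0            # per-capita demand, kg
    f0: float = 1.0             # self-sufficiency rate
    f1_yield: float = 10_845.0  # kg/ha
    f2_ratio: float = 0.2668    # crop cultivation ratio
    f3_index: float = 1.29      # multiple-cropping index
    cropland_cap: float = 957_862.0
    # green-equivalent forest-cover floor
    green_coefs: tuple[float, float, float] = (0.46, 1.00, 0.49)
    green_floor_frac: float = 0.20
    # per-class box bounds (hm²)
    forest_bounds: tuple[float, float] = (92_537.0, 121_697.0)
    grassland_bounds: tuple[float, float] = (2_364_064.0, 2_616_499.0)
    water_bounds: tuple[float, float] = (148_363.0, 166_058.0)
    construction_bounds: tuple[float, float] = (62_739.0, 91_707.0)
    unused_bounds: tuple[float, float] = (0.0, 1_326_661.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.a21, self.a22, self.forest_bounds,
                       self.grassland_bounds, self.water_bounds,
                       self.construction_bounds, self.unused_bounds):
            if lo > hi:
                raise ValueError("interval lower bound exceeds upper bound")

    def food_floor(self) -> float:
        """Cropland floor from food demand: P·S·f0/(f1·f2·f3), hm²."""
        return (self.population * self.S * self.f0
                / (self.f1_yield * self.f2_ratio * self.f3_index))

    def bounds(self) -> list[tuple[float, float]]:
        return [
            (self.food_floor(), self.cropland_cap),
            self.forest_bounds,
            self.grassland_bounds,
            self.water_bounds,
            self.construction_bounds,
            self.unused_bounds,
        ]


@dataclass
class GreyResolution:
    """Whitening of the grey population coefficients.

    Each interval (lo, hi) resolves to lo + λ·(hi − lo); λ defaults to
    the midpoint.
    """

    lam_a21: float = 0.5
    lam_a22: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.lam_a21 <= 1 and 0 <= self.lam_a22 <= 1):
            raise ValueError("λ must lie in [0, 1]")

    @staticmethod
    def whiten(interval: tuple[float, float], lam: float) -> float:
        lo, hi = interval
        return lo + lam * (hi - lo)

    def resolve(self, cs: ConstraintSet) -> tuple[float, float]:
        return (self.whiten(cs.a21, self.lam_a21),
                self.whiten(cs.a22, self.lam_a22))


@dataclass
class ScenarioSpec:
    """Which objectives a scenario maximizes and how they are combined."""

    mode: str  # bau | red | elp | eeb
    weights: dict[str, float] | None = None
    grey: GreyResolution = field(default_factory=GreyResolution)
    aggregation: str = "weighted"  # or "lexicographic"

    OBJECTIVES = {"red": ["f1"], "elp": ["f2", "f3"],
                  "eeb": ["f1", "f2", "f3"], "bau": []}

    def __post_init__(self) -> None:
        self.mode = self.mode.lower()
        if self.mode not in self.OBJECTIVES:
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        objs = self.OBJECTIVES[self.mode]
        if self.weights is None:
            self.weights = {o: 1.0 / len(objs) for o in objs} if objs else {}
        if objs:
            w = np.array([self.weights[o] for o in objs])
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be non-negative, sum > 0")
            self.weights = {o: float(x / w.sum()) for o, x in zip(objs, w)}


@dataclass
class LinearProgram:
    """Assembled LP in SciPy form, rows labelled for diagnostics."""

    c_max: np.ndarray           # objective to MAXIMIZE
    A_ub: np.ndarray
    b_ub: np.ndarray
    row_labels: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    bounds: list[tuple[float, float]]

    def solve(self, maximize: bool = True):
        sign = -1.0 if maximize else 1.0
        return linprog(sign * self.c_max, A_ub=self.A_ub, b_ub=self.b_ub,
                       A_eq=self.A_eq, b_eq=self.b_eq, bounds=self.bounds,
                       method="highs")


@dataclass
class Solution:
    x: np.ndarray
    objectives: dict[str, float]
    status: str
    binding: list[str]
    lam: tuple[float, float] | None = None

    def to_frame(self, cs: ConstraintSet) -> pd.DataFrame:
        from .grids import CLASS_NAMES
        bounds = cs.bounds()
        return pd.DataFrame(
            {
                "class_code": np.arange(1, N_CLASSES + 1),
                "class_name": [CLASS_NAMES[i] for i in range(1, N_CLASSES + 1)],
                "area_hm2": self.x,
                "lower": [b[0] for b in bounds],
                "upper": [b[1] for b in bounds],
                "binding": [
                    ("lower" if abs(self.x[i] - bounds[i][0]) < 1e-6 * max(1, bounds[i][0])
                     else "upper" if abs(self.x[i] - bounds[i][1]) < 1e-6 * max(1, bounds[i][1])
                     else "") for i in range(N_CLASSES)
                ],
            }
        )


def build_lp(spec: ScenarioSpec, cs: ConstraintSet, obj: ObjectiveSpec,
             objective_vector: np.ndarray | None = None) -> LinearProgram:
    """Assemble the scenario LP with grey coefficients whitened per spec.

    ``objective_vector`` overrides the scenario objective (used when the
    scalarized vector has already been composed).
    """
    a21, a22 = spec.grey.resolve(cs)
    A_ub = np.array([
        [a21, a21, a21, 0.0, a22, 0.0],                       # population
        [-cs.green_coefs[0], -cs.green_coefs[1], -cs.green_coefs[2],
         0.0, 0.0, 0.0],                                      # green floor
    ])
    b_ub = np.array([
        cs.population,
        -cs.green_floor_frac * cs.total_area,
    ])
    labels = ["population", "green_floor"]
    A_eq = np.ones((1, N_CLASSES))
    b_eq = np.array([cs.total_area])
    if objective_vector is None:
        objs = ScenarioSpec.OBJECTIVES[spec.mode]
        objective_vector = (obj.vector(objs[0]) if len(objs) == 1
                            else np.zeros(N_CLASSES))
    return LinearProgram(np.asarray(objective_vector, float), A_ub, b_ub,
                         labels, A_eq, b_eq, cs.bounds())


def _objective_range(name: str, spec: ScenarioSpec, cs: ConstraintSet,
                     obj: ObjectiveSpec) -> tuple[float, float]:
    """(min, max) of one objective over the scenario's feasible region."""
    lp = build_lp(spec, cs, obj, objective_vector=obj.vector(name))
    hi = lp.solve(maximize=True)
    lo = lp.solve(maximize=False)
    if not (hi.success and lo.success):
        raise GMOPError(f"objective {name}: {hi.message or lo.message}")
    return float(lo.fun), float(-hi.fun)


def _binding_rows(lp: LinearProgram, x: np.ndarray,
                  rtol: float = 1e-7) -> list[str]:
    out = []
    slack = lp.b_ub - lp.A_ub @ x
    for lab, s, b in zip(lp.row_labels, slack, lp.b_ub):
        if abs(s) <= rtol * max(1.0, abs(b)):
            out.append(lab)
    return out


def solve_scenario(spec: ScenarioSpec, cs: ConstraintSet, obj: ObjectiveSpec,
                   markov: tuple[TransitionMatrix, AreaTable, int] | None = None,
                   ) -> Solution:
    """Optimal land-use structure for one scenario.

    The business-as-usual mode bypasses the LP entirely and returns the
    Markov projection; LP modes maximize the scalarized objective and
    report all three objective values at the optimum.
    """
    if spec.mode == "bau":
        if markov is None:
            raise ValueError("BAU needs (transition matrix, base table, steps)")
        tm, base, steps = markov
        projected = markov_project(tm, base, steps)
        x = projected.as_vector(list(range(1, N_CLASSES + 1)))
        return Solution(x, _objective_values(x, obj), "markov", [])

    objs = ScenarioSpec.OBJECTIVES[spec.mode]
    if len(objs) == 1:
        vec = obj.vector(objs[0])
    elif spec.aggregation == "weighted":
        # weighted sum of min–max normalized objectives: constants drop,
        # so the scalarized vector is Σ w·coef/range
        vec = np.zeros(N_CLASSES)
        for name in objs:
            lo, hi = _objective_range(name, spec, cs, obj)
            rng = hi - lo
            if rng <= 0:
                continue  # objective constant over the region
            vec = vec + spec.weights[name] * obj.vector(name) / rng
    elif spec.aggregation == "lexicographic":
        return _solve_lexicographic(spec, cs, obj, objs)
    else:
        raise ValueError(f"unknown aggregation {spec.aggregation!r}")

    lp = build_lp(spec, cs, obj, objective_vector=vec)
    res = lp.solve(maximize=True)
    if not res.success:
        raise GMOPError(_diagnose(lp, res))
    x = res.x
    return Solution(x, _objective_values(x, obj), "optimal",
                    _binding_rows(lp, x), spec.grey.resolve(cs))


def _solve_lexicographic(spec: ScenarioSpec, cs: ConstraintSet,
                         obj: ObjectiveSpec, objs: list[str]) -> Solution:
    """Optimize objectives in priority order, fixing each optimum in turn."""
    lp = build_lp(spec, cs, obj, objective_vector=obj.vector(objs[0]))
    for i, name in enumerate(objs):
        lp.c_max = obj.vector(name)
        res = lp.solve(maximize=True)
        if not res.success:
            raise GMOPError(_diagnose(lp, res))
        if i < len(objs) - 1:  # pin the achieved level: -fᵀx <= -opt
            lp.A_ub = np.vstack([lp.A_ub, -obj.vector(name)])
            lp.b_ub = np.append(lp.b_ub, res.fun)  # res.fun = -opt
            lp.row_labels.append(f"lex_{name}")
    x = res.x
    return Solution(x, _objective_values(x, obj), "optimal",
                    _binding_rows(lp, x), spec.grey.resolve(cs))


def _objective_values(x: np.ndarray, obj: ObjectiveSpec) -> dict[str, float]:
    return {n: float(obj.vector(n) @ x) for n in ("f1", "f2", "f3")}


def _diagnose(lp: LinearProgram, res) -> str:
    msg = [f"LP failed: {res.message}"]
    lo_sum = sum(b[0] for b in lp.bounds)
    hi_sum = sum(b[1] for b in lp.bounds)
    msg.append(f"bound sums [{lo_sum:.0f}, {hi_sum:.0f}] vs total "
               f"{lp.b_eq[0]:.0f}")
    # population row attainability at the box minimum
    if "population" in lp.row_labels:
        i = lp.row_labels.index("population")
        min_lhs = float(lp.A_ub[i] @ np.array([b[0] for b in lp.bounds]))
        msg.append(f"population row minimum {min_lhs:.0f} vs cap "
                   f"{lp.b_ub[i]:.0f}")
    return "; ".join(msg)


def feasibility_check(x: Sequence[float], cs: ConstraintSet,
                      grey: GreyResolution | None = None,
                      rtol: float = 1e-6) -> list[tuple[str, float]]:
    """Signed slack of every violated constraint; empty list iff feasible.

    Slack is negative by the amount of violation, in the constraint's
    own units.
    """
    x = np.asarray(x, float)
    if x.shape != (N_CLASSES,):
        raise ValueError("need a 6-vector of class areas")
    grey = grey or GreyResolution()
    a21, a22 = grey.resolve(cs)
    out: list[tuple[str, float]] = []

    tot = float(x.sum())
    if abs(tot - cs.total_area) > rtol * cs.total_area:
        out.append(("total_area", cs.total_area - tot))
    pop_lhs = a21 * x[:3].sum() + a22 * x[4]
    if pop_lhs > cs.population * (1 + rtol):
        out.append(("population", cs.population - pop_lhs))
    green = float(np.dot(cs.green_coefs, x[:3]))
    floor = cs.green_floor_frac * cs.total_area
    if green < floor * (1 - rtol):
        out.append(("green_floor", green - floor))
    names = ["cultivated", "forest", "grassland", "water", "construction",
             "unused"]
    for i, ((lo, hi), name) in enumerate(zip(cs.bounds(), names)):
        scale = max(1.0, hi)
        if x[i] < lo - rtol * scale:
            out.append((f"{name}_floor", x[i] - lo))
        if x[i] > hi + rtol * scale:
            out.append((f"{name}_cap", hi - x[i]))
        if x[i] < -rtol:
            out.append((f"{name}_nonneg", x[i]))
    return out


def grey_sensitivity(spec: ScenarioSpec, cs: ConstraintSet, obj: ObjectiveSpec,
                     lam_grid: Sequence[float] = (0.0, 0.5, 1.0)) -> pd.DataFrame:
    """Solve the scenario over a grid of whitening parameters.

    One row per (λ_a21, λ_a22) pair; infeasible corners are reported
    with their diagnostic instead of being skipped.
    """
    if any(not 0 <= l <= 1 for l in lam_grid):
        raise ValueError("λ grid must lie in [0, 1]")
    rows = []
    for la in lam_grid:
        for lb in lam_grid:
            s = ScenarioSpec(spec.mode, dict(spec.weights) or None,
                             GreyResolution(la, lb), spec.aggregation)
            row: dict[str, object] = {"lam_a21": la, "lam_a22": lb}
            try:
                sol = solve_scenario(s, cs, obj)
                row["status"] = sol.status
                for i in range(N_CLASSES):
                    row[f"x{i + 1}"] = sol.x[i]
                row.update(sol.objectives)
            except GMOPError as exc:
                row["status"] = f"infeasible: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def solution_area_table(sol: Solution, epoch: str) -> AreaTable:
    """Wrap a solution vector as an AreaTable for downstream valuation."""
    return AreaTable(epoch, {i + 1: float(a) for i, a in enumerate(sol.x)})
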