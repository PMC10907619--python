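"""Patch-based spatial allocation of land-use demand.

A behavioural re-implementation of the patch-generating CA family:

* **Expansion-sample learning** — for each class, cells that newly
  became that class between two observed epochs are positives, a sample
  of unchanged cells negatives; an ensemble-of-trees classifier on the
  driving factors yields a per-class suitability surface.
* **Patch-generating CA** — iterative allocation of a demand vector:
  cells convert with preference proportional to suitability times the
  neighbourhood share of the target class, under a transition-permission
  matrix; classes whose demand stays unmet spawn random patch seeds once
  a per-class suitability threshold (decayed geometrically each round)
  admits them. Stops when every class area is within tolerance of its
  demand.
* **Validation** — overall accuracy, Cohen's kappa and the figure of
  merit against an observed map, change-referenced to a base epoch.

This is desk-scale and mechanism-faithful, not parity with any released
simulation package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from sklearn.ensemble import RandomForestClassifier

from .grids import LULCGrid

_NEIGH_KERNEL = np.ones((3, 3))


class AllocationError(RuntimeError):
    pass


@dataclass
class ExpansionSamples:
    """Training set for one class's expansion suitability."""

    class_code: int
    X: np.ndarray          # (n, k) factor vectors
    y: np.ndarray          # 1 = newly this class, 0 = unchanged cell
    n_positive: int
    n_negative: int


@dataclass
class CAParams:
    """Tunables of the allocation CA.

    demand is in hm² per class (same order as ``classes``); tolerance is
    relative to total area. ``delta`` is the per-round decay of the
    patch-seed suitability threshold.
    """

    demand: dict[int, float]
    permission: np.ndarray | None = None  # (n, n) bool, rows = from-class
    neighborhood: int = 3
    patch_seed_prob: float = 0.02
    delta: float = 0.9
    initial_threshold: float = 0.9
    max_iterations: int = 200
    tolerance: float = 0.001
    seed: int = 0
    neighborhood_weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.neighborhood % 2 != 1 or self.neighborhood < 1:
            raise ValueError("neighborhood size must be odd")


@dataclass
class ValidationReport:
    kappa: float
    overall_accuracy: float
    fom: float
    confusion: np.ndarray
    classes: list[int]

    def __post_init__(self) -> None:
        if not (self.kappa <= self.overall_accuracy + 1e-12
                and self.overall_accuracy <= 1 + 1e-12):
            raise AssertionError("kappa must not exceed overall accuracy")

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "overall_accuracy": self.overall_accuracy,
            "fom": self.fom,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
        }


# ------------------------------------------------------------------ LEAS

def extract_expansion_samples(grid_a: LULCGrid, grid_b: LULCGrid,
                              factors, class_c: int,
                              sampling_rate: float = 0.1,
                              seed: int = 0) -> ExpansionSamples:
    """Positives = cells newly ``class_c``; negatives sampled from
    unchanged cells at ``sampling_rate``."""
    grid_a.require_alignment(grid_b)
    a, b = grid_a.values, grid_b.values
    if class_c not in a and class_c not in b:
        raise ValueError(f"class {class_c} absent from both epochs")
    newly = (b == class_c) & (a != class_c)
    unchanged = a == b
    rng = np.random.default_rng(seed)
    neg_idx = np.flatnonzero(unchanged.ravel())
    if sampling_rate < 1.0:
        take = max(1, int(round(sampling_rate * neg_idx.size)))
        neg_idx = rng.choice(neg_idx, size=take, replace=False)
    pos_idx = np.flatnonzero(newly.ravel())
    X = factors.design_matrix(np.concatenate([pos_idx, neg_idx]))
    y = np.concatenate([np.ones(pos_idx.size), np.zeros(neg_idx.size)])
    return ExpansionSamples(class_c, X, y.astype(int),
                            int(pos_idx.size), int(neg_idx.size))


def fit_leas(samples: ExpansionSamples, factors,
             n_estimators: int = 60, seed: int = 0) -> np.ndarray:
    """Score expansion suitability of the sample's class over the grid.

    Random-forest probabilities of the positive class, shaped like the
    factor rasters, in [0, 1].
    """
    if samples.n_positive < 30:
        raise ValueError("need at least 30 positive samples")
    if samples.n_negative == 0 or samples.n_positive == samples.y.size:
        raise ValueError("single-class sample set")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                 n_jobs=1, min_samples_leaf=5)
    clf.fit(samples.X, samples.y)
    proba = clf.predict_proba(factors.design_matrix())[:, 1]
    return proba.reshape(factors.shape)


def suitability_surfaces(grid_a: LULCGrid, grid_b: LULCGrid, factors,
                         classes=None, sampling_rate: float = 0.1,
                         seed: int = 0,
                         min_positives: int = 30) -> dict[int, np.ndarray]:
    """Fit one suitability surface per class with enough expansion.

    Classes with too little observed expansion fall back to a flat 0.5
    surface (no learned preference).
    """
    classes = classes if classes is not None else sorted(
        np.unique(grid_b.values[grid_b.valid_mask]).tolist())
    out: dict[int, np.ndarray] = {}
    for k, c in enumerate(classes):
        try:
            s = extract_expansion_samples(grid_a, grid_b, factors, c,
                                          sampling_rate, seed + k)
            if s.n_positive < min_positives:
                raise ValueError("too few positives")
            out[c] = fit_leas(s, factors, seed=seed + k)
        except ValueError:
            out[c] = np.full(grid_a.shape, 0.5)
    return out


# -------------------------------------------------------------------- CA

def _neighbor_share(values: np.ndarray, code: int, size: int) -> np.ndarray:
    """Share of the (truncated, centre-excluded) neighbourhood in ``code``."""
    kern = np.ones((size, size))
    kern[size // 2, size // 2] = 0.0
    is_code = (values == code).astype(float)
    count = convolve(is_code, kern, mode="constant", cval=0.0)
    denom = convolve(np.ones_like(is_code), kern, mode="constant", cval=0.0)
    return count / denom


def demand_to_cells(demand: dict[int, float], cell_area: float,
                    n_cells: int) -> dict[int, int]:
    """Largest-remainder rounding of an hm² demand vector to whole cells."""
    raw = {c: d / cell_area for c, d in demand.items()}
    floors = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_cells - sum(floors.values())
    if short < 0:
        raise ValueError("demand exceeds grid capacity")
    order = sorted(raw, key=lambda c: raw[c] - floors[c], reverse=True)
    for c in order[:short]:
        floors[c] += 1
    if sum(floors.values()) != n_cells:
        raise ValueError("demand does not sum to the grid total area")
    return floors


def _conversion_quotas(counts: dict[int, int], target: dict[int, int],
                       permission: np.ndarray,
                       classes: list[int]) -> dict[tuple[int, int], int]:
    """Gross per-pair conversion counts realizing the net demand.

    Net deficits can be served through chains (water → unused →
    cultivated), exactly as observed gross transitions do, so this is a
    minimum-churn transshipment problem on the permitted class digraph:
    node imbalance = current − target cells, flow only on permitted
    edges, outflow capped by current cells, total flow minimized.
    """
    from scipy.optimize import linprog

    idx = {c: i for i, c in enumerate(classes)}
    balance = {c: counts.get(c, 0) - target[c] for c in classes}
    deficit = {c: -b for c, b in balance.items() if b < 0}
    if not deficit:
        return {}
    for c in deficit:  # a deficit class nothing may convert into is hopeless
        if not any(permission[idx[d], idx[c]] for d in classes if d != c):
            raise AllocationError(
                f"demand for class {c} infeasible: no permitted "
                f"transition into it")
    edges = [(i, j) for i in classes for j in classes
             if i != j and permission[idx[i], idx[j]]]
    A_eq = np.zeros((len(classes), len(edges)))
    for k, (i, j) in enumerate(edges):
        A_eq[classes.index(i), k] += 1.0   # outflow
        A_eq[classes.index(j), k] -= 1.0   # inflow
    A_ub = np.zeros((len(classes), len(edges)))
    for k, (i, j) in enumerate(edges):
        A_ub[classes.index(i), k] = 1.0
    res = linprog(np.ones(len(edges)),
                  A_ub=A_ub, b_ub=[counts.get(c, 0) for c in classes],
                  A_eq=A_eq, b_eq=[balance[c] for c in classes],
                  bounds=[(0, None)] * len(edges), method="highs")
    if not res.success:
        raise AllocationError(
            f"no permitted conversion flow satisfies demand "
            f"(deficits {deficit})")
    flow: dict[tuple[int, int], int] = {}
    for k, (i, j) in enumerate(edges):
        q = int(round(res.x[k]))
        if q > 0:
            flow[(i, j)] = q
    # repair integer drift so node balances hold exactly
    for c in classes:
        out = sum(q for (i, _), q in flow.items() if i == c)
        inn = sum(q for (_, j), q in flow.items() if j == c)
        drift = (out - inn) - balance[c]
        if drift and any(j == c for (_, j) in flow):
            key = max((p for p in flow if p[1] == c), key=flow.get)
            flow[key] += drift
    return flow


def simulate_ca(grid_start: LULCGrid, suitability: dict[int, np.ndarray],
                params: CAParams) -> LULCGrid:
    """Allocate the demand vector onto the grid.

    Per round, each deficit class claims its best candidate cells —
    score = suitability × (neighbourhood share + seed bonus) — from
    surplus classes that permit the conversion; unmet classes decay
    their seeding threshold by ``delta`` so isolated seeds become
    admissible. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    values = grid_start.values.copy()
    classes = sorted(params.demand)
    perm = (params.permission if params.permission is not None
            else np.ones((len(classes), len(classes)), bool))
    target = demand_to_cells(params.demand, grid_start.cell_area, values.size)
    counts = {c: int((values == c).sum()) for c in classes}
    # how many cells of each donor class convert to each recipient class
    quotas = _conversion_quotas(counts, target, perm, classes)
    tol_cells = max(0, int(np.floor(params.tolerance * values.size)))
    thresholds = {c: params.initial_threshold for c in classes}

    for _ in range(params.max_iterations):
        open_pairs = {p: q for p, q in quotas.items() if q > 0}
        unmet = {}
        for (d, c), q in open_pairs.items():
            unmet[c] = unmet.get(c, 0) + q
        if not unmet or max(unmet.values()) <= tol_cells:
            break
        shares = {c: _neighbor_share(values, c, params.neighborhood)
                  for c in unmet}
        progress = False
        for (d, c), q in sorted(open_pairs.items(),
                                key=lambda kv: -kv[1]):
            donor_mask = values == d
            w = params.neighborhood_weights.get(c, 1.0)
            adjacency = w * shares[c]
            seed_ok = ((suitability[c] > thresholds[c])
                       & (rng.random(values.shape) < params.patch_seed_prob))
            eligible = donor_mask & ((adjacency > 0) | seed_ok)
            if not eligible.any():
                thresholds[c] *= params.delta
                continue
            score = suitability[c] * (adjacency + 1e-6)
            # tiny random jitter breaks ties reproducibly
            score = score * (1.0 + 1e-9 * rng.random(values.shape))
            flat = np.flatnonzero(eligible.ravel())
            order = flat[np.argsort(-score.ravel()[flat], kind="stable")]
            take = order[:q]
            values.ravel()[take] = c
            quotas[(d, c)] = q - take.size
            if take.size:
                progress = True
            if take.size < q:
                thresholds[c] *= params.delta
        if not progress:
            # no eligible cell anywhere this round: decay all thresholds
            for c in unmet:
                thresholds[c] *= params.delta
    else:
        unmet = {c: sum(q for (d2, c2), q in quotas.items() if c2 == c and q > 0)
                 for c in {c for (_, c), q in quotas.items() if q > 0}}
        unmet = {c: n for c, n in unmet.items() if n > tol_cells}
        if unmet:
            raise AllocationError(
                f"demand unmet after {params.max_iterations} iterations: "
                f"{unmet}")

    result = grid_start.with_values(values)
    _assert_permission_safety(grid_start, result, perm, classes)
    return result


def _assert_permission_safety(before: LULCGrid, after: LULCGrid,
                              perm: np.ndarray, classes: list[int]) -> None:
    idx = {c: i for i, c in enumerate(classes)}
    changed = before.values != after.values
    if not changed.any():
        return
    pairs = set(zip(before.values[changed].tolist(),
                    after.values[changed].tolist()))
    for a, b in pairs:
        if a in idx and b in idx and not perm[idx[a], idx[b]]:
            raise AssertionError(f"forbidden transition {a}->{b} committed")


# ------------------------------------------------------------- validation

def validate(sim: LULCGrid, obs: LULCGrid, base: LULCGrid) -> ValidationReport:
    """Overall accuracy, kappa and figure of merit of a simulated map.

    FOM = B/(A+B+C+D) over cells where change was observed or simulated:
    A misses (observed change, simulated persistence), B hits, C wrong
    class, D false alarms (observed persistence, simulated change).
    """
    sim.require_alignment(obs)
    sim.require_alignment(base)
    mask = sim.valid_mask & obs.valid_mask & base.valid_mask
    s, o, bs = sim.values[mask], obs.values[mask], base.values[mask]
    classes = sorted(set(np.unique(s).tolist()) | set(np.unique(o).tolist()))
    cidx = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    conf = np.zeros((n, n))
    np.add.at(conf, (np.vectorize(cidx.get)(o), np.vectorize(cidx.get)(s)), 1.0)
    total = conf.sum()
    po = np.trace(conf) / total
    pe = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / total**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0

    obs_change = o != bs
    sim_change = s != bs
    A = int((obs_change & ~sim_change).sum())
    B = int((obs_change & sim_change & (s == o)).sum())
    C = int((obs_change & sim_change & (s != o)).sum())
    D = int((~obs_change & sim_change).sum())
    denom = A + B + C + D
    fom = B / denom if denom > 0 else 1.0  # no change anywhere: vacuous hit
    return ValidationReport(float(kappa), float(po), float(fom), conf, classes)


def kappa_oa_from_confusion(conf: np.ndarray) -> tuple[float, float]:
    """Kappa and overall accuracy straight from a confusion matrix."""
    conf = np.asarray(conf, float)
    total = conf.sum()
    po = np.trace(conf) / total
    pe = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / total**2
    return (po - pe) / (1 - pe), po
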