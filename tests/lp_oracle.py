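"""Independent brute-force oracles for the linear-programming tests.

Vertex enumeration: the optimum of a bounded feasible LP is attained at
a basic feasible solution, i.e. at the intersection of n active
constraints. Enumerating all such intersections and taking the best
feasible one is an implementation-independent check of the solver.
"""

from __future__ import annotations

import itertools

import numpy as np

from esvopt.gmop import LinearProgram


def enumerate_optimum(lp: LinearProgram, tol: float = 1e-7):
    """Best objective value over all basic feasible solutions."""
    n = lp.c_max.size
    rows = [(lp.A_eq[i], lp.b_eq[i]) for i in range(lp.A_eq.shape[0])]
    n_eq = len(rows)
    cands: list[tuple[np.ndarray, float]] = []
    for i in range(lp.A_ub.shape[0]):
        cands.append((lp.A_ub[i], lp.b_ub[i]))
    for j, (lo, hi) in enumerate(lp.bounds):
        e = np.zeros(n)
        e[j] = 1.0
        cands.append((e, lo))
        cands.append((e, hi))
    best, best_x = -np.inf, None
    for combo in itertools.combinations(range(len(cands)), n - n_eq):
        A = np.array([r for r, _ in rows] + [cands[i][0] for i in combo])
        b = np.array([v for _, v in rows] + [cands[i][1] for i in combo])
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        scale = max(1.0, np.abs(b).max())
        if np.any(lp.A_ub @ x > lp.b_ub + tol * scale):
            continue
        if np.any(np.abs(lp.A_eq @ x - lp.b_eq) > tol * scale):
            continue
        if any(x[j] < lo - tol * scale or x[j] > hi + tol * scale
               for j, (lo, hi) in enumerate(lp.bounds)):
            continue
        v = float(lp.c_max @ x)
        if v > best:
            best, best_x = v, x
    return best, best_x


def random_instance(rng: np.random.Generator) -> LinearProgram | None:
    """A random 6-variable instance with the study's constraint shapes:
    fixed total, one capacity row, one cover-floor row, box bounds.

    Returns None when the draw happens to be infeasible.
    """
    n = 6
    lo = rng.uniform(0, 8, n)
    hi = lo + rng.uniform(10, 30, n)
    total = rng.uniform(lo.sum() + 5, hi.sum() - 5)
    mid = (lo + hi) / 2
    a = rng.uniform(0.05, 0.5)
    b = rng.uniform(1.0, 7.0)
    cap_row = np.array([a, a, a, 0, b, 0])
    cap = float(cap_row @ mid) * rng.uniform(1.0, 1.3)
    g = rng.uniform(0.3, 1.0, 3)
    floor_row = -np.array([g[0], g[1], g[2], 0, 0, 0])
    floor = float(-floor_row @ mid) * rng.uniform(0.5, 0.9)
    c = rng.uniform(-1, 5, n)
    lp = LinearProgram(
        c_max=c,
        A_ub=np.vstack([cap_row, floor_row]),
        b_ub=np.array([cap, -floor]),
        row_labels=["capacity", "cover_floor"],
        A_eq=np.ones((1, n)),
        b_eq=np.array([total]),
        bounds=[(lo[i], hi[i]) for i in range(n)],
    )
    return lp if lp.solve(maximize=True).success else None


def sample_feasible_points(cs, grey, n_points: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample feasible area vectors of the study constraints."""
    bounds = cs.bounds()
    a21, a22 = grey.resolve(cs)
    out = []
    while len(out) < n_points:
        m = 20000
        x5 = np.column_stack([
            rng.uniform(lo, hi, m) for lo, hi in bounds[:5]])
        x6 = cs.total_area - x5.sum(axis=1)
        ok = (x6 >= bounds[5][0]) & (x6 <= bounds[5][1])
        pop = a21 * x5[:, :3].sum(axis=1) + a22 * x5[:, 4]
        ok &= pop <= cs.population
        green = x5[:, :3] @ np.asarray(cs.green_coefs)
        ok &= green >= cs.green_floor_frac * cs.total_area
        pts = np.column_stack([x5[ok], x6[ok]])
        out.extend(pts.tolist())
    return np.array(out[:n_points])
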