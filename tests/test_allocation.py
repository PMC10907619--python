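import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import train_test_split

from esvopt import accounting as acct
from esvopt import allocation as alloc
from esvopt.grids import FactorStack, LULCGrid
from esvopt.synthetic import (FactorSpec, SyntheticConfig,
                              generate_factor_stack, generate_lulc_pair)


class TestExpansionSamples:
    def test_identical_grids_no_positives(self, lulc_pair, factor_stack):
        g = lulc_pair[0]
        s = alloc.extract_expansion_samples(g, g, factor_stack, 1)
        assert s.n_positive == 0

    def test_positive_count_matches_generator_truth(self, lulc_pair,
                                                    factor_stack):
        g1, g2 = lulc_pair
        truth = int(((g2.values == 1) & (g1.values != 1)).sum())
        s = alloc.extract_expansion_samples(g1, g2, factor_stack, 1)
        assert s.n_positive == truth

    def test_full_sampling_rate_takes_all_unchanged(self, lulc_pair,
                                                    factor_stack):
        g1, g2 = lulc_pair
        s = alloc.extract_expansion_samples(g1, g2, factor_stack, 1,
                                            sampling_rate=1.0)
        assert s.n_negative == int((g1.values == g2.values).sum())

    def test_absent_class_rejected(self, lulc_pair, factor_stack):
        with pytest.raises(ValueError):
            alloc.extract_expansion_samples(*lulc_pair, factor_stack, 99)


class TestLEAS:
    def _held_out_auc(self, pair, factors, class_c, seed=0):
        s = alloc.extract_expansion_samples(*pair, factors, class_c,
                                            sampling_rate=0.3, seed=seed)
        Xtr, Xte, ytr, yte = train_test_split(
            s.X, s.y, test_size=0.3, random_state=seed, stratify=s.y)
        clf = RandomForestClassifier(n_estimators=60, random_state=seed,
                                     min_samples_leaf=5, n_jobs=1)
        clf.fit(Xtr, ytr)
        return roc_auc_score(yte, clf.predict_proba(Xte)[:, 1])

    def test_planted_signal_recovered(self, signal_pair, signal_factors):
        """Logit slope 3 on the linked factor gives held-out AUC > 0.8."""
        assert self._held_out_auc(signal_pair, signal_factors, 1) > 0.8

    def test_pure_noise_gives_chance_auc(self, signal_cfg, signal_pair):
        # unsmoothed noise: spatially smoothed noise would act as a
        # location proxy for the clustered change patches
        specs = [FactorSpec(f"n{i}", smooth_sigma=0.0) for i in range(6)]
        cfg = SyntheticConfig(
            grid_rows=signal_cfg.grid_rows, grid_cols=signal_cfg.grid_cols,
            factor_specs=specs, seed=signal_cfg.seed)
        noise = generate_factor_stack(cfg, signal_pair).normalized()
        assert abs(self._held_out_auc(signal_pair, noise, 1) - 0.5) < 0.05

    def test_constant_factor_gives_flat_surface(self, signal_pair):
        g1, _ = signal_pair
        flat = FactorStack({"c": np.full(g1.shape, 3.0)})
        s = alloc.extract_expansion_samples(*signal_pair, flat, 1)
        surface = alloc.fit_leas(s, flat)
        assert np.allclose(surface, surface.ravel()[0])
        assert surface.min() >= 0 and surface.max() <= 1

    def test_too_few_positives_rejected(self, lulc_pair, factor_stack):
        g = lulc_pair[0]
        s = alloc.ExpansionSamples(1, np.zeros((40, 2)),
                                   np.r_[np.ones(10), np.zeros(30)].astype(int),
                                   10, 30)
        with pytest.raises(ValueError):
            alloc.fit_leas(s, factor_stack)

    def test_single_class_samples_rejected(self, factor_stack):
        s = alloc.ExpansionSamples(1, np.zeros((40, 2)),
                                   np.ones(40, int), 40, 0)
        with pytest.raises(ValueError):
            alloc.fit_leas(s, factor_stack)


def _flat_surfaces(shape, classes):
    return {c: np.full(shape, 0.5) for c in classes}


class TestSimulateCA:
    def test_identity_when_demand_met(self, lulc_pair):
        g = lulc_pair[0]
        at = acct.class_areas(g, "a", classes=list(range(1, 7)))
        params = alloc.CAParams(demand=dict(at.areas), patch_seed_prob=0.0)
        out = alloc.simulate_ca(g, _flat_surfaces(g.shape, at.areas), params)
        assert np.array_equal(out.values, g.values)

    def test_demand_shift_met_within_tolerance(self, signal_pair,
                                               signal_factors):
        """Shift 5 % of grassland into cultivated on a 200×200-scale grid."""
        g1, g2 = signal_pair
        surfaces = alloc.suitability_surfaces(g1, g2, signal_factors, seed=0)
        at = acct.class_areas(g1, "a", classes=list(range(1, 7)))
        demand = dict(at.areas)
        shift = 0.05 * demand[3]
        demand[3] -= shift
        demand[1] += shift
        params = alloc.CAParams(demand=demand, tolerance=0.005, seed=1)
        out = alloc.simulate_ca(g1, surfaces, params)
        achieved = acct.class_areas(out, "s", classes=list(range(1, 7)))
        tol = 0.005 * at.total
        for c in demand:
            assert abs(achieved.area(c) - demand[c]) <= tol
        # converted cells were preferentially high-suitability
        converted = (g1.values == 3) & (out.values == 1)
        candidates = (g1.values == 3) & (out.values == 3)
        assert converted.any() and candidates.any()
        assert (surfaces[1][converted].mean()
                > surfaces[1][candidates].mean())

    def test_forbidden_transitions_never_committed(self, lulc_pair):
        g = lulc_pair[0]
        at = acct.class_areas(g, "a", classes=list(range(1, 7)))
        demand = dict(at.areas)
        move = 0.1 * demand[6]
        demand[6] -= move
        demand[3] += move
        perm = np.eye(6, dtype=bool)
        perm[5, 2] = True  # only unused → grassland allowed
        params = alloc.CAParams(demand=demand, permission=perm, seed=2,
                                tolerance=0.005)
        out = alloc.simulate_ca(g, _flat_surfaces(g.shape, demand), params)
        changed = g.values != out.values
        pairs = set(zip(g.values[changed].tolist(), out.values[changed].tolist()))
        assert pairs <= {(6, 3)}

    def test_blocked_demand_raises(self, lulc_pair):
        g = lulc_pair[0]
        at = acct.class_areas(g, "a", classes=list(range(1, 7)))
        demand = dict(at.areas)
        demand[6] -= 50
        demand[1] += 50
        params = alloc.CAParams(demand=demand,
                                permission=np.eye(6, dtype=bool))
        with pytest.raises(alloc.AllocationError, match="class 1"):
            alloc.simulate_ca(g, _flat_surfaces(g.shape, demand), params)

    def test_seed_determinism_and_seed_variation(self, lulc_pair):
        g = lulc_pair[0]
        at = acct.class_areas(g, "a", classes=list(range(1, 7)))
        demand = dict(at.areas)
        move = 0.08 * demand[3]
        demand[3] -= move
        demand[1] += move
        surf = _flat_surfaces(g.shape, demand)
        mk = lambda s: alloc.simulate_ca(
            g, surf, alloc.CAParams(demand=demand, seed=s, tolerance=0.005))
        a, b, c = mk(5), mk(5), mk(6)
        assert np.array_equal(a.values, b.values)
        # different seeds: same class areas, different cell pattern
        for cc in demand:
            assert (a.values == cc).sum() == (c.values == cc).sum()
        assert not np.array_equal(a.values, c.values)

    def test_demand_must_match_grid_total(self, lulc_pair):
        g = lulc_pair[0]
        with pytest.raises(ValueError):
            alloc.demand_to_cells({1: 10.0}, g.cell_area, g.values.size)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            alloc.CAParams(demand={1: 1.0}, delta=1.5)
        with pytest.raises(ValueError):
            alloc.CAParams(demand={1: 1.0}, neighborhood=4)


class TestValidation:
    def test_perfect_simulation(self, lulc_pair):
        g1, g2 = lulc_pair
        rep = alloc.validate(g2, g2, g1)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.overall_accuracy == pytest.approx(1.0)
        assert rep.fom == pytest.approx(1.0)

    def test_no_change_simulated_gives_zero_fom(self, lulc_pair):
        g1, g2 = lulc_pair
        rep = alloc.validate(g1, g2, g1)
        assert rep.fom == 0.0

    def test_hand_computed_confusion_matrix(self):
        kappa, oa = alloc.kappa_oa_from_confusion([[40, 10], [20, 30]])
        assert oa == pytest.approx(0.70)
        assert kappa == pytest.approx(0.40)

    def test_kappa_agrees_with_sklearn(self, rng):
        obs = rng.integers(1, 5, 400)
        sim = np.where(rng.random(400) < 0.7, obs, rng.integers(1, 5, 400))
        base = LULCGrid(np.ones((20, 20), int))
        rep = alloc.validate(LULCGrid(sim.reshape(20, 20)),
                             LULCGrid(obs.reshape(20, 20)), base)
        assert rep.kappa == pytest.approx(cohen_kappa_score(obs, sim))

    def test_fom_recovery_beats_random_baseline(self, signal_pair,
                                                signal_factors):
        """Learned suitability beats flat suitability pairwise over seeds."""
        g1, g2 = signal_pair
        surfaces = alloc.suitability_surfaces(g1, g2, signal_factors, seed=0)
        flat = _flat_surfaces(g1.shape, range(1, 7))
        at2 = acct.class_areas(g2, "b", classes=list(range(1, 7)))
        wins = 0
        for seed in range(5):
            p = alloc.CAParams(demand=dict(at2.areas), seed=seed,
                               tolerance=0.003)
            f_learn = alloc.validate(alloc.simulate_ca(g1, surfaces, p),
                                     g2, g1).fom
            f_rand = alloc.validate(alloc.simulate_ca(g1, flat, p),
                                    g2, g1).fom
            wins += f_learn > f_rand
        assert wins >= 4

    def test_geometry_mismatch_rejected(self, lulc_pair):
        g1, _ = lulc_pair
        with pytest.raises(Exception):
            alloc.validate(g1, LULCGrid(np.ones((3, 3), int)), g1)
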