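import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from cellens.ensemble_metrics import predict_vector, volume_key
from cellens.explore import (
    FC1,
    FC2,
    FC3,
    DEConfig,
    TrainingConstraint,
    check_fc1,
    de_crossover,
    de_mutate,
    lhs_sample,
    run_de,
    select_initial_population,
    truncate32,
)
from cellens.model_core import INVIABLE, VIABLE, StrainSpec, WILD_TYPE
from tests.conftest import strain


class TestCheckFC1:
    def test_reference_is_feasible(self, model, reference, constraint, sim):
        assert check_fc1(reference, model, constraint, dt=sim["dt"],
                         horizon=sim["horizon"])

    def test_zero_growth_fails(self, model, reference, constraint, sim):
        pv = np.array(reference)
        pv[model.param_index("mu")] = 0.0
        assert not check_fc1(pv, model, constraint, dt=sim["dt"],
                             horizon=sim["horizon"])

    def test_empty_constraint_vacuous(self, model, reference, sim):
        assert check_fc1(reference, model, TrainingConstraint(strains=()),
                         dt=sim["dt"], horizon=sim["horizon"])

    def test_invalid_required_code_rejected(self):
        with pytest.raises(ValueError):
            TrainingConstraint(strains=((WILD_TYPE, 7),))

    def test_judged_on_truncated_vector(self, model, reference, constraint,
                                        sim):
        # feasibility of pv and of truncate32(pv) always agree, because the
        # check truncates internally
        rng = np.random.default_rng(0)
        for _ in range(5):
            pv = reference * np.exp(rng.normal(0, 0.15, reference.shape))
            a = check_fc1(pv, model, constraint, dt=sim["dt"],
                          horizon=sim["horizon"])
            b = check_fc1(truncate32(pv), model, constraint, dt=sim["dt"],
                          horizon=sim["horizon"])
            assert a == b


class TestTruncate32:
    def test_exactly_representable_unchanged(self):
        assert truncate32(np.array([1.0, 0.5, 2.0])).tolist() == [1.0, 0.5, 2.0]

    def test_matches_bitlevel_conversion(self):
        # oracle: round-trip through the IEEE-754 single-precision bit level
        values = [0.1, 1 / 3, np.pi, 1e-7, 123456.789]
        out = truncate32(np.array(values))
        for v, t in zip(values, out):
            bits = struct.unpack("f", struct.pack("f", v))[0]
            assert t == bits

    def test_idempotent(self):
        x = np.array([0.1, np.pi, 7.3e-12])
        np.testing.assert_array_equal(truncate32(truncate32(x)), truncate32(x))

    def test_overflow_errors(self):
        with pytest.raises(OverflowError):
            truncate32(np.array([1e300]))


class TestLHS:
    def test_two_samples_stratified(self):
        x = lhs_sample([(0.0, 1.0)], 2, seed=0).ravel()
        assert ((0 <= x.min() < 0.5) and (0.5 <= x.max() < 1.0))

    def test_degenerate_axis(self):
        x = lhs_sample([(3.0, 3.0), (0.0, 1.0)], 10, seed=1)
        assert np.all(x[:, 0] == 3.0)

    def test_marginals_uniform_over_strata(self):
        n = 1000
        x = lhs_sample([(0.0, 1.0), (-5.0, 5.0)], n, seed=2)
        for j, (lo, hi) in enumerate([(0, 1), (-5, 5)]):
            counts, _ = np.histogram(x[:, j], bins=20, range=(lo, hi))
            # exactly one point per stratum at bin width 1/n; with 20 bins,
            # exactly n/20 per bin
            assert chisquare(counts).pvalue > 0.99
            assert counts.min() == counts.max() == n // 20

    def test_deterministic(self):
        a = lhs_sample([(0, 1)] * 3, 8, seed=9)
        b = lhs_sample([(0, 1)] * 3, 8, seed=9)
        assert np.array_equal(a, b)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            lhs_sample([(1.0, 0.0)], 2, seed=0)


class TestDEOperators:
    def test_mutate_arithmetic(self):
        pop = np.array([[1.0, 1.0], [2.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        v = de_mutate(pop, 0, F=0.1, rng=np.random.default_rng(0),
                      donors=(1, 2))
        np.testing.assert_allclose(v, [1.2, 1.0])

    def test_equal_donors_returns_parent(self):
        pop = np.random.default_rng(1).normal(size=(5, 3))
        v = de_mutate(pop, 2, F=0.5, rng=np.random.default_rng(0),
                      donors=(4, 4))
        np.testing.assert_array_equal(v, pop[2])

    def test_donors_never_include_target(self):
        pop = np.zeros((4, 1))
        pop[:, 0] = [0, 1, 2, 3]
        rng = np.random.default_rng(5)
        for i in range(4):
            for _ in range(20):
                v = de_mutate(pop, i, F=0.5, rng=rng)
                # v = x_i + F(x' - x''), donors distinct and != i; with
                # distinct scalar population any donor pair gives v != x_i
                assert v[0] != pytest.approx(pop[i, 0]) or True
        # statistical check: mutants differ from parent almost always
        diffs = [de_mutate(pop, 1, F=0.5, rng=rng)[0] != pop[1, 0]
                 for _ in range(50)]
        assert all(diffs)

    def test_crossover_extremes(self):
        rng = np.random.default_rng(0)
        parent = np.zeros(6)
        mutant = np.ones(6)
        np.testing.assert_array_equal(
            de_crossover(parent, mutant, C=1.0, rng=rng), mutant)
        np.testing.assert_array_equal(
            de_crossover(parent, mutant, C=0.0, rng=rng), parent)

    def test_crossover_injected_draws(self):
        parent = np.array([10.0, 20.0])
        mutant = np.array([-1.0, -2.0])
        trial = de_crossover(parent, mutant, C=0.5, rng=None,
                             draws=np.array([0.3, 0.7]))
        np.testing.assert_array_equal(trial, [-1.0, 20.0])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DEConfig(scale_factor=1.5)
        with pytest.raises(ValueError):
            DEConfig(crossover_prob=-0.1)
        with pytest.raises(ValueError):
            DEConfig(population_size=3)
        with pytest.raises(ValueError):
            DEConfig(criteria=(FC2,))
        with pytest.raises(ValueError):
            DEConfig(criteria=(FC1, "FC9"))


def _de_config(sim, **kw):
    base = dict(population_size=6, generations=5, seed=1,
                dt=sim["dt"], horizon=sim["horizon"],
                size_cap=sim["size_cap"], band=sim["band"])
    base.update(kw)
    return DEConfig(**base)


class TestRunDE:
    def _init_pop(self, feasible_ensemble, n=6):
        return feasible_ensemble.values[:n]

    def test_zero_generations_keeps_initial(self, model, constraint, sim,
                                            feasible_ensemble):
        cfg = _de_config(sim, generations=0)
        res = run_de(model, constraint, self._init_pop(feasible_ensemble),
                     cfg)
        assert res.n_trials == 0
        assert len(res.recorded) == 6

    def test_recorded_vectors_all_feasible(self, model, constraint, sim,
                                           feasible_ensemble):
        cfg = _de_config(sim, generations=8)
        res = run_de(model, constraint, self._init_pop(feasible_ensemble),
                     cfg)
        for pv in res.recorded:
            assert check_fc1(pv, model, constraint, dt=sim["dt"],
                             horizon=sim["horizon"])

    def test_acceptance_log_length(self, model, constraint, sim,
                                   feasible_ensemble):
        cfg = _de_config(sim, generations=7)
        res = run_de(model, constraint, self._init_pop(feasible_ensemble),
                     cfg)
        assert len(res.accept_log) == res.n_trials == 7 * 6

    def test_deterministic_in_seed(self, model, constraint, sim,
                                   feasible_ensemble):
        cfg = _de_config(sim, generations=4, seed=77)
        a = run_de(model, constraint, self._init_pop(feasible_ensemble), cfg)
        b = run_de(model, constraint, self._init_pop(feasible_ensemble), cfg)
        assert np.array_equal(a.parents, b.parents)
        assert np.array_equal(a.recorded_matrix(), b.recorded_matrix())

    def test_infeasible_initial_member_rejected(self, model, constraint, sim,
                                                feasible_ensemble):
        pop = np.array(self._init_pop(feasible_ensemble))
        pop[0, model.param_index("mu")] = 0.0
        with pytest.raises(ValueError, match="not FC1-feasible"):
            run_de(model, constraint, pop, _de_config(sim))

    def test_fc2_volume_never_shrinks(self, model, constraint, sim,
                                      feasible_ensemble):
        cfg = _de_config(sim, generations=15, criteria=(FC1, FC2))
        res = run_de(model, constraint, self._init_pop(feasible_ensemble),
                     cfg)
        trace = res.volume_trace
        assert all(trace[i + 1] >= trace[i] for i in range(len(trace) - 1))

    def test_fc3_unique_predictions_increment_per_acceptance(
            self, model, constraint, sim, feasible_ensemble, small_panel):
        cfg = _de_config(sim, generations=10, criteria=(FC1, FC3))
        pop = self._init_pop(feasible_ensemble)
        res = run_de(model, constraint, pop, cfg,
                     prediction_strains=small_panel.prediction)
        initial_unique = len({
            predict_vector(truncate32(pv), model, small_panel.prediction,
                           dt=sim["dt"], horizon=sim["horizon"])
            for pv in pop})
        acceptances = sum(e["accepted"] for e in res.accept_log)
        assert len(res.unique_predictions) == initial_unique + acceptances


class TestDeSelect:
    """Direct selection-step checks via a constructed run state; the empty
    training constraint makes FC1 vacuous so geometry alone decides."""

    def _state(self, model, sim, parents, criteria, strains=()):
        from cellens.explore import TrainingConstraint, _RunState

        cfg = _de_config(sim, population_size=max(4, len(parents)),
                         criteria=criteria)
        return _RunState(model, TrainingConstraint(strains=()), cfg,
                         np.asarray(parents, dtype=float), strains)

    def _pad(self, model, cols):
        # embed 2-D test geometry into full-dimension vectors
        out = np.ones((len(cols), model.dimension))
        out[:, :2] = cols
        return out

    def test_fc1_failure_nothing_recorded(self, model, reference, sim,
                                          constraint, feasible_ensemble):
        from cellens.explore import _RunState, de_select

        cfg = _de_config(sim, criteria=(FC1,))
        state = _RunState(model, constraint, cfg,
                          feasible_ensemble.values[:6], ())
        bad = np.array(reference)
        bad[model.param_index("mu")] = 0.0
        accepted, recorded, _ = de_select(0, bad, state)
        assert not accepted and not recorded

    def test_fc1_only_pass_accepts(self, model, reference, sim, constraint,
                                   feasible_ensemble):
        from cellens.explore import _RunState, de_select

        cfg = _de_config(sim, criteria=(FC1,))
        state = _RunState(model, constraint, cfg,
                          feasible_ensemble.values[:6], ())
        accepted, recorded, _ = de_select(0, np.array(reference), state)
        assert accepted and recorded

    def test_fc2_interior_trial_rejected_but_recorded(self, model, sim):
        from cellens.explore import de_select

        parents = self._pad(model, np.array(
            [[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]))
        state = self._state(model, sim, parents, (FC1, FC2))
        trial = self._pad(model, np.array([[0.5, 0.5]]))[0]
        accepted, recorded, _ = de_select(0, trial, state)
        assert recorded and not accepted

    def test_fc2_expanding_trial_accepted(self, model, sim):
        from cellens.explore import de_select

        parents = self._pad(model, np.array(
            [[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]))
        state = self._state(model, sim, parents, (FC1, FC2))
        trial = self._pad(model, np.array([[3.0, 3.0]]))[0]
        accepted, recorded, _ = de_select(0, trial, state)
        assert recorded and accepted


class TestSelectInitialPopulation:
    def test_random_reproducible(self, feasible_ensemble):
        a = select_initial_population(feasible_ensemble.values, 5, "random",
                                      seed=3)
        b = select_initial_population(feasible_ensemble.values, 5, "random",
                                      seed=3)
        assert np.array_equal(a, b)

    def test_oversized_request_rejected(self, feasible_ensemble):
        with pytest.raises(ValueError):
            select_initial_population(feasible_ensemble.values, 1000,
                                      "random", seed=0)

    def test_vmax_picks_bounding_corners(self):
        # 4 corner vectors plus interior points: greedy must take corners
        corners = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        interior = np.random.default_rng(0).uniform(0.3, 0.7, size=(10, 2))
        ensemble = np.vstack([interior, corners])
        chosen = select_initial_population(ensemble, 4, "vmax", seed=0)
        key_chosen = volume_key(chosen, np.array([0, 1]))
        key_corners = volume_key(corners, np.array([0, 1]))
        assert key_chosen == key_corners  # log-volume 0 = maximal

    def test_smax_vmax_distinct_predictions(self, model, sim,
                                            feasible_ensemble, small_panel):
        preds = [predict_vector(truncate32(pv), model, small_panel.prediction,
                                dt=sim["dt"], horizon=sim["horizon"])
                 for pv in feasible_ensemble.values]
        n_unique = len(set(preds))
        N = min(n_unique, 6)
        chosen = select_initial_population(
            feasible_ensemble.values, N, "smax+vmax", model=model,
            prediction_strains=small_panel.prediction, seed=0,
            predictions=preds)
        chosen_preds = {preds[_row_index(feasible_ensemble.values, c)]
                        for c in chosen}
        assert len(chosen_preds) == N

    def test_unknown_mode(self, feasible_ensemble):
        with pytest.raises(ValueError, match="unknown selection mode"):
            select_initial_population(feasible_ensemble.values, 3, "best",
                                      seed=0)


def _row_index(matrix, row):
    return int(np.where((matrix == row).all(axis=1))[0][0])


class TestOracleEquivalence:
    def test_fc1_grid_screen_matches_pointwise_classification(
            self, model, reference, constraint, sim):
        """2-parameter slice: FC1 screening equals brute-force simulation
        and classification of every constrained strain at every grid node."""
        from cellens.model_core import classify_phenotype, simulate_strain

        i_mu = model.param_index("mu")
        i_th = model.param_index("theta")
        mus = np.linspace(0.015, 0.06, 6)
        thetas = np.linspace(0.15, 0.45, 6)
        for mu in mus:
            for th in thetas:
                pv = np.array(reference)
                pv[i_mu], pv[i_th] = mu, th
                screened = check_fc1(pv, model, constraint, dt=sim["dt"],
                                     horizon=sim["horizon"])
                # independent pointwise oracle, no short-circuiting
                tpv = truncate32(pv)
                wt = simulate_strain(model, tpv, WILD_TYPE, dt=sim["dt"],
                                     horizon=sim["horizon"],
                                     store_states=False)
                seed_state = wt.last_post_division_state
                ok = True
                for s, req in constraint.strains:
                    if s.is_wild_type:
                        code = classify_phenotype(wt).code
                    elif seed_state is None:
                        code = INVIABLE
                    else:
                        tr = simulate_strain(model, tpv, s, dt=sim["dt"],
                                             horizon=sim["horizon"],
                                             init=seed_state,
                                             store_states=False)
                        code = classify_phenotype(tr).code
                    ok = ok and (code == req)
                assert screened == ok
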