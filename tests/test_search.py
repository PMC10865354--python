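"""Grid search, range refinement, beam search and early stopping."""

import numpy as np
import pytest

from screenopt.dag import Parameterization
from screenopt.search import (
    BeamState,
    NumericRange,
    SearchSpace,
    SpherePerturbationSpec,
    beam_search,
    early_stop,
    grid_search,
    refine_ranges,
)
from screenopt.spheres import perturb_spheres


def quadratic_evaluate(optimum):
    """Noiseless criterion peaking at the hidden optimum."""

    def evaluate(p: Parameterization) -> float:
        sq = sum((float(p.bindings[k]) - v) ** 2 for k, v in optimum.items())
        return float(np.exp(-sq))

    return evaluate


def space2d(n=10, lo=0.0, hi=1.0, **kwargs):
    return SearchSpace(
        numeric={"a": NumericRange(lo, hi, n), "b": NumericRange(lo, hi, n)}, **kwargs
    )


class TestGridSearch:
    def test_ten_by_ten_is_hundred_evaluations(self):
        history = []
        ranked = grid_search(space2d(10), quadratic_evaluate({"a": 0.5, "b": 0.5}),
                             history=history)
        assert len(history) == 100
        assert len(ranked) == 100

    def test_single_point_pool(self):
        space = SearchSpace(numeric={"a": NumericRange(1.0, 1.0, 1)})
        ranked = grid_search(space, lambda p: 0.7)
        assert len(ranked) == 1 and ranked[0][1] == 0.7

    def test_noiseless_argmax_is_nearest_pool_point(self):
        optimum = {"a": 0.533, "b": 0.21}
        space = space2d(11)
        ranked = grid_search(space, quadratic_evaluate(optimum))
        best = ranked[0][0]
        for k, pool in (("a", space.numeric["a"].pool()), ("b", space.numeric["b"].pool())):
            nearest = pool[np.argmin(np.abs(pool - optimum[k]))]
            assert best.bindings[k] == pytest.approx(nearest)

    def test_failures_recorded_and_excluded(self):
        def evaluate(p):
            if p.bindings["a"] < 0.5:
                raise RuntimeError("dock crashed")
            return p.bindings["a"]

        history = []
        ranked = grid_search(SearchSpace(numeric={"a": NumericRange(0, 1, 4)}),
                             evaluate, history=history)
        assert len(history) == 4
        assert sum(not r.ok for r in history) == 2
        assert len(ranked) == 2
        assert all("failed" in r.status for r in history if not r.ok)

    def test_ranking_sorted_descending_with_id_tiebreak(self):
        history = []
        ranked = grid_search(SearchSpace(numeric={"a": NumericRange(0, 1, 5)}),
                             lambda p: 1.0, history=history)
        assert [v for _, v in ranked] == [1.0] * 5
        assert [p.id for p, _ in ranked] == sorted(p.id for p, _ in ranked)


class TestRefineRanges:
    def _state(self, best_value, low=0.0, high=1.0, n=5):
        best = Parameterization(bindings={"a": best_value})
        rng = {"a": NumericRange(low, high, n)}
        return BeamState(step_index=0, retained=[(best, 1.0)], ranges=rng, original=rng)

    def test_width_halves_around_best(self):
        refined = refine_ranges(self._state(0.5), zoom_factor=2.0)["a"]
        assert refined.high - refined.low == pytest.approx(0.5)
        assert (refined.low + refined.high) / 2 == pytest.approx(0.5)
        assert refined.n_points == 5

    def test_edge_best_clipped_to_original_bounds(self):
        refined = refine_ranges(self._state(1.0), zoom_factor=2.0)["a"]
        assert refined.high == 1.0
        assert refined.low == pytest.approx(0.75)
        assert refined.low <= 1.0 <= refined.high

    def test_two_rounds_shrink_distance_to_optimum_monotonically(self):
        optimum = {"a": 0.637, "b": 0.192}
        evaluate = quadratic_evaluate(optimum)
        space = space2d(5)
        distances = []
        current = space
        for _ in range(3):
            ranked = grid_search(current, evaluate)
            best = ranked[0][0]
            distances.append(
                max(abs(best.bindings[k] - optimum[k]) for k in optimum)
            )
            state = BeamState(step_index=0, retained=ranked[:1],
                              ranges=dict(current.numeric), original=dict(space.numeric))
            current = SearchSpace(numeric=refine_ranges(state, 2.0))
        assert distances[0] >= distances[1] >= distances[2]
        assert distances[2] < distances[0]


class TestEarlyStop:
    def test_strictly_improving_never_stops(self):
        assert early_stop([0.1, 0.2, 0.3, 0.4], patience=2, min_delta=0.05) is False

    def test_flat_history_patience_one(self):
        assert early_stop([0.3, 0.3], patience=1) is True

    def test_hand_traced_rule(self):
        assert early_stop([0.10, 0.101, 0.101], patience=2, min_delta=0.005) is True
        assert early_stop([0.10, 0.101, 0.2], patience=2, min_delta=0.005) is False


class TestBeamSearch:
    def test_single_step_equals_grid_plus_first_perturbation_round(self, sphere_set):
        space = space2d(3, base_spheres=sphere_set,
                        perturbation=SpherePerturbationSpec(radius=0.2,
                                                            counts_per_step=(4,)))
        evaluate = quadratic_evaluate({"a": 0.5, "b": 0.5})
        ranked, history = beam_search(space, evaluate, n_steps=1, seed=0)
        # 9 grid points x (base + 4 perturbed sphere sets)
        assert len(history) == 9 * 5
        assert all(r.step == 0 for r in history)

    def test_default_perturbation_counts_start_10_end_50(self):
        spec = SpherePerturbationSpec()
        assert spec.count_at(0) == 10
        assert spec.counts_per_step[-1] == 50
        assert spec.radius == 0.4

    def test_budget_accounting_no_duplicate_evaluations(self, sphere_set):
        space = space2d(3, base_spheres=sphere_set,
                        perturbation=SpherePerturbationSpec(radius=0.2,
                                                            counts_per_step=(2, 2)))
        ranked, history = beam_search(space, quadratic_evaluate({"a": 0.4, "b": 0.6}),
                                      n_steps=3, top_fraction=0.3, max_beam_width=3,
                                      seed=1)
        ids = [r.parameterization.id for r in history]
        assert len(ids) == len(set(ids))
        assert len(ranked) == sum(r.ok for r in history)

    def test_beam_beats_or_matches_grid_noiseless(self):
        optimum = {"a": 0.713, "b": 0.377}
        evaluate = quadratic_evaluate(optimum)
        ranked_beam, history = beam_search(space2d(4), evaluate, n_steps=3,
                                           top_fraction=0.25, seed=0)
        n_side = int(np.floor(np.sqrt(len(history))))
        ranked_grid = grid_search(space2d(n_side), evaluate)
        assert ranked_beam[0][1] >= ranked_grid[0][1]

    def test_all_failing_aborts_with_diagnostic(self):
        def evaluate(p):
            raise RuntimeError("backend down")

        with pytest.raises(RuntimeError, match="all candidates failed"):
            beam_search(space2d(2), evaluate, n_steps=2, seed=0)

    def test_early_stopping_halts_before_n_steps(self):
        ranked, history = beam_search(
            space2d(3), lambda p: 0.5, n_steps=5,
            early_stopping={"patience": 1, "min_delta": 0.01}, seed=0,
        )
        assert max(r.step for r in history) < 4

    def test_perturbed_candidates_inherit_parent_bindings(self, sphere_set):
        space = space2d(3, base_spheres=sphere_set,
                        perturbation=SpherePerturbationSpec(radius=0.3,
                                                            counts_per_step=(2, 3)))
        _, history = beam_search(space, quadratic_evaluate({"a": 0.5, "b": 0.5}),
                                 n_steps=2, max_beam_width=2, seed=3)
        step1 = [r for r in history if r.step == 1]
        assert step1  # refinement round happened
        perturbed = [r for r in step1 if "perturb" in r.parameterization.sphere_provenance]
        assert perturbed


class TestStepSequences:
    def test_nesting_depth_limited_to_three(self):
        from screenopt.search import flatten_sequence

        deep = {"sequence": [{"sequence": [{"sequence": [{"n_steps": 1}]}]}]}
        with pytest.raises(ValueError, match="depth"):
            flatten_sequence([deep])
        ok = [{"sequence": [{"sequence": [{"n_steps": 1}]}]}]
        assert flatten_sequence(ok) == [{"n_steps": 1}]

    def test_iterate_repeats_child_phases(self):
        from screenopt.search import flatten_sequence

        seq = [{"sequence": [{"n_steps": 1}, {"n_steps": 2}], "iterate": 2}]
        assert flatten_sequence(seq) == [{"n_steps": 1}, {"n_steps": 2}] * 2

    def test_sequence_runs_phases_with_distinct_criteria(self):
        from screenopt.search import run_sequence

        optimum = {"a": 0.61, "b": 0.37}
        used = []

        def make_evaluate(criterion_name):
            used.append(criterion_name)
            return quadratic_evaluate(optimum)

        ranked, history = run_sequence(
            space2d(3),
            make_evaluate,
            [{"n_steps": 1, "criterion": "logauc"},
             {"n_steps": 2, "criterion": "normalized_logauc"}],
            seed=0,
        )
        assert used == ["logauc", "normalized_logauc"]
        ids = [r.parameterization.id for r in history]
        assert len(ids) == len(set(ids))
        # later phases refine: steps are phase-global and increase
        assert max(r.step for r in history) >= 1
        # second phase explores a narrower neighborhood around the optimum
        assert max(abs(ranked[0][0].bindings[k] - optimum[k]) for k in optimum) <= 0.25

    def test_pipeline_accepts_sequence_config(self, tmp_path):
        from screenopt.dataset import generate_dataset
        from screenopt.pipeline import run_pipeline

        ds = generate_dataset(n_pos=6, ratio=8, n_clusters=2, seed=2)
        cfg = {
            "seed": 2,
            "parameters": {
                "electrostatic_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 3},
                "desolvation_thin_sphere_radius": {"low": 0.1, "high": 1.9, "n": 3},
            },
            "matching_spheres_perturbation": {"radius": 0.4, "counts_per_step": [2]},
            "search": {"sequence": [{"n_steps": 1}, {"n_steps": 1}]},
            "significance": {"null_reps": 500, "p_value": 0.05},
        }
        result = run_pipeline(cfg, ds, tmp_path / "seq")
        assert result.results["id"].is_unique
        assert result.results["step"].max() >= 1
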