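import math

import numpy as np
import pytest

from moscreen import (ObjectiveSpec, PrecomputedOracle, ScreenConfig,
                      TransformSpec, cluster_initialize, library_from_arrays,
                      load_checkpoint, run_screen)
from moscreen.engine import _allocate_proportional


def two_blob_library(n=200, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    emb = np.vstack([rng.normal(loc=-10, size=(half, 2)),
                     rng.normal(loc=+10, size=(n - half, 2))])
    return library_from_arrays([f"m{i}" for i in range(n)], emb)


class TestClusterInitialize:
    def test_single_cluster_is_uniform_sample(self):
        lib = two_blob_library()
        idx = cluster_initialize(lib, n_clusters=1, n_init=20, seed=1)
        assert len(idx) == 20
        assert len(set(idx.tolist())) == 20

    def test_exhaustive_sample_returns_every_index(self):
        lib = two_blob_library(n=50)
        idx = cluster_initialize(lib, n_clusters=5, n_init=50, seed=1)
        np.testing.assert_array_equal(np.sort(idx), np.arange(50))

    def test_oversized_request_rejected(self):
        lib = two_blob_library(n=50)
        with pytest.raises(ValueError, match="exceeds library size"):
            cluster_initialize(lib, 2, 51, seed=0)

    def test_both_blobs_represented_in_every_seeded_repetition(self):
        lib = two_blob_library(n=120)
        for seed in range(50):
            idx = cluster_initialize(lib, n_clusters=2, n_init=10, seed=seed)
            assert np.any(idx < 60) and np.any(idx >= 60)

    def test_deterministic_given_seed(self):
        lib = two_blob_library()
        a = cluster_initialize(lib, 4, 30, seed=42)
        b = cluster_initialize(lib, 4, 30, seed=42)
        np.testing.assert_array_equal(a, b)


class TestProportionalAllocation:
    def test_sums_and_minimums(self):
        alloc = _allocate_proportional(np.array([70, 20, 10]), 10)
        assert alloc.sum() == 10
        assert np.all(alloc >= 1)
        assert alloc[0] > alloc[2]

    def test_respects_cluster_capacity(self):
        alloc = _allocate_proportional(np.array([2, 98]), 50)
        assert alloc.sum() == 50
        assert alloc[0] <= 2

    def test_fewer_draws_than_clusters_favours_largest(self):
        alloc = _allocate_proportional(np.array([5, 50, 20]), 2)
        assert alloc.tolist() == [0, 1, 1]

    def test_empty_clusters_get_nothing(self):
        alloc = _allocate_proportional(np.array([10, 0, 10]), 4)
        assert alloc[1] == 0
        assert alloc.sum() == 4


class CountingOracle:
    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)
        self.calls = 0
        self.seen = []

    def __call__(self, indices):
        indices = np.asarray(indices, dtype=int)
        self.calls += len(indices)
        self.seen.extend(indices.tolist())
        return self.values[indices]


def make_objectives(benchmark, oracle_cls=PrecomputedOracle):
    out = []
    for obj in benchmark.objectives:
        out.append(ObjectiveSpec(obj.name, oracle_cls(benchmark.values[obj.name]),
                                 obj.transform, obj.desirable_range))
    return out


class TestRunScreen:
    def test_budget_contract_and_no_repeats(self, small_benchmark):
        objectives = make_objectives(small_benchmark, CountingOracle)
        config = ScreenConfig(budget_fraction=0.1, seed=3)
        result = run_screen(small_benchmark.library, config, objectives)
        budget = math.ceil(0.1 * len(small_benchmark.library))
        assert len(result.evaluated_indices) == budget
        assert len(set(result.evaluated_indices.tolist())) == budget
        for obj in objectives:
            assert obj.oracle.calls == budget
            assert sorted(obj.oracle.seen) == sorted(
                result.evaluated_indices.tolist())

    def test_deterministic_given_seed(self, small_benchmark):
        config = ScreenConfig(budget_fraction=0.1, seed=9)
        a = run_screen(small_benchmark.library, config,
                       make_objectives(small_benchmark))
        b = run_screen(small_benchmark.library, config,
                       make_objectives(small_benchmark))
        np.testing.assert_array_equal(a.evaluated_indices, b.evaluated_indices)

    def test_full_budget_evaluates_everything(self):
        rng = np.random.default_rng(0)
        lib = library_from_arrays([f"m{i}" for i in range(120)],
                                  rng.normal(size=(120, 3)))
        vals = rng.normal(size=120)
        objectives = [ObjectiveSpec("affinity", PrecomputedOracle(vals),
                                    TransformSpec("negate"))]
        result = run_screen(lib, ScreenConfig(budget_fraction=1.0, seed=0),
                            objectives)
        np.testing.assert_array_equal(np.sort(result.evaluated_indices),
                                      np.arange(120))

    def test_budget_equal_to_seed_sample_skips_iterations(self, small_benchmark):
        config = ScreenConfig(budget_fraction=0.1,
                              init_fraction_of_budget=1.0, seed=5)
        result = run_screen(small_benchmark.library, config,
                            make_objectives(small_benchmark))
        budget = math.ceil(0.1 * len(small_benchmark.library))
        expected = cluster_initialize(small_benchmark.library,
                                      min(config.n_clusters, budget),
                                      budget, seed=5)
        np.testing.assert_array_equal(result.evaluated_indices, expected)
        assert result.trace == []

    def test_observations_aligned_with_raw_and_transform(self, small_benchmark):
        result = run_screen(small_benchmark.library,
                            ScreenConfig(budget_fraction=0.1, seed=1),
                            make_objectives(small_benchmark))
        for obj in small_benchmark.objectives:
            raw = small_benchmark.values[obj.name][result.evaluated_indices]
            np.testing.assert_array_equal(
                result.observations[obj.name]["raw"], raw)

    def test_oracle_failures_not_charged_to_budget(self, small_benchmark):
        bad = {3, 4, 5, 6, 7}

        class FailingOracle(PrecomputedOracle):
            def __call__(self, indices):
                out = super().__call__(indices).copy()
                out[np.isin(indices, list(bad))] = np.nan
                return out

        objectives = make_objectives(small_benchmark, FailingOracle)
        config = ScreenConfig(budget_fraction=0.1, seed=2)
        result = run_screen(small_benchmark.library, config, objectives)
        budget = math.ceil(0.1 * len(small_benchmark.library))
        assert len(result.evaluated_indices) == budget
        assert not set(result.evaluated_indices.tolist()) & bad

    def test_infeasible_budget_rejected(self, small_benchmark):
        with pytest.raises(ValueError, match="too small"):
            run_screen(small_benchmark.library,
                       ScreenConfig(budget_fraction=0.004, seed=0),
                       make_objectives(small_benchmark))


class TestCheckpointResume:
    def test_interrupted_run_resumes_identically(self, small_benchmark,
                                                 tmp_path):
        ckpt = tmp_path / "state.json"
        limit = 45  # fail partway through the acquisition phase

        class Flaky(PrecomputedOracle):
            budget_used = 0
            armed = True

            def __call__(self, indices):
                if Flaky.armed:
                    Flaky.budget_used += len(indices)
                    if Flaky.budget_used > limit:
                        raise RuntimeError("oracle crashed")
                return super().__call__(indices)

        config = ScreenConfig(budget_fraction=0.2, seed=7,
                              checkpoint_path=str(ckpt))
        objectives = make_objectives(small_benchmark, Flaky)
        with pytest.raises(RuntimeError, match="oracle crashed"):
            run_screen(small_benchmark.library, config, objectives)
        assert ckpt.exists()
        state = load_checkpoint(ckpt, expected_seed=7)
        assert 0 < len(state.evaluated) < math.ceil(
            0.2 * len(small_benchmark.library))

        Flaky.armed = False
        resumed = run_screen(small_benchmark.library, config, objectives,
                             resume_from=ckpt)
        clean = run_screen(small_benchmark.library,
                           ScreenConfig(budget_fraction=0.2, seed=7),
                           make_objectives(small_benchmark))
        np.testing.assert_array_equal(resumed.evaluated_indices,
                                      clean.evaluated_indices)

    def test_checkpoint_seed_mismatch_rejected(self, small_benchmark,
                                               tmp_path):
        ckpt = tmp_path / "state.json"
        config = ScreenConfig(budget_fraction=0.1, seed=1,
                              checkpoint_path=str(ckpt))
        run_screen(small_benchmark.library, config,
                   make_objectives(small_benchmark))
        with pytest.raises(ValueError, match="seed"):
            load_checkpoint(ckpt, expected_seed=2)
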