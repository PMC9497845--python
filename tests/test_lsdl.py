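import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsdl_spectra.errors import (
    DegenerateInputError,
    SearchFailureError,
    ValidationError,
)
from lsdl_spectra.features import FeatureConfig
from lsdl_spectra.lsdl import (
    LSDLModel,
    ThresholdScheme,
    apply_model,
    decompose,
    performance_index,
    threshold_search,
)
from lsdl_spectra.spectra_io import SpectraDataset


# ---------------------------------------------------------------------------
# independent oracle: the index chain written out in plain loops
# ---------------------------------------------------------------------------
def brute_force_j(A, B):
    rows = [list(map(float, r)) for r in A] + [list(map(float, r)) for r in B]
    n, p = len(rows), len(rows[0])
    means = [sum(r[w] for r in rows) / n for w in range(p)]
    sds = [
        math.sqrt(sum((r[w] - means[w]) ** 2 for r in rows) / (n - 1))
        for w in range(p)
    ]
    za = [[(r[w] - means[w]) / sds[w] for w in range(p)] for r in map(list, A)]
    zb = [[(r[w] - means[w]) / sds[w] for w in range(p)] for r in map(list, B)]
    cen_a = [sum(r[w] for r in za) / len(za) for w in range(p)]
    cen_b = [sum(r[w] for r in zb) / len(zb) for w in range(p)]
    ed = math.sqrt(sum((cen_a[w] - cen_b[w]) ** 2 for w in range(p)))
    pooled = za + zb
    zmeans = [sum(r[w] for r in pooled) / n for w in range(p)]
    zsds = [
        math.sqrt(sum((r[w] - zmeans[w]) ** 2 for r in pooled) / (n - 1))
        for w in range(p)
    ]
    sigma_m = sum(zsds) / p
    return ed / sigma_m


class TestDecompose:
    def test_upper_threshold(self):
        sub = decompose(np.array([0.5, 2.2, 1.0, 3.0]), ThresholdScheme("upper", 2.0))
        np.testing.assert_array_equal(sub.retained, [2.2, 3.0])
        assert sub.retained_count == 2

    def test_lower_at_max_is_identity(self, make_spectrum, rng):
        s = make_spectrum(rng.uniform(0, 1, 113))
        sub = decompose(s, ThresholdScheme("lower", float(s.intensities.max())))
        np.testing.assert_array_equal(sub.retained, s.intensities)

    def test_upper_above_max_is_empty(self, make_spectrum):
        s = make_spectrum()
        sub = decompose(s, ThresholdScheme("upper", float(s.intensities.max()) + 1))
        assert sub.retained_count == 0

    def test_order_preserved(self):
        x = np.array([3.0, 0.1, 2.5, 0.2, 2.7])
        sub = decompose(x, ThresholdScheme("upper", 2.0))
        np.testing.assert_array_equal(sub.retained, [3.0, 2.5, 2.7])

    def test_bad_direction_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdScheme("sideways", 1.0)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=8, max_size=40),
        st.floats(-4, 4, allow_nan=False),
        st.floats(0.1, 2.0, allow_nan=False),
    )
    def test_nesting_monotonicity(self, xs, t1, dt):
        x = np.asarray(xs)
        t2 = t1 + dt
        hi = decompose(x, ThresholdScheme("upper", t2)).retained
        lo = decompose(x, ThresholdScheme("upper", t1)).retained
        # retained(t2) is a subsequence of retained(t1)
        assert set(hi.tolist()) <= set(lo.tolist())
        assert len(hi) <= len(lo)
        # dual for lower thresholds
        lo_small = decompose(x, ThresholdScheme("lower", t1)).retained
        lo_big = decompose(x, ThresholdScheme("lower", t2)).retained
        assert len(lo_small) <= len(lo_big)


class TestPerformanceIndex:
    def test_identical_classes_zero(self, rng):
        F = rng.standard_normal((4, 3))
        stats = performance_index(F, F)
        assert stats.ed == pytest.approx(0.0, abs=1e-12)
        assert stats.j == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_hand_value(self):
        # A = {0,0}, B = {2,2}: pooled sd (n-1) = 1.1547, standardized
        # centroids +-0.8660 -> ED = 1.7321, sigma_m = 1
        A = np.array([[0.0], [0.0]])
        B = np.array([[2.0], [2.0]])
        stats = performance_index(A, B)
        assert stats.sigma_m == pytest.approx(1.0)
        assert stats.j == pytest.approx(math.sqrt(3), abs=1e-9)

    def test_scaling_invariance(self, rng):
        A = rng.standard_normal((5, 4))
        B = rng.standard_normal((6, 4)) + 1.0
        j1 = performance_index(A, B).j
        j2 = performance_index(A * 5.0, B * 5.0).j
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(2, 8, size=2)
            p = int(rng.integers(1, 6))
            A = rng.standard_normal((na, p))
            B = rng.standard_normal((nb, p)) + rng.uniform(-1, 1)
            got = performance_index(A, B).j
            want = brute_force_j(A, B)
            assert got == pytest.approx(want, abs=1e-10)

    def test_constant_feature_degenerate(self):
        A = np.array([[1.0, 5.0], [1.0, 6.0]])
        B = np.array([[1.0, 9.0], [1.0, 7.0]])
        with pytest.raises(DegenerateInputError):
            performance_index(A, B)

    def test_single_sample_class_rejected(self):
        with pytest.raises(ValidationError):
            performance_index(np.zeros((1, 2)), np.ones((3, 2)))


class TestThresholdSearch:
    def test_two_classes_required(self, make_spectrum):
        ds = SpectraDataset(
            [make_spectrum(sample_id=f"s{i}", label="cancer") for i in range(6)],
            name="one-class",
        )
        with pytest.raises(ValidationError):
            threshold_search(ds)

    def test_level_above_max_recorded_na(self, labeled_dataset):
        model = threshold_search(
            labeled_dataset, n_iterations=1, levels_per_iteration=8, min_samples=8
        )
        top = max(c.level for c in model.candidates if c.direction == "upper")
        top_cand = [
            c for c in model.candidates
            if c.direction == "upper" and c.level == top
        ][0]
        # the topmost grid level equals the pooled max: at most one sample
        assert not top_cand.feasible
        assert "insufficient samples" in top_cand.reason

    def test_all_candidates_na_raises(self, labeled_dataset):
        with pytest.raises(SearchFailureError, match="min_samples|samples"):
            threshold_search(labeled_dataset, min_samples=10_000)

    def test_search_table_shape(self, labeled_dataset):
        model = threshold_search(labeled_dataset, n_iterations=3,
                                 levels_per_iteration=6)
        table = model.search_table()
        assert set(table) == {"upper", "lower"}
        for rows in table.values():
            assert [r["iteration"] for r in rows] == [1, 2, 3]

    def test_scheme_is_argmax_of_feasible(self, labeled_dataset):
        model = threshold_search(labeled_dataset, n_iterations=2,
                                 levels_per_iteration=8)
        best_j = max(c.j for c in model.candidates if c.feasible)
        chosen = [
            c for c in model.candidates
            if c.feasible and c.direction == model.scheme.direction
            and c.level == model.scheme.level
        ]
        assert chosen and chosen[0].j == best_j

    def test_model_round_trip(self, labeled_dataset, tmp_path):
        model = threshold_search(labeled_dataset, n_iterations=2,
                                 levels_per_iteration=6)
        path = tmp_path / "model.json"
        model.save(path)
        back = LSDLModel.load(path)
        assert back.scheme == model.scheme
        assert back.min_samples == model.min_samples


class TestApplyModel:
    def _model(self, scheme, min_samples=8):
        return LSDLModel(
            scheme=scheme,
            candidates=[],
            min_samples=min_samples,
            feature_config_id=FeatureConfig(reduced_after_lsdl=True).config_id,
        )

    def test_lower_at_max_identity(self, labeled_dataset):
        level = float(labeled_dataset.intensity_matrix().max())
        subs = apply_model(self._model(ThresholdScheme("lower", level)), labeled_dataset)
        for s, sub in zip(labeled_dataset, subs):
            np.testing.assert_array_equal(sub.retained, s.intensities)

    def test_training_counts_reproduced(self, labeled_dataset):
        model = threshold_search(labeled_dataset, n_iterations=2,
                                 levels_per_iteration=8)
        counts = [
            decompose(s, model.scheme).retained_count for s in labeled_dataset
        ]
        subs = apply_model(model, labeled_dataset)
        assert [s.retained_count for s in subs] == counts

    def test_empty_dataset(self, small_grid):
        ds = SpectraDataset([], name="empty", _grid=small_grid)
        assert apply_model(self._model(ThresholdScheme("upper", 1.0)), ds) == []

    def test_under_min_flagged(self, labeled_dataset):
        level = float(labeled_dataset.intensity_matrix().max()) - 1e-9
        subs = apply_model(self._model(ThresholdScheme("upper", level)), labeled_dataset)
        assert all(not s.meets_min for s in subs)


class TestSearchComputationalCost:
    def test_linear_scaling_in_sample_count(self, small_grid, rng):
        import time

        from lsdl_spectra.spectra_io import Spectrum

        def build(n):
            spectra = []
            for i in range(n):
                y = 0.5 + 0.1 * rng.standard_normal(len(small_grid))
                y += (1.5 if i % 2 else 1.0) * np.exp(
                    -0.5 * ((small_grid - 1400) / 80) ** 2
                )
                spectra.append(
                    Spectrum(f"s{i}", small_grid, np.clip(y, 0, None),
                             label="cancer" if i % 2 else "noncancer")
                )
            return SpectraDataset(spectra, name=f"n{n}")

        def timed(ds):
            t0 = time.perf_counter()
            threshold_search(ds, n_iterations=2, levels_per_iteration=8)
            return time.perf_counter() - t0

        ds_small, ds_big = build(10), build(20)
        timed(ds_small)  # warm-up
        t_small = min(timed(ds_small) for _ in range(2))
        t_big = min(timed(ds_big) for _ in range(2))
        # doubling n should not much more than double the cost
        assert t_big / t_small < 3.5
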