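"""Grid geometry, expression transform and batch-correction behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ouroboros.preprocess import (BatchCorrector, TransformState,
                                  aggregate_spot, apply_transform,
                                  correct_batches, fit_transform_expression,
                                  grid_partition)


class TestGridPartition:
    def test_hand_enumerated_1024_case(self):
        geo = grid_partition(1024, 1024, 128, 256)
        # 8x8 spot grid; the 64 px context margin removes the border ring
        assert len(geo) == 36
        rows = {g.row for g in geo}
        assert rows == set(range(1, 7))
        g = geo[0]
        sy, sx, sh, sw = g.spot_bounds
        py, px, ph, pw = g.patch_bounds
        assert (sh, sw, ph, pw) == (128, 128, 256, 256)
        # spot centred in patch
        assert sy - py == 64 and sx - px == 64

    def test_all_spots_when_clamping(self):
        geo = grid_partition(1024, 1024, 128, 256, border="clamp")
        assert len(geo) == 64
        assert sum(g.clamped for g in geo) == 64 - 36

    def test_wsi_equal_to_patch(self):
        assert grid_partition(256, 256, 128, 256) == []
        geo = grid_partition(256, 256, 128, 256, border="clamp")
        assert len(geo) == 4

    def test_zero_margin_when_spot_equals_patch(self):
        geo = grid_partition(512, 512, 128, 128)
        assert len(geo) == 16
        assert all(g.spot_bounds == g.patch_bounds for g in geo)

    def test_tiles_disjoint_and_centred(self):
        geo = grid_partition(640, 512, 64, 128)
        seen = set()
        for g in geo:
            sy, sx, sh, sw = g.spot_bounds
            py, px, ph, pw = g.patch_bounds
            assert (sy, sx) not in seen
            seen.add((sy, sx))
            assert 2 * sy + sh == 2 * py + ph and 2 * sx + sw == 2 * px + pw

    def test_tiny_wsi_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="smaller"):
            assert grid_partition(100, 100, 128, 256) == []


class TestAggregateSpot:
    def test_mean_and_identity(self):
        np.testing.assert_allclose(aggregate_spot(np.array([[2.0], [4.0]])), [3.0])
        np.testing.assert_allclose(aggregate_spot(np.array([[5.0, 1.0]])), [5.0, 1.0])

    def test_matches_brute_force_mean(self, rng):
        cells = rng.integers(0, 20, (5, 7)).astype(float)
        expected = [sum(cells[i][j] for i in range(5)) / 5 for j in range(7)]
        np.testing.assert_allclose(aggregate_spot(cells), expected)

    def test_empty_spot_is_zero_vector(self, caplog):
        with caplog.at_level("WARNING"):
            out = aggregate_spot(np.empty((0, 4)), n_markers=4)
        np.testing.assert_array_equal(out, np.zeros(4))
        assert "empty" in caplog.text


class TestTransform:
    def test_single_value_column_with_zero(self):
        e = np.e
        col = np.array([[e], [e], [e], [0.0]])
        z, state = fit_transform_expression(col)
        # sigma falls back to 1; nonzero log values z-score to 0
        np.testing.assert_allclose(z[:3, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(z[3, 0], -np.log(1000.0), atol=1e-10)

    def test_no_zero_column_is_plain_zscore(self, rng):
        x = rng.lognormal(1.0, 0.7, size=(200, 3))
        z, _ = fit_transform_expression(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (12, 4),
                      elements=st.floats(0, 50, allow_nan=False)))
    def test_zeros_map_strictly_below_all_positives(self, x):
        z, state = fit_transform_expression(x)
        for j in range(x.shape[1]):
            zeros = z[x[:, j] == 0, j]
            pos = z[x[:, j] > 0, j]
            if len(zeros) and len(pos):
                assert zeros.max() < pos.min()

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (10, 3),
                      elements=st.floats(0, 100, allow_nan=False)))
    def test_transform_is_strictly_increasing_on_positives(self, x):
        z, _ = fit_transform_expression(x)
        for j in range(3):
            pos = x[:, j] > 0
            order = np.argsort(x[pos, j])
            vals = z[pos, j][order]
            raw = np.sort(x[pos, j])
            keep = np.diff(raw) > 0
            assert (np.diff(vals)[keep] > 0).all()

    def test_apply_reproduces_fit_bit_exactly(self, rng):
        x = rng.poisson(3.0, size=(50, 6)).astype(float)
        z, state = fit_transform_expression(x)
        np.testing.assert_array_equal(apply_transform(x, state), z)

    def test_heldout_zero_uses_training_min_positive(self, rng):
        x = rng.poisson(5.0, size=(50, 2)).astype(float) + 1.0
        _, state = fit_transform_expression(x)
        held = np.array([[0.0, x[0, 1]]])
        z = apply_transform(held, state)
        expected = (np.log(state.min_positive[0] / 1000.0)
                    - state.mu[0]) / state.sigma[0]
        np.testing.assert_allclose(z[0, 0], expected)

    def test_state_json_round_trip(self, tmp_path, rng):
        x = rng.poisson(2.0, size=(30, 4)).astype(float)
        z, state = fit_transform_expression(x, marker_names=list("ABCD"))
        p = tmp_path / "state.json"
        state.to_json(p)
        back = TransformState.from_json(p)
        np.testing.assert_array_equal(apply_transform(x, back), z)

    def test_all_zero_marker_floors_with_warning(self, caplog):
        x = np.array([[0.0, 1.0], [0.0, 2.0]])
        with caplog.at_level("WARNING"):
            z, _ = fit_transform_expression(x)
        assert "zero everywhere" in caplog.text
        assert (z[:, 0] == -10.0).all()

    def test_marker_width_mismatch_raises(self, rng):
        x = rng.poisson(2.0, size=(10, 3)).astype(float)
        _, state = fit_transform_expression(x)
        with pytest.raises(ValueError, match="match"):
            apply_transform(x[:, :2], state)


class TestBatchCorrection:
    def test_single_batch_identity(self, rng):
        x = rng.standard_normal((30, 5))
        np.testing.assert_array_equal(correct_batches(x, ["b1"] * 30), x)

    def test_known_additive_shift_removed(self, rng):
        n, m = 500, 8
        base = rng.standard_normal((2 * n, m))
        shift = np.full(m, 1.0)
        x = base.copy()
        x[n:] += shift
        batches = np.array(["a"] * n + ["b"] * n)
        out = correct_batches(x, batches)
        gap = out[:n].mean(axis=0) - out[n:].mean(axis=0)
        assert np.abs(gap).max() < 0.05

    def test_grand_mean_preserved(self, rng):
        x = rng.standard_normal((200, 6)) + rng.standard_normal(6)
        x[100:] += 0.8
        out = correct_batches(x, ["a"] * 100 + ["b"] * 100)
        np.testing.assert_allclose(out.mean(axis=0), x.mean(axis=0), atol=1e-6)

    def test_idempotent_on_homogeneous_data(self, rng):
        # already-homogeneous batches are left (near-)unchanged; the bound is
        # set by batch-mean sampling noise ~1/sqrt(n), so n is large here
        n = 8000
        x = rng.standard_normal((2 * n, 5))
        out = correct_batches(x, ["a"] * n + ["b"] * n)
        assert np.abs(out - x).max() < 0.05

    def test_zero_variance_marker_falls_back(self, rng):
        x = rng.standard_normal((40, 3))
        x[:20, 0] = 5.0  # flat within batch a
        with pytest.warns(UserWarning, match="zero variance"):
            out = correct_batches(x, ["a"] * 20 + ["b"] * 20)
        assert np.isfinite(out).all()

    def test_fit_apply_split_corrects_unseen_batch(self, rng):
        train = rng.standard_normal((400, 6))
        train[200:] += 0.5
        corr = BatchCorrector().fit(train, ["a"] * 200 + ["b"] * 200)
        new = rng.standard_normal((200, 6)) + 2.0
        out = corr.apply(new, ["c"] * 200)
        # new batch pulled toward the training reference location
        assert np.abs(out.mean(axis=0) - corr.stand_mean).max() < 0.2


def test_simulated_batch_effect_removed_by_correction(small_cohort):
    """A patient classifier works on raw transformed data, drops after correction."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score

    _, dataset, _ = small_cohort
    z, _ = fit_transform_expression(dataset.expression)
    y = dataset.patients.astype(str)
    acc_raw = cross_val_score(LogisticRegression(max_iter=2000), z, y, cv=3).mean()
    zc = correct_batches(z, y)
    acc_corr = cross_val_score(LogisticRegression(max_iter=2000), zc, y, cv=3).mean()
    assert acc_raw > 0.65          # detectable batch signal before correction
    assert acc_corr < acc_raw - 0.1  # substantially reduced after
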