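"""Recurrence-plot constructions against hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mdrqa as M
from conftest import brute_distance_matrix, brute_plot


def phase(points) -> M.PhaseSpace:
    return M.PhaseSpace(np.asarray(points, dtype=float))


class TestDistanceMatrix:
    def test_three_four_five(self):
        P = phase([[0.0, 0.0], [3.0, 4.0]])
        np.testing.assert_allclose(M.distance_matrix(P), [[0, 5], [5, 0]])

    def test_self_diagonal_exactly_zero(self):
        P = phase(np.random.default_rng(0).normal(size=(12, 3)))
        assert (np.diagonal(M.distance_matrix(P)) == 0.0).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(20, 3)), rng.normal(size=(14, 3))
        np.testing.assert_allclose(
            M.distance_matrix(phase(A), phase(B)), brute_distance_matrix(A, B), atol=1e-12
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            M.distance_matrix(phase(np.zeros((3, 2))), phase(np.zeros((3, 3))))


class TestResolveThreshold:
    def test_absolute_passthrough(self):
        assert M.resolve_threshold(np.ones((3, 3)), 0.5, "absolute") == 0.5

    def test_fraction_of_mean(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert M.resolve_threshold(d, 0.1, "meanfrac") == pytest.approx(0.2)

    def test_degenerate_all_zero(self):
        with pytest.raises(ValueError, match="degenerate"):
            M.resolve_threshold(np.zeros((4, 4)), 0.1, "meanfrac")

    def test_lorenz_md_threshold_consistency(self, lorenz):
        # the fraction convention at 0.08 must land the multidimensional
        # plot's recurrence rate within a factor 2 of the reference 0.69%
        rr = lorenz.measures["md"].rr_pct
        assert 0.69 / 2 < rr < 0.69 * 2


class TestRecurrencePlot:
    def test_distance_equal_to_threshold_recurs(self):
        P = phase([[0.0], [1.0]])
        R = M.recurrence_plot(P, 1.0, mode="absolute", theiler=0)
        assert R.M.all()  # Heaviside(0) = 1

    def test_threshold_above_max_distance_gives_all_ones(self):
        P = phase(np.random.default_rng(2).normal(size=(10, 2)))
        R = M.recurrence_plot(P, 100.0, mode="absolute")
        assert R.M.all()

    def test_rr_monotone_in_threshold(self):
        P = phase(np.random.default_rng(3).normal(size=(40, 3)))
        rates = [
            M.rqa_measures(M.recurrence_plot(P, t, mode="absolute")).rr
            for t in np.linspace(0.1, 4.0, 12)
        ]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_symmetric_with_recurrent_diagonal(self):
        P = phase(np.random.default_rng(4).normal(size=(25, 2)))
        R = M.recurrence_plot(P, 0.5, mode="meanfrac")
        np.testing.assert_array_equal(R.M, R.M.T)
        assert np.diagonal(R.M).all()  # LOI recurrent before masking

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(15, 3))
        T = 1.2
        R = M.recurrence_plot(phase(A), T, mode="absolute")
        np.testing.assert_array_equal(R.M, brute_plot(A, A, T))


class TestCrossRecurrence:
    def test_same_space_equals_auto_plot(self):
        P = phase(np.random.default_rng(6).normal(size=(18, 2)))
        auto = M.recurrence_plot(P, 0.8, mode="absolute", theiler=0)
        cross = M.cross_recurrence_plot(P, P, 0.8, mode="absolute")
        np.testing.assert_array_equal(cross.M, auto.M)

    def test_swap_transposes(self):
        rng = np.random.default_rng(7)
        Px, Py = phase(rng.normal(size=(12, 2))), phase(rng.normal(size=(9, 2)))
        a = M.cross_recurrence_plot(Px, Py, 1.0, mode="absolute")
        b = M.cross_recurrence_plot(Py, Px, 1.0, mode="absolute")
        np.testing.assert_array_equal(a.M, b.M.T)
        assert a.shape == (12, 9)

    def test_periodic_vdp_has_long_diagonals(self):
        ts = M.simulate_vdp_pair(M.VdpParams(eps1=0.01), zscore=True)
        Px = M.delay_embed(ts.channel("x"), 2, 1, "x")
        Py = M.delay_embed(ts.channel("y"), 2, 1, "y")
        R = M.cross_recurrence_plot(Px, Py, 0.05, mode="meanfrac")
        res = M.rqa_measures(R)
        assert res.ldl > 20  # long unbroken diagonals from shared periodicity

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        A, B = rng.normal(size=(15, 2)), rng.normal(size=(11, 2))
        R = M.cross_recurrence_plot(phase(A), phase(B), 1.0, mode="absolute")
        np.testing.assert_array_equal(R.M, brute_plot(A, B, 1.0))


class TestJointRecurrence:
    def test_copies_of_same_space_reproduce_plot(self):
        P = phase(np.random.default_rng(9).normal(size=(20, 2)))
        single = M.recurrence_plot(P, 1.0, mode="absolute")
        joint = M.joint_recurrence_plot([P, P, P], 1.0, mode="absolute")
        np.testing.assert_array_equal(joint.M, single.M)

    def test_count_bounded_by_constituents(self):
        rng = np.random.default_rng(10)
        spaces = [phase(rng.normal(size=(25, 2))) for _ in range(3)]
        joint = M.joint_recurrence_plot(spaces, 1.5, mode="absolute")
        counts = [
            M.recurrence_plot(s, 1.5, mode="absolute").M.sum() for s in spaces
        ]
        assert joint.M.sum() <= min(counts)

    def test_equals_elementwise_minimum(self):
        rng = np.random.default_rng(11)
        spaces = [phase(rng.normal(size=(20, 2))) for _ in range(3)]
        joint = M.joint_recurrence_plot(spaces, 1.0, mode="absolute")
        plots = [M.recurrence_plot(s, 1.0, mode="absolute").M for s in spaces]
        np.testing.assert_array_equal(joint.M, np.minimum(np.minimum(*plots[:2]), plots[2]))

    def test_row_count_mismatch(self):
        with pytest.raises(ValueError, match="row count"):
            M.joint_recurrence_plot(
                [phase(np.zeros((5, 1))), phase(np.zeros((6, 1)))], 1.0
            )

    def test_per_space_thresholds(self):
        rng = np.random.default_rng(12)
        spaces = [phase(rng.normal(size=(15, 2))) for _ in range(2)]
        R = M.joint_recurrence_plot(spaces, [0.5, 2.0], mode="absolute")
        assert R.thresholds == (0.5, 2.0)


class TestMdrp:
    def test_single_channel_equals_classical_rqa(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=120)
        ts = M.TimeSeriesSet(x, ("x",))
        spec = M.EmbeddingSpec(m=3, tau=4, zscore=True)
        R1 = M.mdrp(ts, spec, 0.1, mode="meanfrac")
        z = M.zscore_channels(ts).data[:, 0]
        R2 = M.recurrence_plot(M.delay_embed(z, 3, 4), 0.1, mode="meanfrac")
        np.testing.assert_array_equal(R1.M, R2.M)

    def test_duplicated_channel_rescales_by_sqrt2(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=80)
        one = M.TimeSeriesSet(x, ("a",))
        two = M.TimeSeriesSet(np.column_stack([x, x]), ("a", "b"))
        spec = M.EmbeddingSpec(m=1, tau=1, zscore=False)
        R1 = M.mdrp(one, spec, 0.5, mode="absolute")
        R2 = M.mdrp(two, spec, 0.5 * np.sqrt(2.0), mode="absolute")
        np.testing.assert_array_equal(R1.M, R2.M)

    def test_lorenz_attractor_plot_is_dense_in_structure(self, lorenz):
        # the three-channel plot is square, symmetric, sparse but non-empty
        assert lorenz.md.kind == "multidim"
        assert lorenz.md.is_square
        np.testing.assert_array_equal(lorenz.md.M, lorenz.md.M.T)
        assert 0 < lorenz.measures["md"].rr < 0.05


@given(
    pts=arrays(
        np.float64,
        st.tuples(st.integers(4, 15), st.integers(1, 3)),
        elements=st.floats(-5, 5, allow_nan=False),
    ),
    T=st.floats(0.1, 3.0),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_plot_entries_match_naive_loop(pts, T):
    """Property: every auto-plot entry equals the naive per-pair Heaviside."""
    R = M.recurrence_plot(phase(pts), T, mode="absolute")
    np.testing.assert_array_equal(R.M, brute_plot(pts, pts, T))
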