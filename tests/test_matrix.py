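"""Physio-matrix construction, gated volumes and rebinning error."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from physiomatrix import (
    CycleSegmentation,
    FlowSampleSeries,
    PhysioMatrix,
    assign_phases,
    build_matrix,
    marginals,
    net_flow_volume,
    respiratory_rebin_error,
    retrograde_fraction,
    retrograde_volume,
)
from physiomatrix.errors import (
    CoverageWarning,
    EmptyBinError,
    MatrixBuildError,
    ParameterError,
    UndefinedMetricError,
)
from physiomatrix.signals import PhaseAssignments


def grid_matrix(values, dt_i=0.1, dt_j=0.05, counts=None):
    values = np.asarray(values, dtype=float)
    if counts is None:
        counts = np.ones(values.shape, dtype=int)
    return PhysioMatrix(values, counts, dt_i, dt_j)


def make_assignments(ri, cj, n_i, n_j, valid=None):
    ri = np.asarray(ri)
    cj = np.asarray(cj)
    if valid is None:
        valid = np.ones(len(ri), dtype=bool)
    return PhaseAssignments(
        resp_index=ri, cardiac_index=cj,
        resp_frac=(ri + 0.5) / n_i, cardiac_frac=(cj + 0.5) / n_j,
        valid=valid, n_i=n_i, n_j=n_j,
    )


SEG = CycleSegmentation(np.array([[0.0, 0.5]]), np.array([[0.0, 4.0]]))


class TestBuildMatrix:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_coincident_samples_average(self):
        samples = FlowSampleSeries([0.0, 0.048], [10.0, 14.0])
        a = make_assignments([2, 2], [3, 3], 4, 5)
        M = build_matrix(samples, a, SEG)
        assert M.values[2, 3] == pytest.approx(12.0)
        assert M.counts[2, 3] == 2
        assert M.delta_t_i == pytest.approx(1.0)  # 4 s / 4 phases
        assert M.delta_t_j == pytest.approx(0.1)  # 0.5 s / 5 phases

    def test_matches_group_by_mean_oracle(self):
        rng = np.random.default_rng(11)
        n = 500
        ri = rng.integers(0, 6, n)
        cj = rng.integers(0, 4, n)
        flows = rng.normal(0, 10, n)
        samples = FlowSampleSeries(0.048 * np.arange(n), flows)
        M = build_matrix(samples, make_assignments(ri, cj, 6, 4), SEG)
        for i in range(6):
            for j in range(4):
                sel = (ri == i) & (cj == j)
                if sel.any():
                    assert M.values[i, j] == pytest.approx(flows[sel].mean())
                    assert M.counts[i, j] == sel.sum()
                else:
                    assert np.isnan(M.values[i, j])

    def test_all_invalid_raises_and_sparse_warns(self):
        samples = FlowSampleSeries([0.0, 0.048], [1.0, 2.0])
        bad = make_assignments([-1, -1], [-1, -1], 4, 4,
                               valid=np.array([False, False]))
        with pytest.raises(MatrixBuildError):
            build_matrix(samples, bad, SEG)
        sparse = make_assignments([0, 1], [0, 1], 10, 10)
        with pytest.warns(CoverageWarning):
            build_matrix(samples, sparse, SEG)

    def test_full_occupancy_on_default_synthetic_acquisition(self, fontan_result):
        assert fontan_result.matrix.occupancy == 1.0


class TestVolumes:
    def test_net_volume_hand_example(self):
        M = grid_matrix([[10.0, -2.0], [6.0, 4.0]], dt_j=0.05)
        assert net_flow_volume(M) == pytest.approx(18 * 0.05 / 2)  # 0.45 ml

    def test_constant_flow_gives_flow_times_cardiac_period(self):
        q, n_i, n_j, dt_j = 20.0, 8, 5, 0.15
        M = grid_matrix(np.full((n_i, n_j), q), dt_j=dt_j)
        assert net_flow_volume(M) == pytest.approx(q * n_j * dt_j)

    def test_net_volume_invariant_to_row_permutation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 5, (6, 4))
        M = grid_matrix(vals)
        Mp = grid_matrix(vals[rng.permutation(6)])
        assert net_flow_volume(M) == pytest.approx(net_flow_volume(Mp))

    def test_bsa_indexing(self):
        M = grid_matrix([[10.0, -2.0], [6.0, 4.0]], dt_j=0.05)
        assert net_flow_volume(M, bsa_m2=1.5) == pytest.approx(0.45 / 1.5)

    def test_retrograde_hand_example_three_modes(self):
        M = grid_matrix([[10.0, -2.0], [6.0, 4.0]], dt_j=0.05)
        assert retrograde_volume(M, "simultaneous") == pytest.approx(-0.05)
        assert retrograde_volume(M, "ecg") == 0.0  # P^c = {16, 2}
        assert retrograde_volume(M, "resp") == 0.0  # P^r = {8, 10}

    def test_respiration_driven_retrograde_needs_respiratory_gating(self):
        # retrograde confined to one respiratory row: ECG gating blind to it
        M = grid_matrix([[-5.0, -5.0], [10.0, 10.0]], dt_j=0.05)
        assert retrograde_volume(M, "resp") == pytest.approx(-10 * 0.05 / 2)
        assert retrograde_volume(M, "ecg") == 0.0
        assert retrograde_volume(M, "simultaneous") == pytest.approx(-0.25)

    def test_all_positive_matrix_has_zero_retrograde(self):
        M = grid_matrix(np.abs(np.random.default_rng(0).normal(5, 1, (4, 3))))
        for mode in ("simultaneous", "ecg", "resp"):
            assert retrograde_volume(M, mode) == 0.0

    def test_unknown_mode_and_empty_bins_raise(self):
        M = grid_matrix([[1.0, 2.0]])
        with pytest.raises(ParameterError):
            retrograde_volume(M, "cardiac")
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        counts = np.array([[1, 0], [1, 1]])
        Me = PhysioMatrix(vals, counts, 0.1, 0.05)
        with pytest.raises(EmptyBinError) as err:
            net_flow_volume(Me)
        assert (0, 1) in err.value.empty_bins

    def test_fraction_examples_and_zero_net_error(self):
        assert retrograde_fraction(-0.05, 0.45) == pytest.approx(100 / 9)
        assert retrograde_fraction(0.0, 0.45) == 0.0
        with pytest.raises(UndefinedMetricError):
            retrograde_fraction(-0.1, 0.0)


class TestVolumeProperties:
    def test_brute_force_oracle_on_random_matrices(self):
        """Net and all three retrograde volumes equal exhaustive summation."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            vals = rng.uniform(-10, 10, (4, 3))
            M = grid_matrix(vals, dt_i=0.7, dt_j=0.08)
            scale = M.delta_t_j / M.n_i
            net_oracle = np.sum([vals[i, j] for i in range(4) for j in range(3)]) * scale
            sim_oracle = np.sum([vals[i, j] for i in range(4) for j in range(3)
                                 if vals[i, j] < 0]) * scale
            pc = [sum(vals[i, j] for i in range(4)) for j in range(3)]
            pr = [sum(vals[i, j] for j in range(3)) for i in range(4)]
            ecg_oracle = np.sum([v for v in pc if v < 0]) * scale
            resp_oracle = np.sum([v for v in pr if v < 0]) * scale
            assert net_flow_volume(M) == pytest.approx(net_oracle, rel=1e-12, abs=1e-15)
            assert retrograde_volume(M, "simultaneous") == pytest.approx(sim_oracle, rel=1e-12, abs=1e-15)
            assert retrograde_volume(M, "ecg") == pytest.approx(ecg_oracle, rel=1e-12, abs=1e-15)
            assert retrograde_volume(M, "resp") == pytest.approx(resp_oracle, rel=1e-12, abs=1e-15)

    def test_marginal_gating_bounds_retrograde(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            M = grid_matrix(rng.uniform(-10, 10, (5, 4)))
            sim = retrograde_volume(M, "simultaneous")
            assert abs(retrograde_volume(M, "ecg")) <= abs(sim) + 1e-12
            assert abs(retrograde_volume(M, "resp")) <= abs(sim) + 1e-12

    def test_flow_scaling_scales_volumes_not_fractions(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(-10, 10, (5, 4))
        c = 3.7
        M, Mc = grid_matrix(vals), grid_matrix(c * vals)
        assert net_flow_volume(Mc) == pytest.approx(c * net_flow_volume(M))
        for mode in ("simultaneous", "ecg", "resp"):
            assert retrograde_volume(Mc, mode) == pytest.approx(
                c * retrograde_volume(M, mode))
        f = retrograde_fraction(retrograde_volume(M, "simultaneous"),
                                net_flow_volume(M))
        fc = retrograde_fraction(retrograde_volume(Mc, "simultaneous"),
                                 net_flow_volume(Mc))
        assert fc == pytest.approx(f)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(arrays(np.float64, (4, 3),
                  elements=st.floats(-10, 10, allow_nan=False)))
    def test_gating_hierarchy_holds_for_any_matrix(self, vals):
        """Marginalizing before thresholding can only lose retrograde volume,
        and replacing 'negative entries' by 'all entries' gives V_net in
        every gating mode."""
        M = grid_matrix(vals)
        net = net_flow_volume(M)
        sim = retrograde_volume(M, "simultaneous")
        scale = M.delta_t_j / M.n_i
        for mode, collapsed in (
            ("ecg", M.values.sum(axis=0)),
            ("resp", M.values.sum(axis=1)),
        ):
            assert abs(retrograde_volume(M, mode)) <= abs(sim) + 1e-12
            assert collapsed.sum() * scale == pytest.approx(net, abs=1e-12)

    def test_marginal_sums_preserve_total(self):
        M = grid_matrix(np.random.default_rng(9).normal(0, 5, (6, 3)))
        g = marginals(M)
        assert g.cardiac_marginal.sum() == pytest.approx(M.values.sum())
        assert g.respiratory_marginal.sum() == pytest.approx(M.values.sum())


class TestRebinError:
    def test_constant_flow_has_zero_error_everywhere(self):
        n = 2000
        samples = FlowSampleSeries(0.048 * np.arange(n), np.full(n, 7.0))
        frac = np.random.default_rng(0).uniform(0, 1, n)
        a = PhaseAssignments(
            resp_index=np.minimum((40 * frac).astype(int), 39),
            cardiac_index=np.zeros(n, dtype=int),
            resp_frac=frac, cardiac_frac=np.zeros(n),
            valid=np.ones(n, dtype=bool), n_i=40, n_j=1,
        )
        errs = respiratory_rebin_error(samples, a, [2, 10, 40], reference=50)
        assert all(e == 0.0 for e in errs.values())

    def test_matches_count_weighted_block_aggregation_oracle(self):
        rng = np.random.default_rng(4)
        n = 5000
        frac = rng.uniform(0, 1, n)
        flows = np.sin(2 * np.pi * frac) * 30 + rng.normal(0, 2, n)
        samples = FlowSampleSeries(0.048 * np.arange(n), flows)
        a = PhaseAssignments(
            resp_index=np.zeros(n, dtype=int), cardiac_index=np.zeros(n, dtype=int),
            resp_frac=frac, cardiac_frac=np.zeros(n),
            valid=np.ones(n, dtype=bool), n_i=40, n_j=1,
        )
        # rebinning 50 -> 10 by factor 5 equals count-weighted block means
        errs = respiratory_rebin_error(samples, a, [10], reference=50)
        idx50 = np.minimum((50 * frac).astype(int), 49)
        sums = np.bincount(idx50, weights=flows, minlength=50)
        cnts = np.bincount(idx50, minlength=50)
        w50 = sums / cnts
        w10 = sums.reshape(10, 5).sum(1) / cnts.reshape(10, 5).sum(1)
        a50 = w50.max() - w50.min()
        a10 = w10.max() - w10.min()
        assert errs[10] == pytest.approx(1 - a10 / a50, rel=1e-12)

    def test_reference_must_dominate_phase_counts(self):
        samples = FlowSampleSeries([0.0, 0.048], [1.0, 2.0])
        a = make_assignments([0, 1], [0, 0], 2, 1)
        with pytest.raises(ParameterError):
            respiratory_rebin_error(samples, a, [2, 60], reference=50)
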