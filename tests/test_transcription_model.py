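import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promlock import (
    CellTrajectory,
    LockMode,
    ParameterError,
    TranscriptionModelParams,
    mean_interval_closed_form,
    sample_first_intervals,
    simulate_cell,
    simulate_commit_times,
    theoretical_fractions,
)
from promlock.population_protocol import run_protocol
from promlock.single_cell_stats import ks_compare

GRID = np.arange(0.0, 61.0, 15.0)


def make_params(**kw):
    base = dict(k1=1.0, k_minus1=0.0, k2=1.0, k_cc=0.0, k_unlock=math.inf,
                rna_delay=0.0)
    base.update(kw)
    return TranscriptionModelParams(**base)


class TestParams:
    def test_accepts_infinite_k_unlock(self):
        p = make_params(k_unlock=math.inf, k_cc=5.0)
        assert p.lock_disabled

    @pytest.mark.parametrize("bad", [
        dict(k1=-1.0), dict(k_minus1=-0.1), dict(k2=math.nan),
        dict(k_cc=-2.0), dict(k_unlock=-1.0), dict(rnap_level=0.0),
        dict(rnap_level=-1.0), dict(rna_delay=-0.5), dict(p_lock=1.5),
        dict(p_lock=-0.1), dict(k_rep_bind=-1.0),
    ])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ParameterError):
            make_params(**bad)

    def test_from_dict_plus_inf_string(self):
        p = TranscriptionModelParams.from_dict(
            {"k1": 1, "k_minus1": 0, "k2": 1, "k_cc": 1, "k_unlock": "+inf"}
        )
        assert math.isinf(p.k_unlock)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ParameterError, match="unknown"):
            TranscriptionModelParams.from_dict(
                {"k1": 1, "k_minus1": 0, "k2": 1, "k_cc": 0, "k_unlock": 1,
                 "bogus": 3}
            )

    def test_dict_round_trip_preserves_inf(self):
        p = make_params(k_unlock=math.inf)
        q = TranscriptionModelParams.from_dict(p.to_dict())
        assert q == p


class TestSimulateCell:
    def test_no_initiation_channel_count_constant(self):
        p = make_params(k1=0.0)
        traj = simulate_cell(p, 60.0, GRID, seed=1, initial_rna=3)
        assert np.all(traj.rna_counts == 3)

    def test_counts_start_at_initial_and_never_decrease(self):
        p = make_params(k1=2.0, k_minus1=1.0, k2=1.0, k_cc=0.5, k_unlock=1.0,
                        rna_delay=1.0)
        traj = simulate_cell(p, 60.0, GRID, seed=7, initial_rna=2)
        assert traj.rna_counts[0] == 2
        assert np.all(np.diff(traj.rna_counts) >= 0)

    def test_determinism_bit_identical(self):
        p = make_params(k1=2.0, k_cc=1.0, k_unlock=0.5)
        a = simulate_cell(p, 60.0, GRID, seed=11)
        b = simulate_cell(p, 60.0, GRID, seed=11)
        assert np.array_equal(a.rna_counts, b.rna_counts)
        c = simulate_cell(p, 60.0, GRID, seed=12)
        assert not np.array_equal(a.rna_counts, c.rna_counts)

    def test_rna_delay_shifts_observation(self):
        p = make_params(k1=100.0, k2=100.0, rna_delay=30.0)
        traj = simulate_cell(p, 60.0, np.array([0.0, 15.0, 29.9]), seed=3)
        assert np.all(traj.rna_counts == 0)

    @pytest.mark.parametrize("kwargs", [
        dict(t_end=-5.0, sample_times=GRID),
        dict(t_end=0.0, sample_times=GRID),
        dict(t_end=60.0, sample_times=[10.0, 5.0]),
        dict(t_end=60.0, sample_times=[0.0, 90.0]),
        dict(t_end=60.0, sample_times=[]),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            simulate_cell(make_params(), seed=1, **kwargs)

    def test_commit_times_sorted_within_horizon(self):
        p = make_params(k1=1.0, k2=2.0)
        times = simulate_commit_times(p, 50.0, seed=9)
        assert np.all(np.diff(times) > 0)
        assert times.size == 0 or times[-1] <= 50.0

    def test_trajectory_validation(self):
        with pytest.raises(ParameterError):
            CellTrajectory(sample_times=[0.0, 10.0], rna_counts=[3, 2], seed=0)
        with pytest.raises(ParameterError):
            CellTrajectory(sample_times=[10.0, 0.0], rna_counts=[0, 1], seed=0)


class TestClosedForm:
    def test_two_sequential_unit_steps(self):
        p = make_params(k1=1.0, k_minus1=0.0, k2=1.0, k_cc=0.0)
        assert mean_interval_closed_form(p) == pytest.approx(2.0)

    def test_locking_first_step_analysis_value(self):
        # first-step analysis of the ON/CC/LOCKED chain gives exactly 5
        p = make_params(k1=1.0, k_minus1=1.0, k2=1.0, k_cc=1.0, k_unlock=1.0)
        assert mean_interval_closed_form(p) == pytest.approx(5.0)

    def test_infinite_unlock_equals_no_lock(self):
        a = make_params(k1=0.7, k_minus1=0.3, k2=2.0, k_cc=4.0,
                        k_unlock=math.inf)
        b = a.with_(k_cc=0.0, k_unlock=1.0)
        assert mean_interval_closed_form(a) == mean_interval_closed_form(b)

    def test_repressed_configuration_unsupported(self):
        p = make_params(k_rep_bind=0.5)
        with pytest.raises(ParameterError):
            mean_interval_closed_form(p)

    def test_zero_k1_unsupported(self):
        with pytest.raises(ParameterError):
            mean_interval_closed_form(make_params(k1=0.0))

    def test_per_initiation_mode(self):
        p = make_params(k1=1.0, k2=1.0, k_cc=0.0, k_unlock=2.0,
                        lock_mode=LockMode.per_initiation, p_lock=0.5)
        assert mean_interval_closed_form(p) == pytest.approx(2.0 + 0.25)

    @given(
        k1=st.floats(0.2, 5.0), k_minus1=st.floats(0.0, 3.0),
        k2=st.floats(0.2, 5.0), k_cc=st.floats(0.0, 3.0),
        k_unlock=st.floats(0.1, 10.0), rnap=st.floats(0.3, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, k1, k_minus1, k2, k_cc, k_unlock, rnap):
        p = make_params(k1=k1, k_minus1=k_minus1, k2=k2, k_cc=k_cc,
                        k_unlock=k_unlock, rnap_level=rnap)
        prior, after = theoretical_fractions(p)
        assert prior + after == pytest.approx(1.0)
        assert 0.0 <= prior <= 1.0


class TestTheoreticalFractions:
    def test_equal_sequential_steps(self):
        p = make_params(k1=1.0, k_minus1=0.0, k2=1.0, k_cc=0.0)
        assert theoretical_fractions(p) == pytest.approx((0.5, 0.5))

    def test_prior_fraction_increases_as_unlock_slows(self):
        fracs = []
        for ku in [10.0, 1.0, 0.1, 0.01]:
            p = make_params(k1=1.0, k2=1.0, k_cc=1.0, k_unlock=ku)
            fracs.append(theoretical_fractions(p)[0])
        assert all(a < b for a, b in zip(fracs, fracs[1:]))


class TestOracleEquivalence:
    # empirical mean first-passage interval vs closed form, 3 SE, per the
    # renewal structure (intervals are i.i.d. first-passage times)
    PARAM_SETS = [
        make_params(k1=1.0, k_minus1=0.0, k2=1.0, k_cc=0.0),
        make_params(k1=1.0, k_minus1=1.0, k2=1.0, k_cc=1.0, k_unlock=1.0),
        make_params(k1=19.0, k_minus1=0.0, k2=1.0, k_cc=0.0),
        make_params(k1=0.733, k_minus1=0.035, k2=0.0349, k_cc=1.0,
                    k_unlock=25.0),
        make_params(k1=2.0, k_minus1=0.5, k2=0.5, k_cc=0.5, k_unlock=0.5,
                    rnap_level=1.5),
    ]

    @pytest.mark.parametrize("idx", range(len(PARAM_SETS)))
    def test_mean_interval_within_3se(self, idx):
        p = self.PARAM_SETS[idx]
        n = 2000
        intervals = sample_first_intervals(p, n, seed=314 + idx)
        assert not np.any(np.isnan(intervals))
        se = intervals.std(ddof=1) / math.sqrt(n)
        assert abs(intervals.mean() - mean_interval_closed_form(p)) < 3 * se

    def test_mean_count_matches_renewal_rate(self):
        # mean count at t over 2000 cells ~ (t - delay) / dt
        p = make_params(k1=1.0, k_minus1=0.0, k2=5.0, k_cc=0.0, rna_delay=1.0)
        t_end = 150.0
        run = run_protocol(p, n_cells=2000, t_end=t_end, sample_every=t_end,
                           init_rna_poisson_mean=0.0, seed=99)
        finals = run.counts_matrix()[:, -1]
        expected = (t_end - p.rna_delay) / mean_interval_closed_form(p)
        se = finals.std(ddof=1) / math.sqrt(finals.size)
        assert abs(finals.mean() - expected) < 3 * se

    def test_per_initiation_interval_within_3se(self):
        p = make_params(k1=1.0, k2=1.0, k_cc=0.0, k_unlock=0.5,
                        lock_mode="per_initiation", p_lock=0.4)
        intervals = sample_first_intervals(p, 2000, seed=5)
        # first passage from ON has no preceding commitment, so the
        # per-initiation lock dwell is not part of the first interval
        expected = 2.0
        se = intervals.std(ddof=1) / math.sqrt(2000)
        assert abs(intervals.mean() - expected) < 3 * se


class TestLockDisableEquivalence:
    def test_final_count_distributions_indistinguishable(self):
        pa = make_params(k1=1.0, k_minus1=0.5, k2=0.5, k_cc=0.0, k_unlock=1.0)
        pb = pa.with_(k_cc=2.0, k_unlock=math.inf)
        a, b = [], []
        for s in range(20):
            ra = run_protocol(pa, n_cells=100, t_end=60, sample_every=60,
                              init_rna_poisson_mean=0.0, seed=1000 + s)
            rb = run_protocol(pb, n_cells=100, t_end=60, sample_every=60,
                              init_rna_poisson_mean=0.0, seed=5000 + s)
            a.extend(ra.counts_matrix()[:, -1])
            b.extend(rb.counts_matrix()[:, -1])
        res = ks_compare(a, b)
        assert not res.distinguishable
        assert res.p_value > 0.01
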