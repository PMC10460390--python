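import numpy as np
import pytest

from cgmficc.ficc import (
    CurvePanel,
    bootstrap_ci,
    build_panel,
    estimate_ficc,
    stratified_report,
)
from cgmficc.ingest_qc import SLOTS_PER_DAY, SubjectSeries
from cgmficc.simulate import simulate_panel

from conftest import make_curve, make_series
from oracles import icc_trace_oracle_balanced


def random_panel(rng, n=4, J=3, p=5, between_scale=1.0):
    eta = rng.normal(0, between_scale, (n, p))
    Y = np.repeat(eta, J, axis=0) + rng.normal(0, 1.0, (n * J, p))
    return CurvePanel(Y=Y, subject_index=np.repeat(np.arange(n), J), grid=np.arange(p, dtype=float))


class TestBuildPanel:
    def test_shape_and_order(self, small_cohort):
        panel = build_panel(small_cohort)
        assert panel.Y.shape == (12, SLOTS_PER_DAY)
        assert panel.subject_ids == ("P0", "P1", "P2", "P3")

    def test_input_order_irrelevant(self, small_cohort):
        a = build_panel(small_cohort)
        b = build_panel(list(reversed(small_cohort)))
        assert np.array_equal(a.Y, b.Y) and np.array_equal(a.subject_index, b.subject_index)

    def test_single_day_subject_rejected(self):
        series = SubjectSeries("A", [make_curve("A", 1)])
        with pytest.raises(ValueError, match="need >= 2"):
            build_panel([series])

    def test_gappy_curve_rejected(self):
        gappy = make_curve("A", 1, values={0: 100.0})
        with pytest.raises(ValueError, match="gaps"):
            build_panel([SubjectSeries("A", [gappy, make_curve("A", 2)])])


class TestEstimate:
    def test_identical_days_per_subject_gives_one(self, rng):
        # within-trace zero: each subject's days are exact copies
        eta = rng.normal(0, 10, (5, 20))
        Y = np.repeat(eta, 3, axis=0)
        panel = CurvePanel(Y, np.repeat(np.arange(5), 3), np.arange(20, dtype=float))
        res = estimate_ficc(panel)
        assert res.icc == pytest.approx(1.0)
        assert res.trace_within == pytest.approx(0.0)

    def test_no_subject_effect_truncates_to_zero(self, rng):
        # large n, pure noise: MSB <= tr_W about half the time; truncation keeps 0
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            panel = random_panel(r, n=50, J=3, p=4, between_scale=0.0)
            vals.append(estimate_ficc(panel).icc)
        assert min(vals) == 0.0  # truncation actually engages
        assert max(vals) <= 0.15  # p=4 components: MSB fluctuations are sizeable

    def test_degenerate_all_identical(self):
        Y = np.full((6, 4), 100.0)
        panel = CurvePanel(Y, np.repeat(np.arange(3), 2), np.arange(4, dtype=float))
        res = estimate_ficc(panel)
        assert res.degenerate and np.isnan(res.icc)

    def test_matches_brute_force_oracle(self, rng):
        for i in range(30):
            n, J, p = rng.integers(2, 7), rng.integers(2, 5), rng.integers(2, 9)
            panel = random_panel(rng, int(n), int(J), int(p), between_scale=rng.uniform(0, 2))
            mine = estimate_ficc(panel).icc
            theirs = icc_trace_oracle_balanced(panel.Y, panel.subject_index)
            assert mine == pytest.approx(theirs, rel=1e-10, abs=1e-12)

    def test_scale_equivariance(self, rng):
        panel = random_panel(rng, 5, 3, 8)
        base = estimate_ficc(panel)
        scaled = estimate_ficc(CurvePanel(3.7 * panel.Y, panel.subject_index, panel.grid))
        assert scaled.icc == pytest.approx(base.icc, rel=1e-12)
        assert scaled.trace_between == pytest.approx(3.7**2 * base.trace_between, rel=1e-9)
        assert scaled.trace_within == pytest.approx(3.7**2 * base.trace_within, rel=1e-9)

    def test_location_invariance(self, rng):
        panel = random_panel(rng, 5, 3, 8)
        g = rng.normal(0, 50, 8)  # arbitrary fixed function of t
        shifted = estimate_ficc(CurvePanel(panel.Y + g, panel.subject_index, panel.grid))
        assert shifted.icc == pytest.approx(estimate_ficc(panel).icc, rel=1e-12)

    def test_monotone_in_between_variance_crn(self, rng):
        # common random numbers: growing subject effect never lowers the estimate
        n, J, p = 12, 3, 10
        eta = rng.normal(0, 1, (n, p))
        eps = rng.normal(0, 1, (n * J, p))
        idx = np.repeat(np.arange(n), J)
        last = -1.0
        for scale in (0.0, 0.5, 1.0, 2.0, 4.0):
            Y = scale * np.repeat(eta, J, axis=0) + eps
            icc = estimate_ficc(CurvePanel(Y, idx, np.arange(p, dtype=float))).icc
            assert icc >= last - 1e-12
            last = icc

    def test_unbalanced_design_recovers_truth(self):
        # unbalanced J_i: method-of-moments c0 correction keeps recovery honest
        rng = np.random.default_rng(5)
        n, p, lam = 400, 24, 0.5
        rows, idx = [], []
        for i in range(n):
            J = int(rng.integers(2, 7))
            eta = rng.normal(0, 1.0, p)  # between var 1 per point
            for _ in range(J):
                rows.append(eta + rng.normal(0, 1.0, p))  # within var 1 -> icc 0.5
                idx.append(i)
        panel = CurvePanel(np.array(rows), np.array(idx), np.arange(p, dtype=float))
        assert estimate_ficc(panel).icc == pytest.approx(lam, abs=0.05)

    def test_subgrid_consistency(self):
        # covariance structure constant across the grid: a 32-slot subgrid
        # estimate agrees with the full-grid estimate up to Monte-Carlo noise
        panel = simulate_panel(120, 4, 0.4, seed=99)
        sub = CurvePanel(panel.Y[:, ::9], panel.subject_index, panel.grid[::9])
        full = estimate_ficc(panel).icc
        coarse = estimate_ficc(sub).icc
        assert coarse == pytest.approx(full, abs=0.06)

    def test_two_way_day_demeaning_option(self, small_cohort):
        panel = build_panel(small_cohort)
        res = estimate_ficc(panel, demean_by_day=True)
        assert 0.0 <= res.icc <= 1.0


class TestBootstrap:
    def test_deterministic_for_seed(self, rng):
        panel = random_panel(rng, 8, 3, 6)
        a = bootstrap_ci(panel, B=200, seed=123)
        b = bootstrap_ci(panel, B=200, seed=123)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = bootstrap_ci(panel, B=200, seed=124)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_degenerate_panel_ci_collapses_to_one(self, rng):
        eta = rng.normal(0, 10, (5, 6))
        Y = np.repeat(eta, 2, axis=0)
        panel = CurvePanel(Y, np.repeat(np.arange(5), 2), np.arange(6, dtype=float))
        res = bootstrap_ci(panel, B=100, seed=1)
        assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)

    def test_ci_brackets_point_estimate(self):
        panel = simulate_panel(60, 4, 0.4, seed=7)
        res = bootstrap_ci(panel, B=300, seed=11)
        assert 0.0 <= res.ci_low <= res.icc <= res.ci_high <= 1.0

    def test_matches_loop_bootstrap(self, rng):
        """The vectorised sufficient-statistic bootstrap equals a naive loop
        that rebuilds each resampled panel explicitly."""
        panel = random_panel(rng, 6, 3, 5)
        n = panel.n_subjects
        res = bootstrap_ci(panel, B=50, seed=42)
        rng2 = np.random.default_rng(42)
        choices = rng2.integers(0, n, size=(50, n))
        loops = []
        for row in choices:
            blocks, idx = [], []
            for new_id, s in enumerate(sorted(row)):
                block = panel.Y[panel.subject_index == s]
                blocks.append(block)
                idx.extend([new_id] * block.shape[0])
            rep = CurvePanel(np.vstack(blocks), np.array(idx), panel.grid)
            loops.append(estimate_ficc(rep).icc)
        lo, hi = np.percentile(loops, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo, rel=1e-10)
        assert res.ci_high == pytest.approx(hi, rel=1e-10)


class TestStratifiedReport:
    def test_single_stratum_equals_unstratified(self, small_cohort):
        from cgmficc.cohort import Sex

        for s in small_cohort:
            s.covariates = _cov(s.subject_id, sex=Sex.FEMALE)
        table = stratified_report(small_cohort, axes=["sex"], B=100, seed=5)
        assert len(table.rows) == 1
        row = table.rows[0]
        assert row.n == 4 and row.pct == 100.0
        direct = estimate_ficc(build_panel(small_cohort))
        assert row.icc.icc == pytest.approx(direct.icc, rel=1e-12)

    def test_strata_partition_cohort(self, small_cohort):
        from cgmficc.cohort import Sex

        for i, s in enumerate(small_cohort):
            s.covariates = _cov(s.subject_id, sex=Sex.FEMALE if i % 2 else Sex.MALE, age=30 + 20 * i)
        table = stratified_report(small_cohort, axes=["sex", "age_group"], B=50, seed=5)
        frame = table.to_frame()
        for axis in ("sex", "age_group"):
            assert frame.loc[frame.axis == axis, "n"].sum() == len(small_cohort)

    def test_small_stratum_flagged(self, small_cohort):
        from cgmficc.cohort import Sex

        small_cohort[0].covariates = _cov("P0", sex=Sex.MALE)
        for s in small_cohort[1:]:
            s.covariates = _cov(s.subject_id, sex=Sex.FEMALE)
        table = stratified_report(small_cohort, axes=["sex"], B=50, seed=5)
        male = next(r for r in table.rows if r.label == "male")
        assert male.flagged and male.icc is None


def _cov(sid, sex, age=45.0):
    from cgmficc.cohort import CovariateRecord

    return CovariateRecord(
        subject_id=sid, age=age, sex=sex, weight_kg=70.0, height_m=1.7,
        fpg_mgdl=90.0, a1c_pct=5.2,
    )
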