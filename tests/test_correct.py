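"""Tests for the stratified-bootstrap winner's-curse correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from wincurse import correct
from wincurse.correct import (
    BootstrapRun,
    DegenerateBootstrapError,
    adjust,
    bootstrap_once,
    estimate_bias,
)
from wincurse.gbt import maf_difference, run_test
from wincurse.posthoc import PosthocStats, naive_stats
from wincurse.simulate import GeneSetting, simulate_gene


def make_run(bias_rows, significant, statistic_family="D", alpha=0.01):
    bias_rows = np.asarray(bias_rows, dtype=float)
    return BootstrapRun(
        n_bootstrap=bias_rows.shape[0],
        alpha=alpha,
        test_family="burden",
        statistic_family=statistic_family,
        per_bootstrap_bias=bias_rows,
        significant=np.asarray(significant, dtype=bool),
        residual_fraction=np.full((bias_rows.shape[0], 2), 0.37),
    )


class TestBootstrapOnce:
    @pytest.fixture
    def gene(self):
        geno, _ = simulate_gene(
            GeneSetting("g", np.array([0.1, 0.3]), np.array([1.0, 2.0]), 40, 60), 3
        )
        return geno

    def test_stratum_sizes_preserved(self, gene):
        boot, resid = bootstrap_once(gene, 1)
        assert boot.n_cases == 40 and boot.n_controls == 60
        assert 0 < resid.n_cases < 40 and 0 < resid.n_controls < 60

    def test_same_seed_identical_resample(self, gene):
        b1, r1 = bootstrap_once(gene, 9)
        b2, r2 = bootstrap_once(gene, 9)
        assert np.array_equal(b1.dosages, b2.dosages)
        assert np.array_equal(r1.dosages, r2.dosages)

    def test_residual_subjects_absent_from_bootstrap(self, gene):
        boot, resid = bootstrap_once(gene, 4)
        assert set(resid.subject_ids).isdisjoint(set(boot.subject_ids))

    def test_single_case_stratum_is_degenerate(self):
        geno, _ = simulate_gene(
            GeneSetting("g", np.array([0.3]), np.array([1.0]), 1, 30), 0
        )
        with pytest.raises(DegenerateBootstrapError):
            bootstrap_once(geno, 0)

    def test_residual_fraction_matches_closed_form(self):
        # E[N_R / N] = (1 - 1/N)^N per stratum (~ e^-1, the 'third of
        # the sample' rule of thumb)
        geno, _ = simulate_gene(
            GeneSetting("g", np.array([0.1]), np.array([1.0]), 1500, 1500), 5
        )
        run = estimate_bias(geno, "burden", "D", alpha=1.0, n_bootstrap=1000, seed=2)
        mean_frac = run.residual_fraction.mean()
        assert (1 - 1 / 1500) ** 1500 == pytest.approx(0.36776, rel=1e-4)
        assert 0.36 <= mean_frac <= 0.375


class TestEstimateBias:
    def test_alpha_one_saturates_the_gate(self):
        geno, _ = simulate_gene(
            GeneSetting("g", np.array([0.2, 0.1]), np.array([2.0, 1.0]), 50, 50), 1
        )
        run = estimate_bias(geno, "burden", "D", alpha=1.0, n_bootstrap=50, seed=0)
        assert run.n_significant == 50

    def test_zero_bootstraps_is_an_empty_run(self):
        geno, _ = simulate_gene(
            GeneSetting("g", np.array([0.2]), np.array([1.0]), 20, 20), 1
        )
        run = estimate_bias(geno, "burden", "D", alpha=0.5, n_bootstrap=0, seed=0)
        assert run.n_bootstrap == 0 and run.n_significant == 0
        stats = naive_stats(geno, "D")
        with pytest.warns(UserWarning):
            assert adjust(stats, run) is stats

    @pytest.mark.parametrize("test_family", ["burden", "skat"])
    @pytest.mark.parametrize("statistic_family", ["D", "D2"])
    def test_matches_brute_force_loop_exactly(self, test_family, statistic_family):
        # independent oracle: rebuild every bootstrap via bootstrap_once
        # from the same seed and recompute statistics from the genotype
        # containers themselves
        geno, _ = simulate_gene(
            GeneSetting("g", np.array([0.3, 0.15]), np.array([2.0, 1.0]), 15, 14), 8
        )
        B, alpha = 20, 0.6
        run = estimate_bias(
            geno, test_family, statistic_family, alpha=alpha, n_bootstrap=B, seed=123,
            p_method="imhof",
        )

        rng = np.random.default_rng(123)
        got = 0
        bias_rows, sig = [], []
        while got < B:
            try:
                boot, resid = bootstrap_once(geno, rng)
            except DegenerateBootstrapError:
                continue
            got += 1
            res = run_test(boot, test_family, alpha=alpha)
            sig.append(res.p_value < alpha)
            d_boot = maf_difference(boot).d_hat
            d_resid = maf_difference(resid).d_hat
            if statistic_family == "D":
                bias_rows.append(d_boot - d_resid)
            else:
                bias_rows.append(d_boot**2 - d_resid**2)
        assert np.array_equal(run.significant, np.array(sig))
        assert np.allclose(run.per_bootstrap_bias, np.array(bias_rows), atol=0, rtol=0)
        if run.n_significant:
            expected_median = np.median(np.array(bias_rows)[np.array(sig)], axis=0)
            assert np.array_equal(run.bias_summary("median"), expected_median)

    def test_winners_curse_direction_on_selected_null_gene(self):
        # a null gene that happens to clear Step 1: recorded bootstrap
        # bias should push positive-D variants back toward zero
        setting = GeneSetting("null", np.full(4, 0.1), np.ones(4), 150, 150)
        for seed in range(200):
            geno, _ = simulate_gene(setting, seed)
            res = run_test(geno, "burden", alpha=0.05)
            if res.significant and res.q_value > 0:
                break
        else:  # pragma: no cover - seed scan should always find one
            pytest.fail("no significant null replicate found")
        run = estimate_bias(geno, "burden", "D", alpha=0.05, n_bootstrap=400, seed=1)
        assert run.n_significant > 10
        med = run.bias_summary("median")
        d_hat = maf_difference(geno).d_hat
        # aggregate direction: bias estimates align with the observed excess
        assert (np.sign(med) == np.sign(d_hat)).mean() >= 0.5
        assert med[np.argmax(d_hat)] > 0


class TestAdjust:
    def test_plain_subtraction(self):
        stats = PosthocStats(("v1",), "D", np.array([0.002]))
        run = make_run(np.full((5, 1), 0.0005), np.ones(5))
        out = adjust(stats, run)
        assert out.adjusted[0] == pytest.approx(0.0015)
        assert out.n_significant_bootstraps == 5

    def test_overcorrection_clamps_to_zero(self):
        stats = PosthocStats(("v1",), "D", np.array([0.001]))
        run = make_run(np.full((5, 1), 0.002), np.ones(5))
        assert adjust(stats, run).adjusted[0] == 0.0

    def test_negative_branch(self):
        stats = PosthocStats(("v1",), "D", np.array([-0.001]))
        run = make_run(np.full((5, 1), -0.0004), np.ones(5))
        assert adjust(stats, run).adjusted[0] == pytest.approx(-0.0006)

    def test_zero_stays_zero(self):
        stats = PosthocStats(("v1",), "D", np.array([0.0]))
        run = make_run(np.full((5, 1), -0.01), np.ones(5))
        assert adjust(stats, run).adjusted[0] == 0.0

    def test_median_over_significant_rows_only(self):
        stats = PosthocStats(("v1",), "D", np.array([0.01]))
        bias = np.array([[0.001], [0.009], [0.002], [0.003]])
        run = make_run(bias, [True, False, True, True])
        assert adjust(stats, run).adjusted[0] == pytest.approx(0.01 - 0.002)

    def test_mean_summary_option(self):
        stats = PosthocStats(("v1",), "D", np.array([0.01]))
        bias = np.array([[0.001], [0.003]])
        run = make_run(bias, [True, True])
        assert adjust(stats, run, summary="mean").adjusted[0] == pytest.approx(0.008)

    @settings(deadline=None, derandomize=True)
    @given(
        naive=arrays(float, 6, elements=st.floats(-0.05, 0.05, allow_nan=False)),
        bias=arrays(float, (9, 6), elements=st.floats(-0.1, 0.1, allow_nan=False)),
    )
    def test_sign_preservation_property(self, naive, bias):
        stats = PosthocStats(tuple(f"v{i}" for i in range(6)), "D", naive)
        out = adjust(stats, make_run(bias, np.ones(9)))
        assert np.all((out.adjusted == 0) | (np.sign(out.adjusted) == np.sign(naive)))

    def test_shrinks_when_bias_shares_sign(self):
        rng = np.random.default_rng(12)
        naive = np.array([0.01, -0.02, 0.005])
        bias = np.abs(rng.normal(scale=0.003, size=(7, 3))) * np.sign(naive)
        out = adjust(PosthocStats(("a", "b", "c"), "D", naive), make_run(bias, np.ones(7)))
        assert (np.abs(out.adjusted) <= np.abs(naive)).all()

    def test_family_mismatch_rejected(self):
        stats = PosthocStats(("v1",), "D2", np.array([0.1]))
        run = make_run(np.zeros((3, 1)), np.ones(3), statistic_family="D")
        with pytest.raises(ValueError):
            adjust(stats, run)
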