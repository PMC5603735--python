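"""Tests for the case-control genotype simulator and its known truth."""

import numpy as np
import pytest

from wincurse import simulate
from wincurse.simulate import (
    GeneSetting,
    canonical_settings,
    case_control_mafs,
    expected_values,
    lowpower_scenario,
    simulate_gene,
)


class TestCanonicalSettings:
    def test_grid_size_and_shape(self):
        settings = canonical_settings()
        assert len(settings) == 50
        for s in settings:
            assert s.n_variants == 10
            assert s.n_cases == 1500 and s.n_controls == 1500
        assert len({s.setting_id for s in settings}) == 50

    def test_all_null_mix_gives_ten_null_settings(self):
        nulls = [s for s in canonical_settings() if (s.rr == 1).all()]
        assert len(nulls) == 10

    def test_low_power_worked_scenario_is_in_the_grid(self):
        # 5 rare risk variants (f=1e-4, RR 8), 4 rare neutral, 1 common neutral f=0.01
        target = sorted(zip(lowpower_scenario().maf, lowpower_scenario().rr))
        found = [
            s for s in canonical_settings() if sorted(zip(s.maf, s.rr)) == target
        ]
        assert len(found) == 1

    def test_risk_lambda_pairing_and_reciprocals(self):
        for s in canonical_settings():
            for f, lam in zip(s.maf, s.rr):
                if lam > 1:
                    assert lam == simulate.RISK_LAMBDA[f]
                elif lam < 1:
                    assert lam == pytest.approx(1.0 / simulate.RISK_LAMBDA[f])

    def test_risk_mix_proportions(self):
        for s in canonical_settings():
            mix = s.setting_id.rsplit("rr", 1)[1]
            up, neutral, down = (int(x) for x in mix.split(":"))
            assert (s.rr > 1).sum() == up * 10 // 100
            assert (s.rr < 1).sum() == down * 10 // 100


class TestCaseControlMafs:
    def test_neutral_variant_is_frequency_identical(self):
        f_plus, f_minus = case_control_mafs(0.01, 1.0)
        assert f_plus == f_minus == 0.01

    def test_rare_high_risk_mapping(self):
        f_plus, f_minus = case_control_mafs(0.0001, 8.0)
        assert f_minus == 0.0001
        assert f_plus == pytest.approx(7.9944e-4, rel=1e-4)

    def test_protective_variant_is_rarer_in_cases(self):
        f_plus, _ = case_control_mafs(0.05, 1 / 1.2)
        assert f_plus < 0.05

    def test_monotone_in_relative_risk(self):
        lams = [0.5, 1.0, 2.0, 8.0]
        values = [case_control_mafs(0.01, lam)[0] for lam in lams]
        assert values == sorted(values)

    @pytest.mark.parametrize("f,lam", [(0.0, 2.0), (1.0, 2.0), (0.1, -1.0), (0.1, 0.0)])
    def test_domain_violations(self, f, lam):
        with pytest.raises(ValueError):
            case_control_mafs(f, lam)


class TestGeneSettingValidation:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            GeneSetting("bad", np.array([0.01, 0.02]), np.array([1.0]))

    def test_maf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GeneSetting("bad", np.array([0.7]), np.array([1.0]))


class TestSimulateGene:
    def test_same_seed_is_bit_identical(self):
        s = lowpower_scenario()
        g1, _ = simulate_gene(s, 7)
        g2, _ = simulate_gene(s, 7)
        assert np.array_equal(g1.dosages, g2.dosages)
        assert np.array_equal(g1.status, g2.status)

    def test_shapes_and_labels(self):
        s = lowpower_scenario()
        geno, truth = simulate_gene(s, 0)
        assert geno.dosages.shape == (3000, 10)
        assert geno.n_cases == 1500 and geno.n_controls == 1500
        assert truth.causal_mask.sum() == 5

    def test_null_symmetry_of_maf_difference(self):
        # all f+ = f-: the mean MAF difference over replicates is 0 up to MC error
        s = GeneSetting("null", np.array([0.05, 0.1]), np.array([1.0, 1.0]), 100, 100)
        n_rep = 3000
        diffs = np.empty((n_rep, 2))
        for r in range(n_rep):
            geno, _ = simulate_gene(s, simulate.replicate_seed(12, r))
            diffs[r] = geno.case_allele_counts() / 200 - geno.control_allele_counts() / 200
        se = np.sqrt(simulate._variance_d(s.maf, s.maf, 100, 100) / n_rep)
        assert (np.abs(diffs.mean(axis=0)) < 3 * se).all()

    def test_case_frequency_converges_to_mapped_maf(self):
        # law-of-large-numbers check on ~1e5 case genotypes
        s = GeneSetting("lln", np.array([0.1]), np.array([2.0]), 1000, 10)
        total = 0
        n_rep = 100
        for r in range(n_rep):
            geno, truth = simulate_gene(s, simulate.replicate_seed(5, r))
            total += geno.case_allele_counts()[0]
        f_plus = truth.case_maf[0]
        n_alleles = 2 * 1000 * n_rep
        se = np.sqrt(f_plus * (1 - f_plus) / n_alleles)
        assert abs(total / n_alleles - f_plus) < 3 * se

    def test_allele_count_margin_is_binomial(self):
        # chi-square goodness of fit of the case allele-count distribution
        from scipy import stats

        s = GeneSetting("gof", np.array([0.2]), np.array([1.5]), 30, 30)
        n_rep = 10_000
        counts = np.empty(n_rep, dtype=int)
        for r in range(n_rep):
            geno, truth = simulate_gene(s, simulate.replicate_seed(3, r))
            counts[r] = geno.case_allele_counts()[0]
        f_plus = truth.case_maf[0]
        support = np.arange(61)
        expected = stats.binom.pmf(support, 60, f_plus) * n_rep
        keep = expected > 5
        observed = np.bincount(counts, minlength=61)[keep]
        # lump the complement into one cell
        obs = np.append(observed, n_rep - observed.sum())
        exp = np.append(expected[keep], n_rep - expected[keep].sum())
        chi2, p = stats.chisquare(obs, exp * (obs.sum() / exp.sum()))
        assert p > 0.001


class TestExpectedValues:
    def test_neutral_variant_truth(self):
        s = GeneSetting("n", np.array([0.01]), np.array([1.0]), 1500, 1500)
        t = expected_values(s)
        assert t.expected_d[0] == 0.0
        assert t.expected_d2[0] > 0.0

    def test_rare_risk_expected_difference(self):
        s = GeneSetting("r", np.array([0.0001]), np.array([8.0]), 1500, 1500)
        t = expected_values(s)
        assert t.expected_d[0] == pytest.approx(6.994e-4, rel=1e-3)

    def test_expected_d2_dominates_squared_mean(self):
        for s in canonical_settings():
            t = expected_values(s)
            assert (t.expected_d2 >= t.expected_d**2).all()

    def test_expected_d2_matches_monte_carlo(self):
        # brute-force moment oracle at a small design
        s = GeneSetting("mc", np.array([0.05]), np.array([2.0]), 40, 40)
        t = expected_values(s)
        rng = np.random.default_rng(123)
        f_plus, f_minus = t.case_maf[0], t.control_maf[0]
        n_rep = 200_000
        d = rng.binomial(80, f_plus, n_rep) / 80 - rng.binomial(80, f_minus, n_rep) / 80
        d2 = d**2
        assert abs(d2.mean() - t.expected_d2[0]) < 3 * d2.std() / np.sqrt(n_rep)
        assert abs(d.mean() - t.expected_d[0]) < 3 * d.std() / np.sqrt(n_rep)


class TestSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        settings = canonical_settings()[:5]
        path = tmp_path / "settings.yaml"
        simulate.settings_to_yaml(settings, path)
        back = simulate.settings_from_yaml(str(path))
        assert len(back) == 5
        for a, b in zip(settings, back):
            assert a.setting_id == b.setting_id
            assert np.allclose(a.maf, b.maf)
            assert np.allclose(a.rr, b.rr)
            assert (a.n_cases, a.n_controls, a.alpha) == (b.n_cases, b.n_controls, b.alpha)

    def test_tsv_roundtrip(self, tmp_path):
        geno, _ = simulate_gene(GeneSetting("x", np.array([0.2, 0.3]), np.array([1.0, 2.0]), 20, 25), 1)
        path = tmp_path / "geno.tsv"
        simulate.genotypes_to_tsv(geno, path)
        back = simulate.genotypes_from_tsv(path)
        assert np.array_equal(geno.dosages, back.dosages)
        assert np.array_equal(geno.status, back.status)
        assert geno.variant_ids == back.variant_ids
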