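import numpy as np
import pytest
from scipy import stats

from ophiopsin.behaviour import (
    BehaviourDataset,
    datasets_from_table,
    f_test_variances,
    normality_test,
    spectral_verdicts,
    students_t_test,
)
from ophiopsin.seqcore import InputError
from ophiopsin.synthetic import generate_behaviour_counts


def closed_form_pooled_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestFTest:
    def test_identical_groups(self):
        F, p = f_test_variances([1, 2, 3, 4], [1, 2, 3, 4])
        assert F == 1 and p == pytest.approx(1.0)

    def test_zero_variance_group_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="zero variance"):
            F, p = f_test_variances([0, 0, 0, 0], [0, 4, 0, 4])
        assert np.isinf(F) and p == 0

    def test_both_constant_rejected(self):
        with pytest.raises(InputError):
            f_test_variances([2, 2, 2], [5, 5, 5])

    def test_matches_closed_form_f_cdf(self, rng):
        a = rng.normal(10, 2, size=9)
        b = rng.normal(10, 4, size=7)
        F, p = f_test_variances(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        expected_F = max(va, vb) / min(va, vb)
        dfn, dfd = (8, 6) if va >= vb else (6, 8)
        assert F == pytest.approx(expected_F)
        assert p == pytest.approx(min(1, 2 * stats.f.sf(expected_F, dfn, dfd)))

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            f_test_variances([1], [1, 2])


class TestNormality:
    def test_gaussian_type_one_rate_is_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            normality_test(rng.normal(size=20)) < 0.05 for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) <= 0.015

    def test_skewed_data_rejected_far_above_alpha(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            normality_test(rng.exponential(size=20)) < 0.05 for _ in range(300)
        )
        assert rejections / 300 > 0.5

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(normality_test([3, 3, 3, 3]))

    def test_supported_sample_sizes(self):
        with pytest.raises(InputError):
            normality_test([1, 2])


class TestStudentsT:
    def test_identical_groups_give_t_zero_p_one(self):
        r = students_t_test([4, 5, 6], [4, 5, 6])
        assert r.t_statistic == 0 and r.p_value == pytest.approx(1.0)
        assert r.verdict == "not_sensitive"

    def test_frozen_closed_form_example(self):
        r = students_t_test([1, 2, 3], [4, 5, 6])
        assert r.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.0213, abs=2e-4)
        assert r.verdict == "sensitive"

    def test_matches_closed_form_on_random_data(self, rng):
        for _ in range(100):
            a = rng.normal(10, 3, size=int(rng.integers(3, 20)))
            b = rng.normal(12, 3, size=int(rng.integers(3, 20)))
            r = students_t_test(a, b)
            t, p = closed_form_pooled_t(a, b)
            assert r.t_statistic == pytest.approx(t, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_swapping_groups_flips_sign_only(self, rng):
        a, b = rng.normal(5, 2, 8), rng.normal(7, 2, 9)
        r1, r2 = students_t_test(a, b), students_t_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        pvals = [
            students_t_test(rng.normal(size=8), rng.normal(size=8)).p_value
            for _ in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            students_t_test([1], [2, 3])


class TestVerdicts:
    def test_counts_capped_by_two_arms_per_animal(self):
        with pytest.raises(InputError):
            BehaviourDataset("white", day_counts=[37], night_counts=[1])

    def test_day_suppression_pattern_from_generator(self):
        ok = {t: 0 for t in ("white", "green", "blue", "red", "none")}
        n_seeds = 40
        for seed in range(n_seeds):
            table = generate_behaviour_counts(seed=seed)
            verdicts = spectral_verdicts(datasets_from_table(table))
            for _, row in verdicts.iterrows():
                want = ("sensitive" if row.treatment in ("white", "green", "blue")
                        else "not_sensitive")
                ok[row.treatment] += row.verdict == want
        for treatment, n_ok in ok.items():
            assert n_ok / n_seeds >= 0.9, treatment

    def test_no_effect_control_type_one_rate(self):
        rejected = 0
        for seed in range(200):
            table = generate_behaviour_counts(effects={"none": 0.0}, seed=seed)
            v = spectral_verdicts(datasets_from_table(table))
            rejected += (v.iloc[0]["verdict"] == "sensitive")
        assert abs(rejected / 200 - 0.05) < 0.05

    def test_weak_red_effect_is_unstable_across_seeds(self):
        sensitive = 0
        for seed in range(100):
            table = generate_behaviour_counts(effects={"red": 0.15}, seed=seed)
            v = spectral_verdicts(datasets_from_table(table))
            sensitive += (v.iloc[0]["verdict"] == "sensitive")
        assert 0.1 < sensitive / 100 < 0.9  # marginal regime, neither verdict stable

    def test_verdict_monotone_in_effect_size(self):
        rates = []
        for effect in (0.0, 0.2, 0.4, 0.6):
            hits = 0
            for seed in range(40):
                table = generate_behaviour_counts(effects={"x": effect}, seed=seed)
                hits += (spectral_verdicts(datasets_from_table(table))
                         .iloc[0]["verdict"] == "sensitive")
            rates.append(hits / 40)
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_direction_note_reports_day_suppression(self):
        table = generate_behaviour_counts(effects={"white": 0.6}, seed=1)
        v = spectral_verdicts(datasets_from_table(table))
        assert bool(v.iloc[0]["day_suppressed"])


class TestTableParsing:
    def test_daily_mean_unit_aggregates_observations(self):
        table = generate_behaviour_counts(effects={"white": 0.5}, n_days=8,
                                          obs_per_phase=2, seed=0)
        daily = datasets_from_table(table, unit="daily_mean")[0]
        raw = datasets_from_table(table, unit="observation")[0]
        assert len(daily.day_counts) == 8 and len(raw.day_counts) == 16
        assert np.mean(daily.day_counts) == pytest.approx(np.mean(raw.day_counts))

    def test_unknown_unit_rejected(self):
        table = generate_behaviour_counts(effects={"white": 0.5}, seed=0)
        with pytest.raises(InputError):
            datasets_from_table(table, unit="weekly")
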