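"""Per-study effects, MH / DL pooling, heterogeneity, model selection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import StratifiedTable

from snpmeta import (
    MetaConfig,
    PoolingMethod,
    StudyEffect,
    TwoByTwoTable,
    ValidationError,
    cochran_q,
    dersimonian_laird_tau2,
    inverse_variance_pool,
    mantel_haenszel_pool,
    meta_analyze,
    select_method,
    study_effect,
    z_from_or_ci,
)

from conftest import make_record


def effects(pairs):
    return [StudyEffect(study_id=f"s{i}", log_or=lo, se=math.sqrt(v))
            for i, (lo, v) in enumerate(pairs)]


class TestStudyEffect:
    def test_symmetric_table(self):
        eff = study_effect(TwoByTwoTable(10, 10, 10, 10))
        assert eff.log_or == pytest.approx(0.0)
        assert eff.se == pytest.approx(math.sqrt(0.4))
        assert not eff.corrected

    def test_crude_or(self):
        eff = study_effect(TwoByTwoTable(20, 10, 10, 20))
        assert math.exp(eff.log_or) == pytest.approx(4.0)

    def test_zero_cell_haldane_correction(self):
        eff = study_effect(TwoByTwoTable(0, 10, 5, 5))
        assert eff.corrected
        assert math.exp(eff.log_or) == pytest.approx(
            (0.5 * 5.5) / (10.5 * 5.5))

    def test_no_information_table_errors(self):
        with pytest.raises(ValidationError):
            study_effect(TwoByTwoTable(0, 0, 0, 5))


class TestMantelHaenszel:
    def test_single_table_reduces_to_crude_or(self):
        log_or, _ = mantel_haenszel_pool([TwoByTwoTable(20, 10, 10, 20)])
        assert math.exp(log_or) == pytest.approx(4.0)

    def test_two_table_hand_example(self):
        tables = [TwoByTwoTable(10, 10, 10, 10), TwoByTwoTable(20, 10, 10, 20)]
        log_or, _ = mantel_haenszel_pool(tables)
        # (2.5 + 6.6667) / (2.5 + 1.6667)
        assert math.exp(log_or) == pytest.approx(2.2, rel=1e-12)

    def test_order_invariance(self):
        tables = [TwoByTwoTable(3, 7, 11, 2), TwoByTwoTable(8, 1, 4, 9),
                  TwoByTwoTable(5, 5, 6, 4)]
        forward = mantel_haenszel_pool(tables)
        reverse = mantel_haenszel_pool(list(reversed(tables)))
        assert forward == pytest.approx(reverse, rel=1e-14)

    def test_infinite_or_errors(self):
        with pytest.raises(ValidationError):
            mantel_haenszel_pool([TwoByTwoTable(5, 0, 0, 5)])

    def test_matches_statsmodels_estimate_and_rbg_se(self):
        """Independent oracle: statsmodels StratifiedTable implements the
        same MH estimator and Robins-Breslow-Greenland variance."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(2, 8))
            raw = rng.integers(1, 80, size=(k, 4))
            tables = [TwoByTwoTable(*row) for row in raw]
            log_or, se = mantel_haenszel_pool(tables)
            oracle = StratifiedTable(
                [np.array([[t.a, t.b], [t.c, t.d]]) for t in tables])
            assert log_or == pytest.approx(float(oracle.logodds_pooled),
                                           rel=1e-10)
            assert se == pytest.approx(float(oracle.logodds_pooled_se),
                                       rel=1e-10)

    @given(st.lists(st.tuples(*[st.integers(1, 50)] * 4), min_size=1,
                    max_size=6))
    def test_pooled_or_within_study_or_range(self, cells):
        tables = [TwoByTwoTable(*c) for c in cells]
        log_or, _ = mantel_haenszel_pool(tables)
        study_ors = [math.log(t.a * t.d / (t.b * t.c)) for t in tables]
        assert min(study_ors) - 1e-9 <= log_or <= max(study_ors) + 1e-9


class TestInverseVariance:
    def test_single_effect_is_identity(self):
        eff = effects([(0.3, 0.04)])
        assert inverse_variance_pool(eff) == pytest.approx((0.3, 0.2))

    def test_two_equal_effects_halve_variance(self):
        eff = effects([(0.5, 0.09), (0.5, 0.09)])
        log_or, se = inverse_variance_pool(eff)
        assert log_or == pytest.approx(0.5)
        assert se == pytest.approx(0.3 / math.sqrt(2))

    def test_equal_weights_give_plain_mean(self):
        eff = effects([(0.0, 1.0), (math.log(2), 1.0)])
        log_or, _ = inverse_variance_pool(eff)
        assert log_or == pytest.approx(math.log(2) / 2)


class TestHeterogeneity:
    def test_identical_effects_are_homogeneous(self):
        q, df, p, i2 = cochran_q(effects([(0.2, 0.01)] * 4))
        assert q == pytest.approx(0.0)
        assert (df, p, i2) == (3, pytest.approx(1.0), 0.0)

    def test_k1_convention(self):
        assert cochran_q(effects([(0.2, 0.01)])) == (0.0, 0, 1.0, 0.0)

    def test_q_hand_oracle(self):
        # brute-force arithmetic: w = 25 each, mean = ln3 / 3
        eff = effects([(0.0, 0.04), (0.0, 0.04), (math.log(3), 0.04)])
        mean = math.log(3) / 3
        expected_q = 25 * (2 * mean ** 2 + (math.log(3) - mean) ** 2)
        q, df, p, i2 = cochran_q(eff)
        assert q == pytest.approx(expected_q, rel=1e-12)
        assert i2 == pytest.approx((expected_q - 2) / expected_q * 100)

    def test_tau2_truncates_at_zero(self):
        assert dersimonian_laird_tau2(effects([(0.2, 0.01)] * 3)) == 0.0

    def test_tau2_hand_oracle(self):
        eff = effects([(0.0, 0.04), (math.log(3), 0.04)])
        w = 25.0
        mean = math.log(3) / 2
        q = w * (mean ** 2 + (math.log(3) - mean) ** 2)
        expected = (q - 1) / (2 * w - (2 * w * w) / (2 * w))
        assert dersimonian_laird_tau2(eff) == pytest.approx(expected,
                                                            rel=1e-12)


@pytest.mark.parametrize(
    "p_het, i2, expected",
    [
        (0.931, 0.0, PoolingMethod.FIXED_MH),
        (0.003, 78.0, PoolingMethod.RANDOM_DL),
        (0.04, 10.0, PoolingMethod.RANDOM_DL),   # significant Q alone
        (0.20, 60.0, PoolingMethod.RANDOM_DL),   # high I2 alone
        (0.06, 49.9, PoolingMethod.FIXED_MH),
    ],
)
def test_select_method_rule(p_het, i2, expected):
    assert select_method(p_het, i2) is expected


class TestMetaAnalyze:
    def test_single_study(self):
        rec = make_record(case=(20, 40, 40), ctrl=(40, 40, 20))
        res = meta_analyze([rec], "allele")
        assert res.k == 1 and res.q == 0.0 and res.df == 0
        assert res.method is PoolingMethod.FIXED_MH
        table_or = (120 * 120) / (80 * 80)
        assert res.or_ == pytest.approx(table_or)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            meta_analyze([], "allele")

    def test_sample_sizes_are_full_subject_counts(self, rs1558139_records):
        for model in ("allele", "homozygote", "heterozygote"):
            res = meta_analyze(rs1558139_records, model)
            assert (res.n_case, res.n_ctrl) == (3462, 3547)

    def test_i2_identity_holds_in_output(self, null_corpus):
        for model in ("allele", "dominant", "recessive"):
            res = meta_analyze(null_corpus, model)
            expected = 0.0 if res.q == 0 else max(
                0.0, (res.q - res.df) / res.q) * 100
            assert res.i2_pct == pytest.approx(expected)
            assert res.ci_low <= res.or_ <= res.ci_high

    def test_random_ci_at_least_as_wide_as_fixed(self):
        eff = effects([(0.0, 0.02), (0.9, 0.03), (-0.5, 0.05), (1.2, 0.04)])
        tau2 = dersimonian_laird_tau2(eff)
        assert tau2 > 0
        _, se_fixed = inverse_variance_pool(eff, tau2=0.0)
        _, se_random = inverse_variance_pool(eff, tau2=tau2)
        assert se_random >= se_fixed

    def test_order_invariance(self, null_corpus):
        res1 = meta_analyze(null_corpus, "allele")
        res2 = meta_analyze(list(reversed(null_corpus)), "allele")
        assert res1.or_ == pytest.approx(res2.or_, rel=1e-14)
        assert res1.q == pytest.approx(res2.q, rel=1e-14)


class TestZFromOrCi:
    def test_null_or_gives_zero(self):
        assert z_from_or_ci(1.0, 0.8, 1.25) == pytest.approx(0.0)

    @pytest.mark.parametrize("row, expected", [
        ((0.92, 0.86, 0.99), 2.31),
        ((0.55, 0.39, 0.77), 3.44),
    ])
    def test_published_rows(self, row, expected):
        assert z_from_or_ci(*row) == pytest.approx(expected, abs=0.02)

    def test_degenerate_interval_errors(self):
        with pytest.raises(ValidationError):
            z_from_or_ci(1.0, 1.0, 1.0)
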