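"""MRCA/ECA timing: per-copy counts, negative-binomial test, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbclock.timing import (
    ClockCalibration,
    MrcaEcaTimer,
    classify_evolution,
    density_to_weeks_pc,
    holm_adjust,
    per_copy_clonal_count,
)
from nbclock.timing import test_segment_pre_mrca as nb_pre_mrca_test
from nbclock.synthetic import late_tumor_spec, generate_tumor
from nbclock.datatypes import SegmentProfile, MutationCall, TumorSample


class TestPerCopyCount:
    @pytest.mark.parametrize(
        "counts,cn,b,expected",
        [
            ({1: 100}, 2, 1, 50.0),
            ({1: 60, 2: 10}, 3, 1, (60 + 20) / 3),
            ({}, 3, 1, 0.0),
        ],
    )
    def test_examples(self, counts, cn, b, expected):
        assert per_copy_clonal_count(counts, cn, b) == pytest.approx(expected)

    def test_cn_zero_errors(self):
        with pytest.raises(ValueError):
            per_copy_clonal_count({1: 5}, 0, 0)


class TestNegativeBinomialTest:
    @staticmethod
    def _oracle(n_amp, g_seg, g, m):
        # term-by-term summation of the negative binomial pmf in log space
        from scipy.special import gammaln, logsumexp
        p = 1.0 / (1.0 + g_seg / g)
        r = np.arange(int(n_amp) + 1)
        logterms = (gammaln(m + r) - gammaln(m) - gammaln(r + 1)
                    + r * math.log1p(-p) + m * math.log(p))
        return float(np.exp(logsumexp(logterms)))

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            m = int(rng.integers(5, 2000))
            frac = rng.uniform(0.01, 0.5)
            n_amp = int(rng.integers(0, int(2 * m * frac) + 2))
            p = nb_pre_mrca_test(n_amp, frac * 1e9, 1e9, m)
            oracle = self._oracle(n_amp, frac * 1e9, 1e9, m)
            assert p == pytest.approx(oracle, rel=1e-10)

    def test_at_the_mean_is_central(self):
        # n_amp at the NB mean m*g_seg/g lands near the distribution center
        p = nb_pre_mrca_test(10, 0.1e9, 1e9, 100)
        assert 0.4 < p < 0.6

    def test_degenerate_zero_segment(self):
        assert nb_pre_mrca_test(5, 0.0, 1e9, 100) == 1.0

    def test_large_m_numerically_stable(self):
        p = nb_pre_mrca_test(100, 0.1e9, 1e9, 100_000)
        assert 0.0 <= p < 1e-30  # far below the mean of 10,000

    def test_segment_larger_than_genome_errors(self):
        with pytest.raises(ValueError):
            nb_pre_mrca_test(1, 2e9, 1e9, 100)


class TestHolm:
    def test_hand_example(self):
        adj = holm_adjust([1e-6, 0.5])
        assert adj[0] == pytest.approx(2e-6)
        assert adj[1] == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_monotone_and_never_decreases(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "per_mb,expected",
        [(0.03, "early"), (0.07, "late"), (0.05, "late"), (0.0499, "early")],
    )
    def test_threshold(self, per_mb, expected):
        assert classify_evolution(per_mb * 1e-6) == expected


class TestWeeksPc:
    def test_zero_density_is_gastrulation(self):
        cal = ClockCalibration(daily_rate_diploid=3.2)
        weeks, sd = density_to_weeks_pc(0.0, cal)
        assert weeks == pytest.approx(2.0)
        assert sd == 0.0

    def test_hand_example(self):
        # mu*lambda = 3.2/day diploid, density 0.02/Mb -> 55.25 days p.c.
        cal = ClockCalibration(daily_rate_diploid=3.2)
        weeks, _ = density_to_weeks_pc(0.02e-6, cal)
        assert weeks * 7 == pytest.approx(14 + 66 / 1.6, rel=1e-12)

    def test_doubling_rate_halves_span(self):
        cal1 = ClockCalibration(daily_rate_diploid=3.2)
        cal2 = ClockCalibration(daily_rate_diploid=6.4)
        w1, _ = density_to_weeks_pc(0.02e-6, cal1)
        w2, _ = density_to_weeks_pc(0.02e-6, cal2)
        assert (w1 - 2.0) == pytest.approx(2 * (w2 - 2.0))


class TestTimer:
    def test_single_class_bootstrap_has_zero_width(self, rng):
        seg = SegmentProfile("1", 0, 150_000_000, cn=2, b_allele=1)
        muts = []
        for i in range(60):
            cov = max(int(rng.poisson(80)), 1)
            nv = rng.binomial(cov, 0.5)
            if nv >= 1:
                muts.append(MutationCall("1", 1000 + i, n_var=int(nv),
                                         n_ref=int(cov - nv), segment_id=0))
        sample = TumorSample("one", 1.0, 2.0, segments=[seg], mutations=muts)
        timer = MrcaEcaTimer(n_boot=100, random_state=0).fit(sample)
        lo, hi = timer.result_.mrca_ci95
        assert lo == pytest.approx(hi)
        assert timer.result_.m_eca_density is None  # no gained segments

    def test_fp_zero_reproduces_uncorrected_density(self, rng):
        sample, _ = generate_tumor(late_tumor_spec(), seed=5)
        t0 = MrcaEcaTimer(fp=0.0, n_boot=50, random_state=0).fit(sample)
        t1 = MrcaEcaTimer(fp=0.15, n_boot=50, random_state=0).fit(sample)
        assert t1.m_mrca_density_ == pytest.approx(0.85 * t0.m_mrca_density_)

    def test_excluded_higher_rule(self, rng):
        # a gained class whose amplified density exceeds the MRCA density is
        # excluded from the ECA regardless of its p-value
        sample, _ = generate_tumor(
            late_tumor_spec(eca_density_per_mb=0.06), seed=9)
        timer = MrcaEcaTimer(n_boot=50, random_state=0).fit(sample)
        for st_ in timer.result_.per_segment:
            if st_.assignment == "excluded-higher":
                assert st_.amp_density > timer.m_mrca_density_

    def test_eca_below_mrca_when_present(self):
        sample, _ = generate_tumor(late_tumor_spec(), seed=11)
        timer = MrcaEcaTimer(n_boot=50, random_state=0).fit(sample)
        res = timer.result_
        assert res.m_eca_density is not None
        assert res.m_eca_density <= res.m_mrca_density
        # conformity of ECA classes with the pooled ECA density
        for st_ in res.per_segment:
            if st_.assignment == "ECA":
                assert st_.eca_conformity_p is None or st_.eca_conformity_p > 0.01
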