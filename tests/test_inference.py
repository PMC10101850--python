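"""Incidence curves, cost functions and VAF-data preparation."""

import numpy as np
import pytest

from nbclock.datatypes import MutationCall, SegmentProfile, TumorSample
from nbclock.inference import (
    IncidenceCurve,
    cohort_incidence,
    cost_growth,
    cost_initiation,
    empirical_incidence,
    incidence_counts,
    prepare_vaf_data,
    simulate_initiation_cohort,
)
from nbclock.initiation import InitiationParams


class TestIncidence:
    def test_strict_inequality_count(self):
        curve = empirical_incidence([1.0, 2.0, 3.0])
        assert list(curve.eval_points) == [1.0, 2.0, 3.0]
        assert list(curve.counts) == [0.0, 1.0, 2.0]

    def test_duplicates_by_multiplicity(self):
        curve = empirical_incidence([1.0, 1.0, 2.0])
        assert list(curve.counts) == [0.0, 0.0, 2.0]

    def test_equal_ci_bounds_give_zero_delta(self):
        d = [1.0, 2.0]
        curve = empirical_incidence(d, ci_lo=d, ci_hi=d)
        assert np.all(curve.delta == 0.0)

    def test_nondecreasing_enforced(self):
        with pytest.raises(ValueError):
            IncidenceCurve(np.array([1.0, 2.0]), np.array([2.0, 1.0]),
                           np.zeros(2))


class TestCostInitiation:
    def _obs(self):
        pts = np.array([0.1e-6, 0.5e-6, 1.0e-6])
        return IncidenceCurve(pts, np.array([0.0, 5.0, 9.0]),
                              np.array([1.0, 2.0, 2.0]))

    def test_zero_on_self_with_matched_incidence(self):
        obs = self._obs()
        d = cost_initiation(obs.counts, obs.counts, 1e-5, obs, obs)
        assert d == 0.0

    def test_low_density_points_weigh_ten(self):
        obs = self._obs()
        sim = obs.counts.copy()
        sim[0] += 1.0  # off by one uncertainty unit at a low-density point
        d = cost_initiation(sim, obs.counts, 1e-5, obs, obs)
        assert d == pytest.approx(10.0)

    def test_weight_switch_at_cut(self):
        pts = np.array([0.2e-6, 0.2000001e-6])
        obs = IncidenceCurve(pts, np.zeros(2), np.ones(2))
        d_low = cost_initiation([1.0, 0.0], [0.0, 0.0], 1e-5, obs, obs)
        d_high = cost_initiation([0.0, 1.0], [0.0, 0.0], 1e-5, obs, obs)
        assert d_low == pytest.approx(10.0)
        assert d_high == pytest.approx(1.0)

    def test_published_variant_is_linear_in_age10(self):
        obs = self._obs()
        d = cost_initiation(obs.counts, obs.counts, 2e-5, obs, obs,
                            age10_term="published")
        assert d == pytest.approx(1e-5 / 1e-8)


class TestCostGrowth:
    def test_zero_iff_identical(self):
        cum = {2: np.array([5.0, 3.0, 1.0]), 3: np.array([4.0, 2.0, 0.0])}
        g = {2: 1.5e9, 3: 1.0e9}
        assert cost_growth(cum, cum, g) == 0.0
        other = {2: cum[2] + 1.0, 3: cum[3]}
        assert cost_growth(other, cum, g) > 0.0

    def test_genome_fraction_weighting(self):
        cum = {2: np.zeros(3), 3: np.zeros(3)}
        g = {2: 2e9, 3: 1e9}
        off2 = {2: np.ones(3), 3: np.zeros(3)}
        off3 = {2: np.zeros(3), 3: np.ones(3)}
        assert cost_growth(off2, cum, g) == pytest.approx(2 * cost_growth(off3, cum, g))


class TestPrepareVafData:
    def _sample(self, vafs_by_seg, cn=3, b=1, rho=1.0, depth=100):
        segs, muts = [], []
        for i, vafs in enumerate(vafs_by_seg):
            segs.append(SegmentProfile(str(i + 1), 0, 200_000_000, cn=cn, b_allele=b))
            for j, v in enumerate(vafs):
                nv = max(int(round(v * depth)), 1)
                muts.append(MutationCall(str(i + 1), j + 1, n_var=nv,
                                         n_ref=depth - nv, segment_id=i))
        return TumorSample("t", rho, float(cn), segments=segs, mutations=muts)

    def test_no_amplified_mutations_unchanged(self):
        sample = self._sample([[0.33] * 20], cn=3, b=1)
        hist = prepare_vaf_data(sample, min_total_bp=1e8)
        assert len(hist.vafs[3]) == 20

    def test_merging_rule_l_over_k(self):
        # one amplified clonal mutation at CN=3 (l=2, VAF ~ 2/3) contributes
        # two entries at VAF * 2/3
        sample = self._sample([[0.33] * 20 + [0.667]], cn=3, b=1)
        hist = prepare_vaf_data(sample, min_total_bp=1e8)
        assert len(hist.vafs[3]) == 22  # 20 singles + 2 merged copies
        merged = np.sort(hist.vafs[3])[-2:]
        assert np.allclose(merged, 0.67 * 2 / 3, atol=0.02)

    def test_total_count_bookkeeping(self):
        # total merged = raw + (l-1) * amplified
        sample = self._sample([[0.33] * 30 + [0.667] * 4], cn=3, b=1)
        hist = prepare_vaf_data(sample, min_total_bp=1e8)
        assert len(hist.vafs[3]) == 34 + 4

    def test_high_cn_state_excluded(self):
        sample = self._sample([[0.2] * 15], cn=5, b=2)
        with pytest.raises(ValueError):
            prepare_vaf_data(sample, min_total_bp=1e8)


class TestSimulateCohort:
    def _params(self):
        return InitiationParams.from_nu2(
            0.75, n_peak=1e6, delta1=0.5, mu=3.0, mu1=3e-7, mu2=3e-7,
            r=1.5, lambda2=1.0, delta2=1.0)

    def test_mu_zero_saturates_incidence(self):
        params = InitiationParams.from_nu2(
            0.75, n_peak=1e6, delta1=0.5, mu=0.0, mu1=3e-7, mu2=3e-7,
            r=1.5, lambda2=1.0, delta2=1.0)
        obs = empirical_incidence(np.array([1e-8, 2e-8]))
        sim_m, sim_e, _ = simulate_initiation_cohort(
            params, 30, 0, obs, obs, t_max=params.T + 8)
        # zero mutation rate puts all simulated densities at 0 < every point
        assert np.all(sim_m == 30.0)

    def test_seeded_reproducibility(self):
        params = self._params()
        obs = empirical_incidence(np.array([1e-8, 3e-8, 6e-8]))
        a = simulate_initiation_cohort(params, 40, 11, obs, obs, t_max=params.T + 8)
        b = simulate_initiation_cohort(params, 40, 11, obs, obs, t_max=params.T + 8)
        assert np.array_equal(a[0], b[0]) and a[2] == b[2]


class TestCohortIncidence:
    def test_tetraploidization_excluded_from_eca(self):
        from nbclock.timing import SegmentTiming, TimingResult

        def res(eca_cn):
            return TimingResult(
                sample_id="x", m_mrca_count=100.0, m_mrca_density=6e-8,
                mrca_ci95=(5e-8, 7e-8), m_eca_density=1e-8,
                eca_ci95=(0.5e-8, 1.5e-8), evolution_class="late",
                per_segment=[SegmentTiming(cn=eca_cn, b=eca_cn // 2,
                                           size_bp=2e8, amplified_size_bp=4e8,
                                           n_amp=4.0, amp_density=1e-8,
                                           assignment="ECA")])
        curves = cohort_incidence([res(4), res(3)], which="eca")
        assert curves.n == 1  # the pure-tetraploidization ECA is dropped
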