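"""Two-hit initiation model: closed forms and inverse sampling."""

import numpy as np
import pytest
from scipy import integrate, stats

from nbclock.initiation import (
    InitiationParams,
    luria_delbruck_factor,
    p_eca_given_mrca,
    p_mrca,
    precursor_population,
    sample_event_times,
    second_hit_survival,
)


def decay_params(**kw):
    d = dict(n_peak=np.exp(7), delta1=0.2, mu=1.0, mu1=1e-3, mu2=1e-3,
             r=2.0, s=2.0, lambda2=0.8, delta2=1.2)
    d.update(kw)
    return InitiationParams(**d)


def homeo_params(**kw):
    d = dict(n_peak=np.exp(7), delta1=0.5, mu=1.0, mu1=2e-3, mu2=5e-4,
             r=2.0, s=2.0, lambda2=1.0, delta2=1.0)
    d.update(kw)
    return InitiationParams(**d)


class TestPopulation:
    def test_boundaries(self):
        p = decay_params()
        assert precursor_population(0.0, p) == pytest.approx(1.0)
        assert precursor_population(p.T, p) == pytest.approx(p.n_peak)

    def test_homeostasis_constant_after_peak(self):
        p = homeo_params()
        assert precursor_population(p.T + 5.0, p) == pytest.approx(p.n_peak)

    def test_decay_shrinks_after_peak(self):
        p = decay_params()
        assert precursor_population(p.T + 5.0, p) < p.n_peak


class TestSurvival:
    def test_no_loss_means_certain_survival(self):
        p = decay_params(delta1=0.0)
        assert second_hit_survival(p, "expansion") == pytest.approx(1.0)

    def test_formula(self):
        p = decay_params(delta2=0.9 * 2.0 * 0.8)  # delta2 = 0.9*s*lambda2
        assert second_hit_survival(p, "decay") == pytest.approx(0.1)

    def test_subcritical_second_phase_errors(self):
        p = decay_params(s=1.0, delta2=1.2, lambda2=0.8)  # ratio 1.5 >= 1
        with pytest.raises(ValueError, match="subcritical"):
            second_hit_survival(p, "decay")

    def test_s_derivation_from_nu2(self):
        p = InitiationParams.from_nu2(0.75, n_peak=1e4, delta1=0.5, mu=1.0,
                                      mu1=1e-5, mu2=1e-5, r=2.0)
        assert p.s == pytest.approx(2.0)
        # when the bound binds, s = 1 and nu2 adjusts to 1 - delta1/lambda1
        p2 = InitiationParams.from_nu2(0.3, n_peak=1e4, delta1=0.2, mu=1.0,
                                       mu1=1e-5, mu2=1e-5, r=2.0)
        assert p2.s == 1.0
        assert second_hit_survival(p2, "expansion") == pytest.approx(0.8)

    def test_luria_delbruck_factor_pure_birth(self):
        # delta1=0, s=1: F = int 1/(1+z) dz = log 2
        p = decay_params(delta1=0.0, s=1.0, delta2=0.8, lambda2=0.8)
        assert luria_delbruck_factor(p) == pytest.approx(np.log(2.0), rel=1e-8)


class TestPMrca:
    @pytest.mark.parametrize("maker", [decay_params, homeo_params])
    def test_valid_cdf(self, maker):
        p = maker()
        ts = np.linspace(0.0, 2.5 * p.T, 200)
        vals = p_mrca(ts, p)
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) >= -1e-15)
        assert np.all((0.0 <= vals) & (vals <= 1.0))

    def test_no_first_events_no_tumors(self):
        p = decay_params(mu1=0.0)
        assert p_mrca(10.0, p) == 0.0

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            p_mrca(-1.0, decay_params())


class TestPEcaGivenMrca:
    def test_endpoints(self):
        p = decay_params()
        assert float(p_eca_given_mrca(np.array([0.0]), 5.0, p)[0]) == 0.0
        assert float(p_eca_given_mrca(np.array([5.0]), 5.0, p)[0]) == 1.0

    def test_uniform_during_expansion(self):
        p = decay_params()
        assert float(p_eca_given_mrca(np.array([3.0]), 6.0, p)[0]) == pytest.approx(0.5)

    def test_t1_beyond_t2_errors(self):
        with pytest.raises(ValueError):
            p_eca_given_mrca(np.array([7.0]), 5.0, decay_params())

    @pytest.mark.parametrize("maker,t2_extra", [(decay_params, 3.25),
                                                (homeo_params, 6.0)])
    def test_matches_direct_clone_integral(self, maker, t2_extra):
        """Closed forms vs numerical integration of the premalignant-clone
        weighting (influx x expected clone size)."""
        p = maker()
        T, lam1, lam2, dlt2, r = p.T, p.lambda1, p.lambda2, p.delta2, p.r
        a = lam1 - p.delta1
        g2 = lam2 - dlt2 / r
        t2 = T + t2_extra

        def m1(tau):
            if tau <= T:
                return np.exp(a * (T - tau)) * np.exp(g2 * (t2 - T))
            return np.exp(g2 * (t2 - tau))

        def influx(tau):
            lam = lam1 if tau <= T else lam2
            n = (np.exp(a * tau) if tau <= T
                 else p.n_peak * np.exp((lam2 - dlt2) * (tau - T)))
            return lam * n

        def num(t1):
            return integrate.quad(lambda u: influx(u) * m1(u), 0, t1,
                                  points=[T] if t1 > T else None, limit=200)[0]

        den = num(t2)
        for t1 in np.linspace(0.4, t2 - 1e-9, 9):
            direct = num(t1) / den
            closed = float(p_eca_given_mrca(np.array([t1]), t2, p)[0])
            assert closed == pytest.approx(direct, abs=1e-9)

    def test_continuous_at_peak(self):
        p = decay_params()
        t2 = p.T + 3.0
        lo = float(p_eca_given_mrca(np.array([p.T - 1e-9]), t2, p)[0])
        hi = float(p_eca_given_mrca(np.array([p.T + 1e-9]), t2, p)[0])
        assert lo == pytest.approx(hi, abs=1e-6)


class TestSampling:
    def test_bit_reproducible(self):
        p = homeo_params(mu1=1e-5, mu2=1e-5)
        a = sample_event_times(p, 50, seed=3, t_max=30.0)
        b = sample_event_times(p, 50, seed=3, t_max=30.0)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_inverse_transform_consistency(self):
        """Sampled t2 ECDF matches the conditional CDF P_MRCA/x_max."""
        p = InitiationParams.from_nu2(0.75, n_peak=1e6, delta1=0.5, mu=3.0,
                                      mu1=3e-7, mu2=3e-7, r=1.5,
                                      lambda2=1.0, delta2=1.0)
        t_max = p.T + 8
        t1, t2 = sample_event_times(p, 10_000, seed=5, t_max=t_max, refine=False)
        fin = np.isfinite(t2)
        cap = min(p_mrca(t_max, p), 1e-5)
        grid = np.sort(t2[fin])
        ecdf = np.arange(1, fin.sum() + 1) / fin.sum()
        model = p_mrca(grid, p) / cap
        assert np.max(np.abs(ecdf - model)) < 0.02
        # expansion-phase first hits follow the uniform law
        sel = fin & (t2 <= p.T)
        assert sel.sum() > 100
        assert stats.kstest(t1[sel] / t2[sel], "uniform").pvalue > 0.01

    def test_censoring_when_model_cannot_reach_quantile(self):
        p = homeo_params(mu1=1e-8, mu2=1e-8)
        t1, t2 = sample_event_times(p, 20, seed=0, t_max=p.T)
        assert np.isinf(t2).all()
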