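"""Clonal binomial-mixture deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbclock.mixture import (
    ClonalBinomialMixture,
    expected_clonal_vafs,
    fit_clonal_mixture,
    grid_map_weights,
    mixture_posterior,
)
from nbclock.datatypes import MutationCall


class TestPeakModel:
    def test_diploid_single_peak(self):
        pm = expected_clonal_vafs(2, 1, 1.0)
        assert pm.multiplicities == (1,)
        assert pm.peak_vafs == (0.5,)

    def test_impure_trisomy(self):
        pm = expected_clonal_vafs(3, 1, 0.8)
        assert pm.zeta == pytest.approx(2.8)
        assert pm.multiplicities == (1, 2)
        assert pm.peak_vafs[0] == pytest.approx(0.8 / 2.8)
        assert pm.peak_vafs[1] == pytest.approx(1.6 / 2.8)

    def test_symmetric_tetrasomy_merges_amplified_peaks(self):
        pm = expected_clonal_vafs(4, 2, 1.0)
        assert pm.multiplicities == (1, 2)
        assert pm.peak_vafs == (0.25, 0.5)
        assert pm.merged_amplified
        assert pm.doubled == (True, False)  # merged peak follows the CN-b rule

    def test_loh_drops_b_peak(self):
        pm = expected_clonal_vafs(2, 0, 1.0)
        assert pm.multiplicities == (1, 2)

    def test_b_above_cn_rejected(self):
        with pytest.raises(ValueError):
            expected_clonal_vafs(2, 3, 1.0)


class TestPosterior:
    def test_concentrated_weight_beats_other_vertex(self):
        pm = expected_clonal_vafs(3, 1, 1.0)
        nv, nr = np.array([27]), np.array([53])  # VAF 1/3 at depth 80
        on_peak = mixture_posterior(nv, nr, pm, [1.0 - 1e-9, 1e-9])
        off_peak = mixture_posterior(nv, nr, pm, [1e-9, 1.0 - 1e-9])
        assert on_peak > off_peak

    def test_duplicate_mutation_adds_its_log_term(self):
        pm = expected_clonal_vafs(3, 1, 1.0)
        w = [0.6, 0.4]
        one = mixture_posterior([27], [53], pm, w)
        two = mixture_posterior([27, 27], [53, 53], pm, w)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_empty_set_errors(self):
        pm = expected_clonal_vafs(2, 1, 1.0)
        with pytest.raises(ValueError):
            mixture_posterior([], [], pm, [1.0])


def _simulate_class(rng, cn, b, rho, weights, n, depth=80):
    """Draw post-cutoff clonal mutations from the peak mixture."""
    pm = expected_clonal_vafs(cn, b, rho)
    ks = rng.choice(pm.multiplicities, p=weights, size=n)
    cov = np.maximum(rng.poisson(depth, n), 1)
    p = {k: v for k, v in zip(pm.multiplicities, pm.peak_vafs)}
    nv = rng.binomial(cov, [p[k] for k in ks])
    keep = nv / cov >= pm.vaf_cutoff
    return nv[keep], (cov - nv)[keep]


class TestFit:
    def test_recovers_counts_on_trisomy(self, rng):
        # 500 mutations, true (post-cutoff) weights 0.7/0.3 over peaks 1/3, 2/3
        nv, nr = _simulate_class(rng, 3, 1, 1.0, [0.7, 0.3], 500)
        X = np.column_stack([nv, nr])
        est = ClonalBinomialMixture(cn=3, b_allele=1, purity=1.0).fit(X)
        assert abs(est.weights_[0] - 0.7 * 0.5 / (0.7 * 0.5 + 0.3)) < 0.05
        # Eq-4 counts: doubled single-copy, undoubled amplified
        n = est.decomposition_.n_total_used
        assert est.decomposition_.counts[1] == pytest.approx(2 * est.weights_[0] * n)
        assert est.decomposition_.counts[2] == pytest.approx(est.weights_[1] * n)

    def test_pure_single_peak_diploid(self):
        muts = [MutationCall("1", i, n_var=40, n_ref=40) for i in range(30)]
        pm = expected_clonal_vafs(2, 1, 1.0)
        dec = fit_clonal_mixture(muts, pm)
        assert dec.weights[1] == pytest.approx(1.0)
        assert dec.n_single == pytest.approx(2 * dec.n_total_used)

    def test_matches_grid_oracle(self, rng):
        nv, nr = _simulate_class(rng, 3, 1, 0.9, [0.6, 0.4], 100)
        pm = expected_clonal_vafs(3, 1, 0.9)
        est = ClonalBinomialMixture(cn=3, b_allele=1, purity=0.9).fit(
            np.column_stack([nv, nr]))
        gw = grid_map_weights(nv, nr, pm, step=0.01)
        assert np.all(np.abs(est.weights_ - gw) <= 0.02)

    def test_low_count_flagged(self):
        muts = [MutationCall("1", i, n_var=40, n_ref=40) for i in range(5)]
        dec = fit_clonal_mixture(muts, expected_clonal_vafs(2, 1, 1.0))
        assert dec.low_confidence

    def test_weight_recovery_over_many_classes(self, rng):
        # mean absolute weight error over simulated classes stays small
        errs = []
        for i in range(60):
            w_true = rng.dirichlet([5, 5])
            nv, nr = _simulate_class(rng, 3, 1, 1.0, w_true, 300)
            est = ClonalBinomialMixture(cn=3, b_allele=1, purity=1.0,
                                        n_restarts=3, random_state=i).fit(
                np.column_stack([nv, nr]))
            # compare on the post-cutoff scale the fit sees
            w_cut = np.array([w_true[0] * 0.5, w_true[1]])
            w_cut /= w_cut.sum()
            errs.append(np.abs(est.weights_ - w_cut).mean())
        assert np.mean(errs) < 0.03

    def test_counts_permutation_invariant(self, rng):
        nv, nr = _simulate_class(rng, 3, 1, 1.0, [0.6, 0.4], 120)
        X = np.column_stack([nv, nr])
        perm = rng.permutation(len(X))
        a = ClonalBinomialMixture(cn=3, b_allele=1, purity=1.0).fit(X)
        b = ClonalBinomialMixture(cn=3, b_allele=1, purity=1.0).fit(X[perm])
        for k in a.decomposition_.counts:
            assert a.decomposition_.counts[k] == pytest.approx(
                b.decomposition_.counts[k], abs=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(cn=st.integers(1, 4), rho=st.floats(0.3, 1.0), seed=st.integers(0, 10_000))
def test_weights_simplex_and_counts_nonnegative(cn, rho, seed):
    """Degenerate peak configurations never break the simplex or counts."""
    rng = np.random.default_rng(seed)
    b = int(rng.integers(0, cn + 1))
    pm = expected_clonal_vafs(cn, b, rho)
    ks = rng.choice(pm.multiplicities, size=50)
    cov = np.maximum(rng.poisson(80, 50), 1)
    p = dict(zip(pm.multiplicities, pm.peak_vafs))
    nv = rng.binomial(cov, [min(p[k], 1.0) for k in ks])
    keep = nv / cov >= pm.vaf_cutoff
    if keep.sum() == 0:
        return
    est = ClonalBinomialMixture(cn=cn, b_allele=b, purity=rho, n_restarts=2,
                                random_state=0).fit(
        np.column_stack([nv[keep], cov[keep] - nv[keep]]))
    assert est.weights_.sum() == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in est.decomposition_.counts.values())
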