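"""Binomial-mixture deconvolution of clonal VAF peaks.

On a genomic class of copy number CN with b B-alleles, clonal SSNVs cluster
at variant allele frequencies rho*k/zeta for multiplicities
k in {1, CN-b, b}, where zeta = rho*CN + 2(1-rho) is the average locus copy
number of the impure sample.  Multiplicity-1 mutations are "non-amplified
clonal" (acquired on a single copy, either on the non-gained allele or after
the gain); multiplicity >= 2 mutations are "amplified clonal" (acquired
before the gain, hence present on every copy of the gained allele).

Variants with VAF below the non-amplified peak position rho/zeta are
discarded to avoid subclonal contamination; by symmetry this removes half of
the non-amplified peak, so its fitted count is doubled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

MIN_MUTATIONS = 10  # below this the decomposition is flagged low-confidence


@dataclass
class ClonalPeakModel:
    """Expected clonal peak structure of one (CN, b) class."""

    cn: int
    b_allele: int
    purity: float
    zeta: float = field(init=False)
    multiplicities: tuple = field(init=False)  # unique k, ascending
    peak_vafs: tuple = field(init=False)
    doubled: tuple = field(init=False)  # per peak: cutoff-correction factor 2?
    merged_amplified: bool = field(init=False)  # b == CN-b >= 2

    def __post_init__(self) -> None:
        cn, b, rho = self.cn, self.b_allele, self.purity
        if not (1 <= cn):
            raise ValueError("CN must be >= 1")
        if not (0 <= b <= cn):
            raise ValueError(f"b={b} outside [0, {cn}]")
        if not (0.0 < rho <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        self.zeta = rho * cn + 2.0 * (1.0 - rho)
        ks = []
        doubled = []
        self.merged_amplified = (b == cn - b) and b >= 2
        for k in (1, cn - b, b):
            if k >= 1 and k not in ks:
                ks.append(k)
                # the factor 2 compensates the VAF >= rho/zeta cutoff for the
                # k=1 peak and, by the published convention, to the b-peak as
                # well; the merged b == CN-b peak follows the CN-b
                # (undoubled) rule.
                if k == 1:
                    doubled.append(True)
                elif k == b and not self.merged_amplified and b != cn - b:
                    doubled.append(True)
                else:
                    doubled.append(False)
        order = np.argsort(ks)
        self.multiplicities = tuple(int(ks[i]) for i in order)
        self.doubled = tuple(bool(doubled[i]) for i in order)
        self.peak_vafs = tuple(rho * k / self.zeta for k in self.multiplicities)

    @property
    def vaf_cutoff(self) -> float:
        return self.purity / self.zeta

    @property
    def n_peaks(self) -> int:
        return len(self.multiplicities)


@dataclass
class ClonalDecomposition:
    """MAP mixture weights and clonal mutation counts of one genomic class."""

    weights: dict  # multiplicity k -> weight
    counts: dict  # multiplicity k -> estimated clonal count (factor-2 applied)
    n_total_used: int  # mutations with VAF >= rho/zeta
    peak_vafs: dict
    mean_depth: float
    low_confidence: bool = False

    @property
    def n_single(self) -> float:
        return self.counts.get(1, 0.0)

    def amplified_counts(self, cn: int, b: int) -> dict:
        """Counts on amplified classes only (multiplicity >= 2)."""
        return {k: v for k, v in self.counts.items() if k >= 2}


def expected_clonal_vafs(cn: int, b: int, purity: float) -> ClonalPeakModel:
    """Peak model with deduplicated clonal peak VAFs rho*k/zeta."""
    return ClonalPeakModel(cn=cn, b_allele=b, purity=purity)


def _peak_log_pmf(n_var, depth, peak_model):
    """(n, K) matrix of binomial log-pmfs at each peak."""
    p = np.asarray(peak_model.peak_vafs)
    return stats.binom.logpmf(n_var[:, None], depth[:, None], np.clip(p[None, :], 0, 1))


def mixture_posterior(n_var, n_ref, peak_model: ClonalPeakModel, weights) -> float:
    """Log-posterior (flat prior; up to an additive constant) of peak weights.

    Only mutations with VAF >= rho/zeta enter; the caller is expected to have
    filtered, but the cutoff is re-applied defensively.
    """
    n_var = np.asarray(n_var, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    depth = n_var + n_ref
    keep = n_var / depth >= peak_model.vaf_cutoff
    n_var, depth = n_var[keep], depth[keep]
    if n_var.size == 0:
        raise ValueError("no clonal mutations above the VAF cutoff")
    w = np.asarray(weights, dtype=float)
    if w.shape != (peak_model.n_peaks,):
        raise ValueError("weight vector length must match number of peaks")
    log_pmf = _peak_log_pmf(n_var, depth, peak_model)
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    m = np.max(log_pmf + logw[None, :], axis=1)
    return float(np.sum(m + np.log(np.sum(np.exp(log_pmf + logw[None, :] - m[:, None]), axis=1))))


class ClonalBinomialMixture(BaseEstimator):
    """MAP fit of the clonal binomial mixture on one (CN, b) genomic class.

    Parameters
    ----------
    cn, b_allele, purity : define the peak model.
    n_restarts : random EM restarts from Dirichlet(1) draws (plus the
        uniform start); the best log-posterior wins.
    tol, max_iter : EM convergence controls.
    random_state : seed for the restarts.

    Attributes (after ``fit``)
    --------------------------
    weights_ : MAP mixture weights, one per deduplicated peak.
    decomposition_ : :class:`ClonalDecomposition` with clonal counts, where
        the factor 2 compensating the VAF cutoff is applied to the
        non-amplified (and, by the published convention, the b-) peak.
    """

    def __init__(self, cn=2, b_allele=1, purity=1.0, n_restarts=10, tol=1e-8,
                 max_iter=500, random_state=0):
        self.cn = cn
        self.b_allele = b_allele
        self.purity = purity
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on X = array-like of shape (n, 2) with columns (n_var, n_ref)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: n_var, n_ref")
        pm = expected_clonal_vafs(self.cn, self.b_allele, self.purity)
        n_var, n_ref = X[:, 0], X[:, 1]
        depth = n_var + n_ref
        if np.any(depth == 0):
            raise ValueError("zero-depth mutation")
        keep = n_var / depth >= pm.vaf_cutoff
        n_var, depth = n_var[keep], depth[keep]
        n_used = int(n_var.size)
        if n_used == 0:
            raise ValueError("no clonal mutations above the VAF cutoff")

        log_pmf = _peak_log_pmf(n_var, depth, pm)
        K = pm.n_peaks
        rng = np.random.default_rng(self.random_state)
        starts = [np.full(K, 1.0 / K)]
        starts += [rng.dirichlet(np.ones(K)) for _ in range(self.n_restarts)]
        best_w, best_lp = starts[0], -np.inf
        for w0 in starts:
            w, lp = self._em(log_pmf, w0)
            if lp > best_lp:
                best_w, best_lp = w, lp

        self.peak_model_ = pm
        self.weights_ = best_w
        self.log_posterior_ = best_lp
        counts = {}
        for k, w, dbl in zip(pm.multiplicities, best_w, pm.doubled):
            counts[k] = (2.0 if dbl else 1.0) * w * n_used
        self.decomposition_ = ClonalDecomposition(
            weights={k: float(w) for k, w in zip(pm.multiplicities, best_w)},
            counts={k: float(v) for k, v in counts.items()},
            n_total_used=n_used,
            peak_vafs={k: float(v) for k, v in zip(pm.multiplicities, pm.peak_vafs)},
            mean_depth=float(np.mean(depth)),
            low_confidence=n_used < MIN_MUTATIONS,
        )
        return self

    def _em(self, log_pmf, w0):
        w = np.array(w0, dtype=float)
        lp_old = -np.inf
        for _ in range(self.max_iter):
            with np.errstate(divide="ignore"):
                a = log_pmf + np.log(np.maximum(w, 1e-300))[None, :]
            m = np.max(a, axis=1, keepdims=True)
            r = np.exp(a - m)
            r /= np.sum(r, axis=1, keepdims=True)
            w = np.mean(r, axis=0)
            lp = float(np.sum(m[:, 0] + np.log(np.sum(np.exp(a - m), axis=1))))
            if lp - lp_old < self.tol:
                break
            lp_old = lp
        return w, lp


def fit_clonal_mixture(mutations, peak_model: ClonalPeakModel,
                       n_restarts: int = 10, random_state: int = 0) -> ClonalDecomposition:
    """Functional wrapper: fit the MAP mixture on a list of MutationCall."""
    X = np.array([[m.n_var, m.n_ref] for m in mutations], dtype=float)
    est = ClonalBinomialMixture(
        cn=peak_model.cn, b_allele=peak_model.b_allele, purity=peak_model.purity,
        n_restarts=n_restarts, random_state=random_state,
    ).fit(X)
    return est.decomposition_


def grid_map_weights(n_var, n_ref, peak_model: ClonalPeakModel, step: float = 0.01):
    """Exhaustive simplex grid search for the MAP weights (test oracle)."""
    n_var = np.asarray(n_var, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    depth = n_var + n_ref
    keep = n_var / depth >= peak_model.vaf_cutoff
    log_pmf = _peak_log_pmf(n_var[keep], depth[keep], peak_model)
    K = peak_model.n_peaks
    n_steps = int(round(1.0 / step))
    best, best_lp = None, -np.inf
    if K == 1:
        return np.array([1.0])
    grids = []
    if K == 2:
        for i in range(n_steps + 1):
            grids.append((i * step, 1.0 - i * step))
    else:
        for i in range(n_steps + 1):
            for j in range(n_steps + 1 - i):
                grids.append((i * step, j * step, 1.0 - (i + j) * step))
    for w in grids:
        w_arr = np.maximum(np.asarray(w), 0.0)
        with np.errstate(divide="ignore"):
            a = log_pmf + np.log(np.maximum(w_arr, 1e-300))[None, :]
        m = np.max(a, axis=1)
        lp = float(np.sum(m + np.log(np.sum(np.exp(a - m[:, None]), axis=1))))
        if lp > best_lp:
            best, best_lp = w_arr, lp
    return best
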