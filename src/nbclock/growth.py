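"""Neutral mutation accumulation during exponential tumor growth.

The tumor grows deterministically as N_T(t) = exp((lambda_T - delta_T) t)
while neutral SSNVs arise at rate mu*lambda_T*N_T(t) and drift as
supercritical birth-death clones.  The resulting site frequency spectrum
S(i, mu) gives the expected number of subclonal mutations per clone-size
window; clonal mutations (present in the founder cell) sit at cell
fraction f = 1 and are allocated across copy-number states in proportion
to k*g_k.  Cell fractions f map to variant allele frequencies via
VAF = f*rho*k/zeta with zeta = rho*k + 2(1-rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

F_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 2)  # lower bin edges 0.05..1.00

_LEGGAUSS_CACHE: dict = {}


def _leggauss(n: int):
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _LEGGAUSS_CACHE[n]


@dataclass
class GrowthParams:
    """Birth-death growth model of one tumor."""

    mu: float  # SSNVs per division
    delta_over_lambda: float  # relative loss rate delta_T/lambda_T in [0, 1)
    n_clonal: float = 0.0  # clonal SSNVs in the founder cell
    lambda_t: float = 1.0  # division rate (time unit)
    n_end: float = 1e9  # tumor size at diagnosis

    def __post_init__(self):
        if not (0.0 <= self.delta_over_lambda < 1.0):
            raise ValueError("delta_T/lambda_T must lie in [0, 1)")
        if self.mu < 0 or self.n_clonal < 0 or self.n_end < 1:
            raise ValueError("mu, n_clonal >= 0 and n_end >= 1 required")

    @property
    def delta_t(self) -> float:
        return self.delta_over_lambda * self.lambda_t

    @property
    def t_end(self) -> float:
        """Growth duration to n_end cells at net rate lambda - delta."""
        return math.log(self.n_end) / (self.lambda_t - self.delta_t)

    @property
    def mu_eff(self) -> float:
        """Mutations per effective (net-growth) division, mu/(1 - delta/lambda)."""
        return self.mu / (1.0 - self.delta_over_lambda)


def _alpha_beta(params: GrowthParams, t):
    """Extinction and geometric parameters of the birth-death clone law."""
    lam, dlt = params.lambda_t, params.delta_t
    t = np.asarray(t, dtype=float)
    e = np.exp((lam - dlt) * t)
    denom = lam * e - dlt
    alpha = dlt * (e - 1.0) / denom
    beta = lam * (e - 1.0) / denom
    return alpha, beta


def clone_size_dist(i, t, params: GrowthParams):
    """P_{1,i}: probability a clone founded by one cell has i cells at age t.

    Geometric with an extinction atom: P(0) = alpha(t),
    P(i) = (1-alpha)(1-beta) beta^(i-1) for i >= 1.
    """
    alpha, beta = _alpha_beta(params, t)
    i = np.asarray(i)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(
            i == 0,
            alpha,
            (1.0 - alpha) * (1.0 - beta) * np.where(i >= 1, beta ** np.maximum(i - 1, 0), 0.0),
        )
    return p


def site_frequency_spectrum(a: float, b: float, params: GrowthParams,
                            epsrel: float = 1e-6) -> float:
    """Expected number of subclonal mutations in clone-size window [a, b].

    The sum over clone sizes is replaced by its integral (geometric in i, so
    the inner integral is analytic); the outer integral over mutation birth
    times uses adaptive quadrature.
    """
    if a > b:
        raise ValueError("window requires a <= b")
    lam, t_end = params.lambda_t, params.t_end

    def integrand(t):
        u = t_end - t
        alpha, beta = _alpha_beta(params, u)
        if beta <= 0.0:
            return 0.0
        lb = math.log(beta)
        inner = (math.exp((b - 1.0) * lb) - math.exp((a - 1.0) * lb)) / lb
        return params.mu * lam * math.exp((lam - params.delta_t) * t) * (1.0 - alpha) * (1.0 - beta) * inner

    val, _ = integrate.quad(integrand, 0.0, t_end, epsrel=epsrel, limit=400)
    return float(val)


def n_subclonal(params: GrowthParams) -> float:
    """Total expected subclonal mutation count (clone sizes 1..n_end).

    Evaluated with the same integral approximation of the clone-size sum as
    the windowed spectrum, so windows tile consistently.
    """
    return site_frequency_spectrum(1.0, params.n_end, params)


def sfs_bin_counts(params: GrowthParams, f_grid=None, n_nodes: int = 160) -> np.ndarray:
    """Expected subclonal counts in f-bins [f, f+0.05), vectorized.

    Fixed-order Gauss-Legendre over mutation birth times with the analytic
    clone-size integral per bin; used by the ABC forward model where
    thousands of evaluations are needed.  f bins start at 0.05; the last
    bin [1.00, ...] is empty by construction (f <= 1).
    """
    if f_grid is None:
        f_grid = F_GRID
    edges = np.append(f_grid, f_grid[-1] + 0.05) * params.n_end
    x, w = _leggauss(n_nodes)
    t = 0.5 * params.t_end * (x + 1.0)
    wt = 0.5 * params.t_end * w
    u = params.t_end - t
    alpha, beta = _alpha_beta(params, u)
    good = beta > 0
    lb = np.log(beta[good])
    rate = params.mu * params.lambda_t * np.exp((params.lambda_t - params.delta_t) * t[good])
    pref = rate * (1.0 - alpha[good]) * (1.0 - beta[good]) / lb
    # counts per bin: analytic integral over i of beta^(i-1) between edges;
    # pref includes the 1/log(beta) factor, so bin = edge[j+1] - edge[j].
    expo = np.exp(np.clip((edges[None, :] - 1.0) * lb[:, None], -745.0, 0.0))
    per_edge = np.sum(wt[good][:, None] * pref[:, None] * expo, axis=0)
    return np.maximum(per_edge[1:] - per_edge[:-1], 0.0)


def allocate_clonal(n_clonal: float, cn_profile) -> dict:
    """Distribute clonal mutations over CN states: n_{1,k} ~ k*g_k.

    cn_profile: mapping k -> genome length (or fraction) at copy number k.
    """
    ks = sorted(cn_profile)
    denom = sum(k * cn_profile[k] for k in ks)
    if denom == 0:
        raise ValueError("empty copy-number profile")
    return {k: n_clonal * k * cn_profile[k] / denom for k in ks}


def f_to_vaf(f, purity: float, cn: int, multiplicity: int = 1):
    """Cell fraction -> variant allele frequency: VAF = f*rho*k/zeta."""
    zeta = purity * cn + 2.0 * (1.0 - purity)
    return np.asarray(f, dtype=float) * purity * multiplicity / zeta


def vaf_to_f(vaf, purity: float, cn: int, multiplicity: int = 1):
    """Inverse of :func:`f_to_vaf`."""
    zeta = purity * cn + 2.0 * (1.0 - purity)
    return np.asarray(vaf, dtype=float) * zeta / (purity * multiplicity)


@dataclass
class VafHistogram:
    """Per-CN-state VAF data with cumulative counts on the 0.05 f-grid.

    cumulative[k][j] = number of mutations with VAF_k > f_grid[j], after
    genome extrapolation by sum(g)/g_k.
    """

    vafs: dict  # k -> array of VAFs (merged, single-copy-equivalent)
    g_k: dict  # k -> genome length at copy number k
    mean_depth: dict  # k -> average coverage C_k
    purity: float
    f_grid: np.ndarray = field(default_factory=lambda: F_GRID.copy())
    extrapolated: bool = True

    def cumulative(self) -> dict:
        out = {}
        g_tot = sum(self.g_k.values())
        for k, v in self.vafs.items():
            counts = np.array([(np.asarray(v) > f).sum() for f in self.f_grid], dtype=float)
            if self.extrapolated:
                counts *= g_tot / self.g_k[k]
            out[k] = counts
        return out


def simulate_vaf_histogram(params: GrowthParams, cn_profile: dict, purity: float,
                           mean_depth: dict, seed, f_grid=None) -> VafHistogram:
    """Forward model: sample a per-CN-state VAF histogram.

    Clonal mutations (n_clonal, allocated ~ k*g_k and scaled to genome
    equivalents) get VAF rho/zeta_k; subclonal counts per 0.05 f-bin are
    Poisson draws around the expected site frequency spectrum at n_end,
    evaluated at the lower bin edge.  Every mutation receives Poisson
    coverage (floored at 1 read) and a binomial read draw.

    cn_profile: k -> genome length; CN states above 4 or totalling < 1e8 bp
    are the caller's responsibility to exclude (see prepare_vaf_data).
    """
    if not cn_profile:
        raise ValueError("empty copy-number profile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if f_grid is None:
        f_grid = F_GRID
    g_tot = sum(cn_profile.values())
    clonal = allocate_clonal(params.n_clonal, cn_profile)
    sub_bins = sfs_bin_counts(params, f_grid=f_grid)
    vafs = {}
    for k in sorted(cn_profile):
        zeta = purity * k + 2.0 * (1.0 - purity)
        depth_k = mean_depth[k]
        vlist = []
        # clonal peak at genome scale (extrapolation factor g_tot/g_k)
        n_cl = rng.poisson(clonal[k] * g_tot / cn_profile[k])
        if n_cl > 0:
            cov = _pois_min1(rng, depth_k, n_cl)
            reads = rng.binomial(cov, min(purity / zeta, 1.0))
            vlist.append(reads / cov)
        # subclonal tail from the SFS (already genome-wide)
        for f, lam_count in zip(f_grid, sub_bins):
            n_sub = rng.poisson(lam_count)
            if n_sub == 0:
                continue
            cov = _pois_min1(rng, depth_k, n_sub)
            p = min(f * purity / zeta, 1.0)
            reads = rng.binomial(cov, p)
            vlist.append(reads / cov)
        vafs[k] = np.concatenate(vlist) if vlist else np.empty(0)
    return VafHistogram(
        vafs=vafs, g_k=dict(cn_profile),
        mean_depth=dict(mean_depth), purity=purity,
        f_grid=np.asarray(f_grid), extrapolated=False,
    )


def _pois_min1(rng, lam, size):
    cov = rng.poisson(lam, size=size)
    while np.any(cov == 0):  # depth floor: redraw zero-coverage sites
        z = cov == 0
        cov[z] = rng.poisson(lam, size=int(z.sum()))
    return cov
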