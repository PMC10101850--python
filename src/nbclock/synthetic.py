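"""Forward generators and brute-force stochastic oracles.

``generate_tumor`` inverts the timing analysis: clonal SSNVs are placed at
multiplicity-determined VAFs (amplified clonal mutations on gained alleles
at the ECA density, single-copy clonal mutations filling up the per-copy
MRCA density, plus a false-positive fraction emulating incomplete tumor
sampling), a subclonal tail follows the birth-death site frequency
spectrum, and reads are drawn with Poisson depth and binomial sampling.

``simulate_two_hit_process`` and ``simulate_birth_death_sfs`` are explicit
branching-process simulators used as independent oracles for the
initiation-model closed forms and the SFS integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import MutationCall, SegmentProfile, TumorSample
from .growth import GrowthParams, sfs_bin_counts, F_GRID
from .initiation import InitiationParams, sample_event_times, second_hit_survival
from .timing import HAPLOID_GENOME_BP


def spawn_rngs(seed: int, n: int):
    """Independent child generators from one master seed (counter-based)."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# ----------------------------------------------------------------------
# single-tumor generator
# ----------------------------------------------------------------------

@dataclass
class SyntheticSegmentSpec:
    chrom: str
    size_bp: float
    cn: int
    b: int
    timing: str = "none"  # "eca" | "mrca" | "none" (no gain / untimed)


@dataclass
class TumorSpec:
    """Study conditions for one synthetic tumor."""

    purity: float = 0.9
    depth: float = 80.0
    mrca_density_per_mb: float = 0.06  # per-copy clonal SSNVs per Mb
    eca_density_per_mb: float = 0.01  # amplified clonal SSNVs per Mb on ECA gains
    fp_fraction: float = 0.15  # spurious clonal calls from incomplete sampling
    segments: list = field(default_factory=list)
    growth_mu: float = 4.0  # SSNVs per division during growth (subclonal tail)
    growth_delta_over_lambda: float = 0.9
    sample_id: str = "synthetic"
    age_days: float = 365.0
    sample_type: str = "primary"
    tmm: str = "ALT"

    def __post_init__(self):
        if self.eca_density_per_mb > self.mrca_density_per_mb:
            raise ValueError("ECA density cannot exceed the MRCA density")
        if not self.segments:
            self.segments = _default_segments()


def _default_segments():
    """A near-triploid profile: triploidization as the (candidate) early
    event, two tetrasomic MRCA-coincident gains, disomic background."""
    tri = [("1", 249e6), ("2", 243e6), ("3", 198e6), ("4", 191e6), ("5", 181e6)]
    tet = [("9", 141e6), ("20", 63e6)]
    dis = [("6", 171e6), ("7", 159e6), ("8", 146e6), ("10", 135e6),
           ("11", 135e6), ("12", 134e6), ("13", 115e6), ("14", 107e6),
           ("15", 103e6), ("16", 90e6), ("17", 81e6), ("18", 78e6)]
    segs = [SyntheticSegmentSpec(c, s, 3, 1, "eca") for c, s in tri]
    segs += [SyntheticSegmentSpec(c, s, 4, 2, "mrca") for c, s in tet]
    segs += [SyntheticSegmentSpec(c, s, 2, 1, "none") for c, s in dis]
    return segs


def late_tumor_spec(**overrides) -> TumorSpec:
    """Late-MRCA tumor: early triploidization (ECA 0.01/Mb), MRCA 0.06/Mb."""
    return TumorSpec(**overrides)


def early_tumor_spec(**overrides) -> TumorSpec:
    """Early-MRCA tumor: a single aneuploidization event at 0.03 SSNVs/Mb
    (all gains coincident with the MRCA)."""
    defaults = dict(mrca_density_per_mb=0.03, eca_density_per_mb=0.03)
    defaults.update(overrides)
    spec = TumorSpec(**defaults)
    for seg in spec.segments:
        if seg.timing == "eca":
            seg.timing = "mrca"
    return spec


@dataclass
class SyntheticTruth:
    """Ground truth of one generated tumor (JSON-serializable)."""

    mrca_density_per_mb: float
    eca_density_per_mb: float
    class_timing: dict  # "(cn,b)" -> "eca"|"mrca"|"none"
    evolution_class: str
    purity: float
    depth: float
    fp_fraction: float
    seed: int

    def to_dict(self):
        return asdict(self)


def generate_tumor(spec: TumorSpec, seed: int):
    """Generate a (TumorSample, SyntheticTruth) pair under ``spec``.

    Amplified clonal mutations are drawn per gained allele class at the ECA
    density (or at the per-copy MRCA density for MRCA-coincident gains);
    single-copy clonal mutations fill the per-copy density up to the MRCA,
    inflated by fp/(1-fp) spurious clonal calls so that the downstream
    (1-fp) correction is unbiased.  The subclonal tail follows the expected
    birth-death spectrum with Poisson noise.
    """
    rng = np.random.default_rng(seed)
    rho = spec.purity
    m_m = spec.mrca_density_per_mb * 1e-6  # per-copy clonal density, per bp
    m_e = spec.eca_density_per_mb * 1e-6
    g_tot = sum(s.size_bp for s in spec.segments)
    ploidy = sum(s.cn * s.size_bp for s in spec.segments) / g_tot
    zeta_bar = rho * ploidy + 2.0 * (1.0 - rho)

    segments, mutations = [], []
    sub_bins = sfs_bin_counts(GrowthParams(
        mu=spec.growth_mu, delta_over_lambda=spec.growth_delta_over_lambda))
    class_timing = {}
    for seg_id, s in enumerate(spec.segments):
        start, end = 0, int(s.size_bp)
        zeta = rho * s.cn + 2.0 * (1.0 - rho)
        segments.append(SegmentProfile(
            chrom=s.chrom, start=start, end=end, cn=s.cn, b_allele=s.b,
            coverage_ratio=zeta / zeta_bar, baf=s.b / s.cn,
        ))
        class_timing[f"({s.cn},{s.b})"] = s.timing

        amp_classes = [k for k in {s.b, s.cn - s.b} if k >= 2]
        n_amp_classes = int(s.b >= 2) + int(s.cn - s.b >= 2)
        amp_dens = m_e if s.timing == "eca" else (m_m if s.timing == "mrca" else 0.0)

        def emit(n, mult):
            n = int(n)
            if n <= 0:
                return
            pos = rng.integers(start, end, size=n)
            cov = rng.poisson(spec.depth * zeta / zeta_bar, size=n)
            cov = np.maximum(cov, 1)
            p = min(rho * mult / zeta, 1.0)
            reads = rng.binomial(cov, p)
            for j in range(n):
                if reads[j] < 1:
                    continue
                mutations.append(MutationCall(
                    chrom=s.chrom, pos=int(pos[j]), n_var=int(reads[j]),
                    n_ref=int(cov[j] - reads[j]), segment_id=seg_id,
                ))

        # amplified clonal mutations: one draw per gained allele class
        amp_per_copy = 0.0
        for k in amp_classes:
            reps = n_amp_classes if len(amp_classes) == 1 and n_amp_classes == 2 else 1
            for _ in range(reps):
                emit(rng.poisson(amp_dens * s.size_bp), k)
                amp_per_copy += amp_dens * k
        # single-copy clonal: biological remainder + false-positive inflation
        n1_bio = max(s.cn * m_m - amp_per_copy, 0.0) * s.size_bp
        n1_fp = spec.fp_fraction / (1.0 - spec.fp_fraction) * s.cn * m_m * s.size_bp
        emit(rng.poisson(n1_bio + n1_fp), 1)
        # subclonal tail allocated by genome fraction, single copy
        for f, lam in zip(F_GRID, sub_bins):
            n_sub = rng.poisson(lam * s.size_bp / g_tot)
            if n_sub:
                pos = rng.integers(start, end, size=n_sub)
                cov = np.maximum(rng.poisson(spec.depth * zeta / zeta_bar, size=n_sub), 1)
                reads = rng.binomial(cov, min(f * rho / zeta, 1.0))
                for j in range(n_sub):
                    if reads[j] >= 1:
                        mutations.append(MutationCall(
                            chrom=s.chrom, pos=int(pos[j]), n_var=int(reads[j]),
                            n_ref=int(cov[j] - reads[j]), segment_id=seg_id,
                        ))

    sample = TumorSample(
        sample_id=spec.sample_id, purity=rho, ploidy=ploidy,
        age_days=spec.age_days, sample_type=spec.sample_type, tmm=spec.tmm,
        segments=segments, mutations=mutations,
    )
    has_eca = any(s.timing == "eca" for s in spec.segments)
    truth = SyntheticTruth(
        mrca_density_per_mb=spec.mrca_density_per_mb,
        eca_density_per_mb=spec.eca_density_per_mb if has_eca else None,
        class_timing=class_timing,
        evolution_class="early" if spec.mrca_density_per_mb < 0.05 else "late",
        purity=rho, depth=spec.depth, fp_fraction=spec.fp_fraction, seed=seed,
    )
    return sample, truth


# ----------------------------------------------------------------------
# two-hit Gillespie oracle
# ----------------------------------------------------------------------

def _first_hit_times(params: InitiationParams, t_max: float, rng) -> np.ndarray:
    """Inhomogeneous-Poisson first-event times on the deterministic N(t)."""
    lam1, lam2 = params.lambda1, params.lambda2
    r1 = lam1 - params.delta1
    r2 = params.lambda2 - params.delta2
    T = min(params.T, t_max)
    mu1 = params.mu1
    # phase 1: rate mu1*lam1*e^{r1 t}
    big1 = mu1 * lam1 * (math.exp(r1 * T) - 1.0) / r1
    n1 = rng.poisson(big1)
    u = rng.uniform(0.0, big1, size=n1)
    times = list(np.log(u * r1 / (mu1 * lam1) + 1.0) / r1)
    if t_max > params.T:
        dt = t_max - params.T
        NT = params.n_peak
        if abs(r2) < 1e-12:
            big2 = mu1 * lam2 * NT * dt
            n2 = rng.poisson(big2)
            times += list(params.T + rng.uniform(0.0, dt, size=n2))
        else:
            big2 = mu1 * lam2 * NT * (math.exp(r2 * dt) - 1.0) / r2
            n2 = rng.poisson(big2)
            u = rng.uniform(0.0, big2, size=n2)
            times += list(params.T + np.log(u * r2 / (mu1 * lam2 * NT) + 1.0) / r2)
    return np.sort(np.array(times))


def simulate_two_hit_process(params: InitiationParams, t_max: float,
                             n_reps: int, seed: int, record: str = "first"):
    """Gillespie-style oracle for the two-hit initiation model.

    First-hit clones branch with rates (lambda1, delta1) before the peak and
    (lambda2, delta2/r) after; each division spawns a second hit with
    probability mu2, which survives with the phase's ultimate survival
    probability nu2.

    Returns a dict with per-replicate earliest surviving second-hit times
    "t2" (inf = none) and the founding first-hit times "t1".  With
    ``record="all"``, every surviving second hit is additionally collected
    in "t1_all"/"t2_all" (clones then always run to t_max): this is the
    event ensemble whose conditional first-hit law the closed form P(t1|t2)
    describes — restricting to first successes size-biases against early
    clones, a selection the mean-field conditional does not model.
    """
    rng = np.random.default_rng(seed)
    T = params.T
    nu_e = second_hit_survival(params, "expansion")
    nu_d = second_hit_survival(params, "decay", clip=True)
    lam1, d1 = params.lambda1, params.delta1
    lam2, d2r = params.lambda2, params.delta2 / params.r
    mu2 = params.mu2
    t2_rep = np.full(n_reps, np.inf)
    t1_rep = np.full(n_reps, np.inf)
    t1_all, t2_all = [], []
    for rep in range(n_reps):
        best_t2, best_t1 = np.inf, np.inf
        for tau in _first_hit_times(params, t_max, rng):
            horizon = t_max if record == "all" else min(t_max, best_t2)
            t, m = tau, 1
            while m > 0 and t < horizon:
                if t < T:
                    birth, death = lam1, d1
                else:
                    birth, death = lam2, d2r
                rate = m * (birth + death)
                dt = rng.exponential(1.0 / rate)
                if t < T < t + dt:
                    t = T  # memoryless re-draw at the phase boundary
                    continue
                t += dt
                if t >= horizon:
                    break
                if rng.random() < birth / (birth + death):
                    m += 1
                    if rng.random() < mu2:
                        nu = nu_e if t <= T else nu_d
                        if rng.random() < nu:
                            if record == "all":
                                t1_all.append(tau)
                                t2_all.append(t)
                            if t < best_t2:
                                best_t2, best_t1 = t, tau
                else:
                    m -= 1
        t2_rep[rep], t1_rep[rep] = best_t2, best_t1
    out = {"t2": t2_rep, "t1": t1_rep}
    if record == "all":
        out["t1_all"] = np.array(t1_all)
        out["t2_all"] = np.array(t2_all)
    return out


def empirical_p_mrca(sim: dict, eval_times) -> tuple:
    """(estimate, MC standard error) of P_MRCA at each evaluation time."""
    t2 = sim["t2"]
    n = len(t2)
    est = np.array([(t2 <= t).mean() for t in np.atleast_1d(eval_times)])
    se = np.sqrt(np.maximum(est * (1 - est), 1e-12) / n)
    return est, se


# ----------------------------------------------------------------------
# birth-death SFS oracle
# ----------------------------------------------------------------------

def simulate_birth_death_sfs(params: GrowthParams, n_end: int, n_reps: int,
                             seed: int, windows, condition: str = "size"):
    """Lineage-tracking birth-death oracle for the site frequency spectrum.

    Attaches Poisson(mu/2) mutations to each daughter branch and counts
    mutations whose final clone size falls in each [a, b] window.

    condition="size": grow to ``n_end`` cells, restarting on extinction
    (the observable-tumor ensemble; mildly inflated near fixation relative
    to the mean-field integral).  condition="none": run to the fixed time
    t_end = log(n_end)/(lambda-delta) with extinct replicates contributing
    zero — by the branching property this ensemble's mean equals the
    spectrum integral exactly, making it the unbiased oracle.

    Returns (mean_counts, se_counts, per_rep_counts).
    """
    rng = np.random.default_rng(seed)
    lam, dlt = params.lambda_t, params.delta_t
    p_birth = lam / (lam + dlt)
    half_mu = params.mu / 2.0
    windows = [(int(a), int(b)) for a, b in windows]
    t_end = math.log(n_end) / (lam - dlt) if condition == "none" else None
    per_rep = np.zeros((n_reps, len(windows)))
    for rep in range(n_reps):
        while True:
            parent = [-1]
            nmut = [0]
            alive = [0]
            t = 0.0
            extinct = False
            while True:
                if not alive:
                    extinct = True
                    break
                if condition == "size":
                    if len(alive) >= n_end:
                        break
                else:
                    t += rng.exponential(1.0 / ((lam + dlt) * len(alive)))
                    if t >= t_end:
                        break
                j = rng.integers(len(alive))
                cell = alive[j]
                alive[j] = alive[-1]
                alive.pop()
                if rng.random() < p_birth:
                    for _ in range(2):
                        parent.append(cell)
                        nmut.append(rng.poisson(half_mu))
                        alive.append(len(parent) - 1)
            if condition == "none" or not extinct:
                break
        sizes = np.zeros(len(parent), dtype=np.int64)
        for cell in alive:
            c = cell
            while c != -1:
                sizes[c] += 1
                c = parent[c]
        nm = np.asarray(nmut)
        for w, (a, b) in enumerate(windows):
            sel = (sizes >= a) & (sizes <= b)
            per_rep[rep, w] = nm[sel].sum()
    mean = per_rep.mean(axis=0)
    se = per_rep.std(axis=0, ddof=1) / math.sqrt(n_reps)
    return mean, se, per_rep


# ----------------------------------------------------------------------
# cohort generator
# ----------------------------------------------------------------------

def generate_cohort(params: InitiationParams, n: int, seed: int, t_max: float,
                    genome_bp: float = HAPLOID_GENOME_BP):
    """Cohort of (t1, t2, ECA/MRCA densities) under the initiation model.

    Censored draws (no tumor by t_max) carry infinite densities.  Synthetic
    95% CIs use the Poisson-count normal approximation, giving the
    incidence-curve uncertainties the analysis expects.
    """
    rng = np.random.default_rng(seed)
    t1, t2 = sample_event_times(params, n, rng, t_max=t_max)
    fin = np.isfinite(t2)
    cnt_m = np.where(fin, rng.poisson(params.mu * np.where(fin, t2, 0.0)), np.inf)
    cnt_e = np.where(fin, rng.poisson(params.mu * np.where(fin, t1, 0.0)), np.inf)
    half = 1.96 * np.sqrt(np.maximum(cnt_m, 1.0))
    half_e = 1.96 * np.sqrt(np.maximum(cnt_e, 1.0))
    return {
        "t1": t1, "t2": t2,
        "m_mrca": cnt_m / genome_bp,
        "m_mrca_lo": np.maximum(cnt_m - half, 0.0) / genome_bp,
        "m_mrca_hi": (cnt_m + half) / genome_bp,
        "m_eca": cnt_e / genome_bp,
        "m_eca_lo": np.maximum(cnt_e - half_e, 0.0) / genome_bp,
        "m_eca_hi": (cnt_e + half_e) / genome_bp,
    }
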