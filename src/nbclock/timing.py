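"""Molecular-clock timing of the MRCA and of clonal chromosomal gains (ECA).

The density of non-amplified clonal SSNVs times the most recent common
ancestor (MRCA) of the resected tumor; the density of amplified clonal SSNVs
on a gained segment times the gain itself.  Gains whose amplified density is
significantly below the MRCA density (negative-binomial test, Holm-corrected
at 0.01) predate the MRCA and define an early common ancestor (ECA).
Densities are SSNVs per haploid basepair throughout; 1 SSNV/Mb = 1e-6 per bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import TumorSample
from .io import merge_segment_classes
from .mixture import ClonalBinomialMixture

EARLY_LATE_THRESHOLD_PER_MB = 0.05  # SSNVs per Mb; >= threshold = late
DEFAULT_FP = 0.15  # fraction of apparently-clonal mutations that are sampling artifacts
HAPLOID_GENOME_BP = 3.3e9


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------

def per_copy_clonal_count(counts: dict, cn: int, b: int) -> float:
    """Clonal mutations per chromosome copy acquired up to the MRCA.

    n_l = (n_1 + n_{CN-b}*(CN-b) + n_b*b) / CN, with missing classes as 0.
    """
    if cn == 0:
        raise ValueError("CN=0 segment cannot be timed")
    n1 = counts.get(1, 0.0)
    total = n1
    for k, n in counts.items():
        if k >= 2:
            total += n * k
    return total / cn


def test_segment_pre_mrca(n_amp: float, g_seg: float, g: float, m_mrca: float) -> float:
    """One-sided negative-binomial test that a gain predates the MRCA.

    Under the null (gain coincident with the MRCA) the amplified clonal count
    on a segment of size g_seg follows a negative binomial with size m_MRCA
    and success probability p = 1/(1 + g_seg/g) — overdispersed around the
    expectation m_MRCA * g_seg/g.  Returns P(X <= n_amp); small values mean
    significantly fewer amplified mutations than expected, i.e. an early gain.
    """
    if g_seg > g:
        raise ValueError("segment cannot exceed the retained genome")
    if m_mrca <= 0:
        raise ValueError("m_mrca must be positive")
    if g_seg == 0:
        return 1.0
    p = 1.0 / (1.0 + g_seg / g)
    # scipy's nbinom counts failures with success prob p; survival/CDF via
    # the regularized incomplete beta — stable up to m ~ 1e5 and beyond.
    return float(stats.nbinom.cdf(np.floor(n_amp), m_mrca, p))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never smaller than raw)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def classify_evolution(m_mrca_density_per_bp: float) -> str:
    """Early- vs late-MRCA class at the 0.05 SSNVs/Mb bimodality threshold.

    Densities exactly at the threshold are late (the threshold is the upper
    border of the early mode); a 1e-9 relative guard absorbs float noise
    from unit conversion.
    """
    per_mb = m_mrca_density_per_bp * 1e6
    return "early" if per_mb < EARLY_LATE_THRESHOLD_PER_MB * (1.0 - 1e-9) else "late"


@dataclass
class ClockCalibration:
    """Real-time calibration of the mutation clock.

    daily_rate_diploid: mu*lambda, SSNVs per day per diploid genome.
    haploid_divisor: converts the diploid rate to the haploid scale of the
    densities (default 2).  Mutation counting starts at gastrulation
    (~2 weeks post conception), hence the 14-day offset.
    """

    daily_rate_diploid: float
    daily_rate_sd: float = 0.0
    haploid_divisor: float = 2.0
    genome_bp: float = HAPLOID_GENOME_BP
    gastrulation_offset_days: float = 14.0

    def __post_init__(self):
        if self.daily_rate_diploid <= 0 or self.haploid_divisor <= 0 or self.genome_bp <= 0:
            raise ValueError("calibration rates must be positive")


def density_to_weeks_pc(m_density_per_bp: float, calibration: ClockCalibration):
    """Convert a haploid SSNV density to weeks post conception.

    t = 14 d + m * genome_bp / (rate/d); the uncertainty of the daily rate is
    propagated linearly.  Returns (weeks_pc, sd_weeks).
    """
    rate_h = calibration.daily_rate_diploid / calibration.haploid_divisor
    span = m_density_per_bp * calibration.genome_bp / rate_h
    t_days = calibration.gastrulation_offset_days + span
    sd_days = span * calibration.daily_rate_sd / calibration.daily_rate_diploid
    return t_days / 7.0, sd_days / 7.0


# ----------------------------------------------------------------------
# per-tumor timing estimator
# ----------------------------------------------------------------------

@dataclass
class SegmentTiming:
    """Timing diagnostics of one gained genomic class."""

    cn: int
    b: int
    size_bp: float
    amplified_size_bp: float
    n_amp: float
    amp_density: float  # amplified clonal SSNVs per amplified-allele bp
    p_raw: Optional[float] = None
    p_adj: Optional[float] = None
    assignment: str = "MRCA"  # "ECA" | "MRCA" | "excluded-higher"
    eca_conformity_p: Optional[float] = None


@dataclass
class TimingResult:
    sample_id: str
    m_mrca_count: float
    m_mrca_density: float  # per haploid bp
    mrca_ci95: tuple
    m_eca_density: Optional[float]
    eca_ci95: Optional[tuple]
    evolution_class: str
    per_segment: list = field(default_factory=list)
    genome_bp: float = 0.0

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "m_mrca_count": self.m_mrca_count,
            "m_mrca_density_per_bp": self.m_mrca_density,
            "m_mrca_density_per_mb": self.m_mrca_density * 1e6,
            "mrca_ci95_per_bp": list(self.mrca_ci95),
            "m_eca_density_per_bp": self.m_eca_density,
            "m_eca_density_per_mb": (None if self.m_eca_density is None
                                     else self.m_eca_density * 1e6),
            "eca_ci95_per_bp": None if self.eca_ci95 is None else list(self.eca_ci95),
            "evolution_class": self.evolution_class,
            "genome_bp": self.genome_bp,
            "per_segment": [
                {
                    "cn": s.cn, "b": s.b, "size_bp": s.size_bp,
                    "amplified_size_bp": s.amplified_size_bp,
                    "n_amp": s.n_amp, "amp_density_per_bp": s.amp_density,
                    "p_raw": s.p_raw, "p_adj": s.p_adj,
                    "assignment": s.assignment,
                    "eca_conformity_p": s.eca_conformity_p,
                }
                for s in self.per_segment
            ],
        }


class MrcaEcaTimer(BaseEstimator):
    """Estimate MRCA and ECA mutation densities for one tumor sample.

    Parameters
    ----------
    fp : fraction of apparently-clonal SSNVs attributed to incomplete
        sampling; the MRCA count is multiplied by (1 - fp).
    n_boot : bootstrap resamples of the genomic classes for the 95% CIs.
    alpha : Holm-adjusted significance level for calling a gain pre-MRCA.
    merge_by : "cn_b" pools segments of equal allelic state genome-wide;
        "chrom" keeps chromosomes separate.
    n_restarts, random_state : forwarded to the mixture fits / bootstrap.

    Attributes (after ``fit``)
    --------------------------
    result_ : :class:`TimingResult`
    m_mrca_density_, m_eca_density_, evolution_class_ : shortcuts.
    """

    def __init__(self, fp=DEFAULT_FP, n_boot=1000, alpha=0.01, merge_by="cn_b",
                 n_restarts=10, random_state=0):
        self.fp = fp
        self.n_boot = n_boot
        self.alpha = alpha
        self.merge_by = merge_by
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _decompose(self, sample: TumorSample):
        classes = merge_segment_classes(sample, merge_by=self.merge_by)
        units = []
        for g in classes:
            muts = g["mutations"]
            if len(muts) == 0:
                continue
            X = np.array([[m.n_var, m.n_ref] for m in muts], dtype=float)
            try:
                est = ClonalBinomialMixture(
                    cn=g["cn"], b_allele=g["b"], purity=sample.purity,
                    n_restarts=self.n_restarts, random_state=self.random_state,
                ).fit(X)
            except ValueError:
                continue  # no mutations above the clonal cutoff
            units.append({
                "cn": g["cn"], "b": g["b"], "size_bp": float(g["size_bp"]),
                "decomp": est.decomposition_,
            })
        return units

    def fit(self, sample: TumorSample, y=None):
        units = self._decompose(sample)
        if not units:
            raise ValueError("no timeable genomic classes with clonal mutations")
        rng = np.random.default_rng(self.random_state)

        n_l = np.array([per_copy_clonal_count(u["decomp"].counts, u["cn"], u["b"])
                        for u in units])
        g_l = np.array([u["size_bp"] for u in units])
        g = float(np.sum(g_l))
        m_mrca = float(np.sum(n_l)) * (1.0 - self.fp)
        m_density = m_mrca / g

        # segment-level bootstrap of the pooled density
        idx = rng.integers(0, len(units), size=(self.n_boot, len(units)))
        boot = (np.sum(n_l[idx], axis=1) * (1.0 - self.fp)) / np.sum(g_l[idx], axis=1)
        mrca_ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

        # gained classes: amplified clonal densities and the pre-MRCA test
        gained = []
        for u in units:
            amp = {k: v for k, v in u["decomp"].counts.items() if k >= 2}
            if not amp:
                continue
            n_amp = float(sum(amp.values()))
            # one segment length per amplified allele class (b and CN-b are
            # separate classes even when their peaks coincide, e.g. CN=4 b=2)
            n_classes = int(u["b"] >= 2) + int(u["cn"] - u["b"] >= 2)
            amp_len = float(n_classes * u["size_bp"])
            gained.append(SegmentTiming(
                cn=u["cn"], b=u["b"], size_bp=u["size_bp"],
                amplified_size_bp=amp_len, n_amp=n_amp,
                amp_density=n_amp / amp_len,
            ))

        testable = []
        for st in gained:
            if st.amp_density > m_density:
                st.assignment = "excluded-higher"
            else:
                testable.append(st)
        if testable and m_mrca > 0:
            raw = [test_segment_pre_mrca(st.n_amp, st.amplified_size_bp, g, m_mrca)
                   for st in testable]
            adj = holm_adjust(raw)
            for st, pr, pa in zip(testable, raw, adj):
                st.p_raw, st.p_adj = float(pr), float(pa)
                st.assignment = "ECA" if pa <= self.alpha else "MRCA"

        eca_segments = [st for st in gained if st.assignment == "ECA"]
        m_eca_density, eca_ci = None, None
        if eca_segments:
            n_amp = np.array([st.n_amp for st in eca_segments])
            g_amp = np.array([st.amplified_size_bp for st in eca_segments])
            m_eca = float(np.sum(n_amp))
            g_eca = float(np.sum(g_amp))
            m_eca_density = m_eca / g_eca
            idx = rng.integers(0, len(eca_segments), size=(self.n_boot, len(eca_segments)))
            boot = np.sum(n_amp[idx], axis=1) / np.sum(g_amp[idx], axis=1)
            eca_ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
            # two-sided conformity of each contributing class with the pooled ECA
            for st in eca_segments:
                if m_eca <= 0:
                    st.eca_conformity_p = 1.0
                    continue
                lo = test_segment_pre_mrca(st.n_amp, st.amplified_size_bp, g_eca, m_eca)
                hi = 1.0 - test_segment_pre_mrca(st.n_amp - 1, st.amplified_size_bp,
                                                 g_eca, m_eca)
                st.eca_conformity_p = float(min(1.0, 2.0 * min(lo, hi)))

        self.result_ = TimingResult(
            sample_id=sample.sample_id,
            m_mrca_count=m_mrca,
            m_mrca_density=m_density,
            mrca_ci95=mrca_ci,
            m_eca_density=m_eca_density,
            eca_ci95=eca_ci,
            evolution_class=classify_evolution(m_density),
            per_segment=gained,
            genome_bp=g,
        )
        self.m_mrca_density_ = m_density
        self.m_eca_density_ = m_eca_density
        self.evolution_class_ = self.result_.evolution_class
        return self


def time_tumor(sample: TumorSample, fp: float = DEFAULT_FP, n_boot: int = 1000,
               seed: int = 0, **kwargs) -> TimingResult:
    """Functional wrapper around :class:`MrcaEcaTimer`."""
    timer = MrcaEcaTimer(fp=fp, n_boot=n_boot, random_state=seed, **kwargs)
    return timer.fit(sample).result_
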