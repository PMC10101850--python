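"""Real-time calibration: per-day division, loss and mutation rates.

The time from gastrulation to diagnosis, t_D = age + 250 days of
embryogenesis, splits into a premalignant span (m_MRCA/(lambda*mu) divisions
on the mutation clock) and the tumor expansion to ~1e9 cells at net rate
lambda*(1 - delta/(s*lambda)).  Solving for lambda gives the per-day cell
division rate; multiplying by mu gives the daily mutation rate that anchors
the molecular clock in gestational time.

Conventions: mu and the MRCA density are per *haploid* genome; mu_eff (from
the VAF-tail fit) is per diploid genome and effective division — the
explicit factors of 2 below translate between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

EMBRYO_OFFSET_DAYS = 250.0
DEFAULT_N_END = 1e9
LOG_N_END = math.log(DEFAULT_N_END)


def effective_mutation_rate(mu: float, delta_over_lambda: float) -> float:
    """mu_eff = mu / (1 - delta_T/lambda_T): SSNVs per effective division."""
    if not (0.0 <= delta_over_lambda < 1.0):
        raise ValueError("delta/lambda must lie in [0, 1)")
    return mu / (1.0 - delta_over_lambda)


def loss_ratio_from_mu_eff(mu: float, mu_eff: float,
                           mu_sd: float = 0.0, mu_eff_sd: float = 0.0):
    """<delta/lambda> = 1 - 2<mu>/<mu_eff> with first-order uncertainty.

    The factor 2 converts the haploid per-division rate mu to the diploid
    scale of mu_eff.  Returns (mean, sd).
    """
    mean = 1.0 - 2.0 * mu / mu_eff
    sd = 2.0 * mu_sd / mu_eff + 2.0 * mu / mu_eff ** 2 * mu_eff_sd
    return mean, sd


def division_rate(age_days: float, m_mrca_density: float, mu: float, mu_eff: float,
                  mu_sd: float = 0.0, m_sd: float = 0.0, mu_eff_sd: float = 0.0,
                  n_end: float = DEFAULT_N_END,
                  genome_bp: float = 3.3e9):
    """Cell division rate per day with first-order error propagation.

    <lambda> = (2*m_MRCA + log(n_end)*mu_eff) / (2*mu*(age + 250 d)), where
    m_MRCA is the haploid mutation *count* (density * genome length), mu the
    haploid per-division SSNV rate and mu_eff the diploid effective rate.
    The sd sums the absolute first-order terms in 2*mu, 2*m_MRCA and mu_eff.
    Returns (mean, sd).
    """
    if age_days is None or age_days < 0:
        raise ValueError("age_days must be >= 0")
    if mu <= 0 or mu_eff <= 0 or m_mrca_density < 0:
        raise ValueError("rates must be positive")
    t_d = age_days + EMBRYO_OFFSET_DAYS
    m_count = m_mrca_density * genome_bp
    log_n = math.log(n_end)
    numer = 2.0 * m_count + log_n * mu_eff
    mean = numer / (2.0 * mu * t_d)
    sd = (numer / (2.0 * mu) * (2.0 * mu_sd)
          + 2.0 * m_sd * genome_bp
          + log_n * mu_eff_sd) / (2.0 * mu * t_d)
    return mean, sd


def daily_mutation_rate(mu: float, lambda_per_day: float,
                        mu_sd: float = 0.0, lambda_sd: float = 0.0):
    """mu*lambda (SSNVs per day, diploid: 2*mu_haploid*lambda) with
    propagated uncertainty mu*d(lambda) + lambda*d(mu)."""
    mean = 2.0 * mu * lambda_per_day
    sd = 2.0 * (mu * lambda_sd + lambda_per_day * mu_sd)
    return mean, sd


@dataclass
class RealtimeEstimate:
    sample_id: str
    sample_type: str
    lambda_mean: float
    lambda_sd: float
    loss_ratio_mean: float
    loss_ratio_sd: float
    daily_mu_mean: float
    daily_mu_sd: float


def cohort_realtime(entries, mu: float, mu_sd: float = 0.0,
                    n_end: float = DEFAULT_N_END, genome_bp: float = 3.3e9):
    """Per-tumor division/loss/daily-mutation rates plus cohort averages.

    entries: iterable of dicts with keys sample_id, sample_type, age_days,
    m_mrca_density (per haploid bp), m_sd (optional), mu_eff, mu_eff_sd
    (optional).  Cohort averages are unweighted means over primary tumors
    and metastases (relapses excluded), with s.d. propagated per entry and
    averaged.
    """
    results = []
    for e in entries:
        lam, lam_sd = division_rate(
            e["age_days"], e["m_mrca_density"], mu, e["mu_eff"],
            mu_sd=mu_sd, m_sd=e.get("m_sd", 0.0), mu_eff_sd=e.get("mu_eff_sd", 0.0),
            n_end=n_end, genome_bp=genome_bp,
        )
        lr, lr_sd = loss_ratio_from_mu_eff(mu, e["mu_eff"], mu_sd, e.get("mu_eff_sd", 0.0))
        dm, dm_sd = daily_mutation_rate(mu, lam, mu_sd, lam_sd)
        results.append(RealtimeEstimate(
            sample_id=e["sample_id"], sample_type=e.get("sample_type", "primary"),
            lambda_mean=lam, lambda_sd=lam_sd,
            loss_ratio_mean=lr, loss_ratio_sd=lr_sd,
            daily_mu_mean=dm, daily_mu_sd=dm_sd,
        ))
    keep = [r for r in results if r.sample_type != "relapse"]
    summary = {}
    if keep:
        summary = {
            "daily_mu_mean": float(np.mean([r.daily_mu_mean for r in keep])),
            "daily_mu_sd": float(np.mean([r.daily_mu_sd for r in keep])),
            "lambda_mean": float(np.mean([r.lambda_mean for r in keep])),
            "loss_ratio_mean": float(np.mean([r.loss_ratio_mean for r in keep])),
            "n": len(keep),
        }
    return results, summary
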