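"""Approximate Bayesian computation with sequential Monte Carlo sampling.

A generic likelihood-free sampler: particles drawn from the prior are
filtered through a decreasing sequence of distance thresholds (the median of
the previously accepted distances), with a Gaussian perturbation kernel
scaled to twice the weighted particle covariance and importance weights
correcting for the kernel.  Fully seeded and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np


@dataclass
class Prior:
    """A one-dimensional prior: uniform or log10-uniform on [lo, hi]."""

    kind: str  # "uniform" | "loguniform"
    lo: float
    hi: float

    def __post_init__(self):
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError("prior kind must be uniform or loguniform")
        if not (self.hi > self.lo):
            raise ValueError("degenerate prior: hi must exceed lo")
        if self.kind == "loguniform" and self.lo <= 0:
            raise ValueError("loguniform prior requires lo > 0")

    # internal (transformed) coordinates: log10 for loguniform
    def to_internal(self, x):
        return np.log10(x) if self.kind == "loguniform" else x

    def from_internal(self, z):
        return 10.0 ** z if self.kind == "loguniform" else z

    @property
    def bounds_internal(self):
        return (self.to_internal(self.lo), self.to_internal(self.hi))

    def sample_internal(self, rng, size=None):
        lo, hi = self.bounds_internal
        return rng.uniform(lo, hi, size=size)


@dataclass
class ABCConfig:
    population_size: int = 1000
    max_generations: int = 25
    epsilon_target: float = 0.05
    seed: int = 0
    max_attempts_per_gen: Optional[int] = None  # default 200 * population

    def __post_init__(self):
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")


@dataclass
class PosteriorSample:
    """Weighted ABC posterior particles with the acceptance trajectory."""

    names: list
    particles: np.ndarray  # (n, d) on the natural scale
    weights: np.ndarray
    distances: np.ndarray
    epsilons: list = field(default_factory=list)
    acceptance_rates: list = field(default_factory=list)

    def quantile(self, name: str, q):
        j = self.names.index(name)
        order = np.argsort(self.particles[:, j])
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        return np.interp(np.asarray(q, dtype=float), cw, self.particles[order, j])

    def mean(self, name: str) -> float:
        j = self.names.index(name)
        return float(np.sum(self.weights * self.particles[:, j]) / np.sum(self.weights))

    def credible_interval(self, name: str, level: float = 0.8):
        a = (1.0 - level) / 2.0
        lo, hi = self.quantile(name, [a, 1.0 - a])
        return float(lo), float(hi)

    def transformed(self, fun: Callable[[dict], float]):
        """Evaluate a scalar function of the parameters on every particle."""
        vals = np.array([
            fun(dict(zip(self.names, row))) for row in self.particles
        ])
        return vals

    def quantile_of(self, fun: Callable[[dict], float], q):
        vals = self.transformed(fun)
        order = np.argsort(vals)
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        return np.interp(np.asarray(q, dtype=float), cw, vals[order])


def run_abc_smc(distance: Callable[[Dict[str, float], np.random.Generator], float],
                priors: Dict[str, Prior],
                config: ABCConfig) -> PosteriorSample:
    """Fit by ABC-SMC: ``distance(theta, rng)`` simulates and scores a particle.

    The epsilon schedule is the median of each generation's accepted
    distances; sampling stops when epsilon reaches ``epsilon_target``, after
    ``max_generations``, or when a generation exhausts its attempt budget.
    """
    names = list(priors)
    rng = np.random.default_rng(config.seed)
    n = config.population_size
    d = len(names)
    lo = np.array([priors[k].bounds_internal[0] for k in names])
    hi = np.array([priors[k].bounds_internal[1] for k in names])
    max_attempts = config.max_attempts_per_gen or 200 * n

    def natural(z):
        return {k: priors[k].from_internal(z[j]) for j, k in enumerate(names)}

    # generation 0: plain prior sample
    Z = np.column_stack([priors[k].sample_internal(rng, n) for k in names])
    dist = np.array([distance(natural(z), rng) for z in Z])
    W = np.full(n, 1.0 / n)
    epsilons, acc_rates = [], []

    for gen in range(1, config.max_generations + 1):
        eps = float(np.median(dist))
        epsilons.append(eps)
        if eps <= config.epsilon_target:
            break
        cov = np.cov(Z.T, aweights=W) if d > 1 else np.array([[np.var(Z[:, 0])]])
        cov = 2.0 * np.atleast_2d(cov) + 1e-12 * np.eye(d)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-12)))
        inv_cov = np.linalg.inv(cov)
        norm = 1.0 / math.sqrt((2 * math.pi) ** d * max(np.linalg.det(cov), 1e-300))

        newZ = np.empty_like(Z)
        new_dist = np.empty(n)
        accepted = 0
        attempts = 0
        cum_w = np.cumsum(W)
        cum_w /= cum_w[-1]
        while accepted < n and attempts < max_attempts:
            attempts += 1
            j = int(np.searchsorted(cum_w, rng.uniform()))
            z = Z[j] + L @ rng.standard_normal(d)
            if np.any(z < lo) or np.any(z > hi):
                continue
            dd = distance(natural(z), rng)
            if dd <= eps:
                newZ[accepted] = z
                new_dist[accepted] = dd
                accepted += 1
        if accepted < n:
            # attempt budget exhausted: keep the particles we have
            newZ, new_dist = newZ[:accepted], new_dist[:accepted]
            if accepted < 10:
                acc_rates.append(accepted / max(attempts, 1))
                break
        acc_rates.append(accepted / attempts)
        # importance weights: flat prior in internal coords
        diff = newZ[:, None, :] - Z[None, :, :]
        kern = norm * np.exp(-0.5 * np.einsum("abi,ij,abj->ab", diff, inv_cov, diff))
        denom = kern @ W
        newW = 1.0 / np.maximum(denom, 1e-300)
        Z, dist = newZ, new_dist
        W = newW / np.sum(newW)
        n = len(Z)

    particles = np.column_stack(
        [priors[k].from_internal(Z[:, j]) for j, k in enumerate(names)]
    )
    return PosteriorSample(
        names=names, particles=particles, weights=W / np.sum(W),
        distances=dist, epsilons=epsilons, acceptance_rates=acc_rates,
    )
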