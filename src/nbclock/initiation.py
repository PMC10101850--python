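"""Two-hit model of tumor initiation on a transient precursor population.

Neural precursor cells expand exponentially (division rate lambda1, loss
rate delta1) to a peak size N(T) and then either decay or stay homeostatic
(lambda2, delta2; homeostasis <=> lambda2 = delta2).  A first oncogenic
event (probability mu1 per division) reduces cell loss by 1/r and sustains a
premalignant clone; a second event (mu2 per division, loss reduced by 1/s)
founds the tumor.  P_MRCA(t) is the probability that a surviving
double-mutant cell exists by time t; P(t1 | t2) is the conditional
distribution of the first-event time given the second occurred at t2
(the classical Luria-Delbrueck law t1/t2 while the precursor pool expands).

Time is measured in units of expansion-phase divisions (lambda1 = 1 by
convention); only products mu*lambda are identified by data on the mutation
count axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import integrate


@dataclass
class InitiationParams:
    """Parameters of the two-hit initiation model.

    n_peak : precursor population size at its peak, N(T).
    lambda1, delta1 : division / loss rate during expansion (lambda1 > delta1).
    lambda2, delta2 : rates afterwards (lambda2 <= delta2; equality =
        homeostasis).
    mu : neutral SSNVs per division (haploid genome).
    mu1, mu2 : probabilities of the first / second oncogenic event per division.
    r : factor by which the first event reduces the loss rate.
    s : same for the second event; use :meth:`from_nu2` to derive s from a
        target survival probability as the fitting protocol does.
    """

    n_peak: float
    delta1: float
    mu: float
    mu1: float
    mu2: float
    r: float
    s: float = 1.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    delta2: float = 1.0

    def __post_init__(self):
        if not (self.lambda1 > self.delta1 >= 0):
            raise ValueError("expansion requires lambda1 > delta1 >= 0")
        if self.lambda2 > self.delta2:
            raise ValueError("second phase requires lambda2 <= delta2")
        if self.n_peak <= 1:
            raise ValueError("n_peak must exceed 1")
        if not (0.0 <= self.mu1 <= 0.1 and 0.0 <= self.mu2 <= 0.1):
            raise ValueError("oncogenic event probabilities must be small and nonnegative")
        if self.r < 1 or self.s < 1:
            raise ValueError("selective advantages r, s must be >= 1")

    @property
    def T(self) -> float:
        """Time of the population peak."""
        return math.log(self.n_peak) / (self.lambda1 - self.delta1)

    @property
    def scenario(self) -> str:
        return "homeostasis" if self.lambda2 == self.delta2 else "decay"

    @classmethod
    def from_nu2(cls, nu2_target: float, **kwargs) -> "InitiationParams":
        """Derive s from a target expansion-phase survival probability.

        s = max(1, delta1 / (lambda1 * (1 - nu2))), with nu2 adjusted
        accordingly when the bound binds (second hits conferring no advantage
        during expansion are excluded).
        """
        if not (0 < nu2_target < 1):
            raise ValueError("nu2 must lie in (0, 1)")
        lam1 = kwargs.get("lambda1", 1.0)
        delta1 = kwargs["delta1"]
        s = max(1.0, delta1 / (lam1 * (1.0 - nu2_target)))
        return cls(s=s, **kwargs)


def precursor_population(t, params: InitiationParams):
    """Deterministic precursor population N(t): piecewise exponential."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    T = params.T
    r1 = params.lambda1 - params.delta1
    r2 = params.lambda2 - params.delta2
    return np.where(t <= T, np.exp(r1 * t), params.n_peak * np.exp(r2 * (t - T)))


def second_hit_survival(params: InitiationParams, phase: str, clip: bool = False) -> float:
    """Ultimate survival probability nu2 of a second-hit clone.

    phase "expansion": nu2_E = 1 - delta1/(s*lambda1);
    phase "decay" (or homeostasis): nu2_D = 1 - delta2/(s*lambda2), which
    must be positive (else the second hit is subcritical in phase 2).
    """
    if phase == "expansion":
        return 1.0 - params.delta1 / (params.s * params.lambda1)
    if phase in ("decay", "homeostasis"):
        ratio = params.delta2 / (params.s * params.lambda2)
        if ratio >= 1.0:
            if clip:
                return 0.0
            raise ValueError("second hit is subcritical in the second phase "
                             "(delta2/(s*lambda2) >= 1)")
        return 1.0 - ratio
    raise ValueError(f"unknown phase {phase!r}")


def luria_delbruck_factor(params: InitiationParams) -> float:
    """Finite-time survival correction F = int_0^1 nu2E/(nu2E + z^alpha) dz.

    alpha = (delta1 - s*lambda1)/(delta1 - lambda1) >= 1; the integrand is
    bounded on (0, 1], so adaptive quadrature converges quickly.
    """
    nu = second_hit_survival(params, "expansion")
    alpha = (params.delta1 - params.s * params.lambda1) / (params.delta1 - params.lambda1)
    val, _ = integrate.quad(lambda z: nu / (nu + z ** alpha), 0.0, 1.0,
                            epsrel=1e-10, limit=200)
    return float(val)


def _em1r(a: float, x) -> np.ndarray:
    """(exp(a*x) - 1)/a, with the a -> 0 limit x."""
    x = np.asarray(x, dtype=float)
    if abs(a) < 1e-12:
        return x.copy()
    return np.expm1(a * x) / a


def p_mrca(t, params: InitiationParams, case1_form: str = "survival") -> np.ndarray:
    """Probability that a surviving tumor-founding (MRCA) cell exists by t.

    Combines the three cases — both events during expansion, first during
    expansion / second after the peak, and both after the peak — as
    P = 1 - (1-P1)(1-P2)(1-P3) for t >= T and P = P1(t) before the peak.

    ``case1_form`` selects the expansion-phase expression.  "survival"
    (default) is the mean-field rate of second hits destined to survive,
    exp(-mu1*mu2*lambda1^2*nu2E * int_0^t u N(u) du), which matches the
    explicit branching-process simulator; "published" evaluates the
    originally published form (1-e^{-mu1(N-1)})(1-e^{-mu1 mu2 lambda1 t N(t) F/(1-delta1/lambda1)})
    with the Luria-Delbrueck factor F, which shares its leading-order
    behaviour but deviates for small mu1*N.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    T = params.T
    lam1, dlt1 = params.lambda1, params.delta1
    lam2, dlt2 = params.lambda2, params.delta2
    mu1, mu2, r = params.mu1, params.mu2, params.r
    nu2d = second_hit_survival(params, "decay", clip=True)

    # case 1: both events during expansion (frozen at T afterwards)
    u = np.minimum(t, T)
    a = lam1 - dlt1
    N_u = np.exp(a * u)
    if case1_form == "survival":
        nu2e = second_hit_survival(params, "expansion")
        J = (N_u * (a * u - 1.0) + 1.0) / a ** 2  # int_0^u v*e^{a v} dv
        P1 = -np.expm1(-mu1 * mu2 * lam1 ** 2 * nu2e * J)
    elif case1_form == "published":
        F = luria_delbruck_factor(params)
        geo = -np.expm1(-mu1 * (N_u - 1.0))
        lam_1 = mu1 * mu2 * lam1 * u * N_u * F / (1.0 - dlt1 / lam1)
        P1 = geo * (-np.expm1(-lam_1))
    else:
        raise ValueError("case1_form must be 'survival' or 'published'")

    out = np.array(P1)
    late = t > T
    if np.any(late) and nu2d > 0.0:
        dt = t[late] - T
        NT = params.n_peak
        if params.scenario == "decay":
            g2 = lam2 - dlt2 / r
            P2 = -np.expm1(-mu1 * mu2 * lam1 * lam2 * nu2d * T * NT * _em1r(g2, dt))
            if abs(1.0 / r - 1.0) < 1e-9:  # r -> 1: premalignant clone tracks N
                x = lam2 - dlt2
                I = ((np.exp(x * dt) * (x * dt - 1.0) + 1.0) / x ** 2
                     if abs(x) > 1e-12 else dt ** 2 / 2.0)
                P3 = -np.expm1(-mu1 * mu2 * lam2 ** 2 * nu2d * NT * I)
            else:
                brace = _em1r(lam2 - dlt2, dt) - _em1r(g2, dt)
                pref = mu1 * mu2 * lam2 ** 2 * nu2d * NT / (dlt2 * (1.0 / r - 1.0))
                P3 = -np.expm1(-pref * brace)
        else:  # homeostasis: lambda2 == delta2
            eps = 1.0 - 1.0 / r
            if eps < 1e-9:
                P2 = -np.expm1(-mu1 * mu2 * lam1 * nu2d * T * NT * lam2 * dt)
                P3 = -np.expm1(-mu1 * mu2 * lam2 * nu2d * NT * lam2 * dt ** 2 / 2.0)
            else:
                P2 = -np.expm1(-mu1 * mu2 * lam1 * nu2d * T * NT * _em1r(lam2 * eps, dt))
                brace = (1.0 - np.exp(lam2 * eps * dt)) / (lam2 * eps) + dt
                P3 = -np.expm1(mu1 * mu2 * lam2 * nu2d * NT / eps * brace)
        out[late] = 1.0 - (1.0 - P1[late]) * (1.0 - P2) * (1.0 - P3)
    return float(out[0]) if scalar else out


def p_eca_given_mrca(t1, t2: float, params: InitiationParams) -> np.ndarray:
    """P(first oncogenic event before t1 | second event at t2).

    For t2 <= T this is the uniform Luria-Delbrueck law t1/t2; afterwards the
    premalignant clone's deterministic growth weights the first-event time,
    with separate closed forms for the decay and homeostasis scenarios.
    """
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    if np.any(t1 < 0) or t2 < 0:
        raise ValueError("times must be >= 0")
    if np.any(t1 > t2):
        raise ValueError("t1 must not exceed t2")
    T = params.T
    lam1, lam2, dlt2, r = params.lambda1, params.lambda2, params.delta2, params.r
    if t2 <= T:
        res = t1 / t2
    elif params.scenario == "decay":
        a = dlt2 * (1.0 - 1.0 / r)  # premalignant net loss scale in phase 2
        # numerator/denominator divided by a; H(x) = (1 - e^{-a x})/a
        def H(x):
            return _em1r(-a, x)
        num = np.where(t1 <= T, lam1 * t1, lam1 * T + lam2 * H(np.maximum(t1 - T, 0.0)))
        den = lam1 * T + lam2 * H(t2 - T)
        res = num / den
    else:  # homeostasis
        eps = 1.0 - 1.0 / r
        if eps < 1e-9:
            num = np.where(t1 <= T, lam1 * t1, lam1 * T + lam2 * np.maximum(t1 - T, 0.0))
            den = lam1 * T + lam2 * (t2 - T)
            res = num / den
        else:
            E2 = np.exp(lam2 * eps * (t2 - T))
            num = np.where(
                t1 <= T,
                lam1 * t1 * eps * E2,
                (lam1 * T * eps + 1.0) * E2 - np.exp(lam2 * eps * (t2 - np.minimum(t1, t2))),
            )
            den = (lam1 * T * eps + 1.0) * E2 - 1.0
            res = num / den
    res = np.clip(res, 0.0, 1.0)
    res[t1 == t2] = 1.0
    return res


def _invert_monotone(fun, target, lo, hi, tol=1e-6, max_iter=200):
    """Bracketed bisection for a nondecreasing scalar function."""
    flo, fhi = fun(lo), fun(hi)
    if target <= flo:
        return lo
    if target > fhi:
        return None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if fun(mid) >= target:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def sample_event_times(params: InitiationParams, n: int, seed, t_max: float,
                       incidence_scale: float = 1e-5, refine: bool = True):
    """Sample (t1, t2) pairs by inverse transform of the model CDFs.

    t2 solves P_MRCA(t2) = x with x ~ U(0, incidence_scale) (the overall
    disease incidence); draws with x beyond P_MRCA(t_max) are censored
    (t2 = inf: no tumor by t_max).  t1 then solves P(t1 | t2) = y, y ~ U(0,1).
    Returns (t1, t2) arrays; censored entries are (inf, inf).

    ``refine=True`` polishes each root by bisection to 1e-6 time units;
    ``refine=False`` interpolates on dense monotone grids (the fast path the
    ABC forward simulation uses, accurate to ~t_max/1000).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs = rng.uniform(0.0, incidence_scale, size=n)
    ys = rng.uniform(0.0, 1.0, size=n)
    # dense monotone grid for bracketing
    grid = np.linspace(0.0, t_max, 1024)
    pg = p_mrca(grid, params)
    p_end = pg[-1]
    t1s = np.full(n, np.inf)
    t2s = np.full(n, np.inf)
    ok = xs <= p_end
    if not refine:
        t2s[ok] = np.interp(xs[ok], pg, grid)
        for i in np.nonzero(ok)[0]:
            t2 = t2s[i]
            if t2 <= params.T:
                t1s[i] = ys[i] * t2
            else:
                tg = np.linspace(0.0, t2, 256)
                cg = p_eca_given_mrca(tg, t2, params)
                t1s[i] = np.interp(ys[i], cg, tg)
        return t1s, t2s
    for i in np.nonzero(ok)[0]:
        x, y = xs[i], ys[i]
        j = int(np.searchsorted(pg, x))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j, len(grid) - 1)]
        t2 = _invert_monotone(lambda tt: p_mrca(tt, params), x, lo, hi)
        if t2 is None or t2 <= 0:
            t2 = max(t2 or 0.0, 1e-9)
        if t2 <= params.T:
            t1 = y * t2  # uniform first-event law during expansion
        else:
            t1 = _invert_monotone(
                lambda tt: float(p_eca_given_mrca(np.array([tt]), t2, params)[0]),
                y, 0.0, t2,
            )
        t1s[i], t2s[i] = t1, t2
    return t1s, t2s
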