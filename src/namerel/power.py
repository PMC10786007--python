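"""Reliability-attenuated power planning for correlational designs.

Individual-differences studies correlate two noisy measures (e.g., mean
picture-naming speed and an operation-span score). Measurement unreliability
attenuates the observable correlation below the true one (Spearman):

    rho_observed = rho_true * sqrt(rel_a * rel_b)

so the sample size needed to detect the association must be planned against
the *attenuated* correlation. This module provides the attenuation step, the
exact power function of the two-sided test of a zero Pearson correlation
(based on the exact sampling distribution of r under a bivariate-normal
alternative), the smallest n achieving a target power, and the
variance-explained bookkeeping used when reporting reliability estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "PowerQuery",
    "attenuate",
    "sample_correlation_pdf",
    "power_at_n",
    "required_n",
    "required_n_fisher",
    "unexplained_variance",
]


@dataclass(frozen=True)
class PowerQuery:
    """A sample-size planning question for a correlational design.

    Attributes
    ----------
    rho_true : float
        Hypothesized true correlation between the latent constructs.
    rel_a, rel_b : float
        Reliabilities of the two measures, each in (0, 1].
    alpha : float
        Two-sided significance level.
    power : float
        Target power.
    """

    rho_true: float
    rel_a: float
    rel_b: float
    alpha: float = 0.05
    power: float = 0.80

    @property
    def rho_observed(self) -> float:
        return attenuate(self.rho_true, self.rel_a, self.rel_b)


def attenuate(rho_true: float, rel_a: float, rel_b: float) -> float:
    """Spearman-attenuated observable correlation.

    Parameters
    ----------
    rho_true : float
        True correlation between constructs, in (-1, 1).
    rel_a, rel_b : float
        Reliabilities of the two observed measures, each in (0, 1].
    """
    if not -1.0 < rho_true < 1.0:
        raise ValueError(f"rho_true must be in (-1, 1), got {rho_true}")
    for name, rel in (("rel_a", rel_a), ("rel_b", rel_b)):
        if not 0.0 < rel <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {rel}")
    return rho_true * math.sqrt(rel_a * rel_b)


def _log_r_pdf(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log density of the sample correlation coefficient r.

    Exact bivariate-normal sampling distribution of r at sample size n and
    population correlation rho, in its Gaussian-hypergeometric form:

        p(r) = (n-2) * Gamma(n-1) / (sqrt(2*pi) * Gamma(n-1/2))
               * (1-rho^2)^((n-1)/2) * (1-r^2)^((n-4)/2)
               * (1-rho*r)^((3-2n)/2)
               * 2F1(1/2, 1/2; (2n-1)/2; (rho*r+1)/2)
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        log_norm = (
            math.log(n - 2)
            + special.gammaln(n - 1)
            - 0.5 * math.log(2 * math.pi)
            - special.gammaln(n - 0.5)
        )
        out = (
            log_norm
            + ((n - 1) / 2) * math.log1p(-rho * rho)
            + ((n - 4) / 2) * np.log1p(-r * r)
            + ((3 - 2 * n) / 2) * np.log1p(-rho * r)
            + np.log(special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2))
        )
    return out


def sample_correlation_pdf(r, rho: float, n: int):
    """Exact density of Pearson's r under a bivariate normal with correlation rho."""
    if n < 4:
        raise ValueError("n must be at least 4")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    return np.exp(_log_r_pdf(r, rho, n))


def _r_tail_prob(r_lo: float, r_hi: float, rho: float, n: int) -> float:
    """P(r_lo < r < r_hi) under the exact distribution of r."""
    if r_lo >= r_hi:
        return 0.0
    val, _ = integrate.quad(
        lambda r: float(np.exp(_log_r_pdf(r, rho, n))), r_lo, r_hi, limit=200
    )
    return val


def power_at_n(rho_observed: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided level-alpha test of H0: rho = 0 at sample size n.

    The test statistic is t = r*sqrt(n-2)/sqrt(1-r^2); the rejection region
    |t| > t_crit maps monotonically to |r| > r_crit, and power is the exact
    probability of that region under the alternative rho = rho_observed.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not -1.0 < rho_observed < 1.0:
        raise ValueError("rho_observed must be in (-1, 1)")
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    r_crit = t_crit / math.sqrt(t_crit**2 + n - 2)
    upper = _r_tail_prob(r_crit, 1.0, rho_observed, n)
    lower = _r_tail_prob(-1.0, -r_crit, rho_observed, n)
    return min(max(upper + lower, 0.0), 1.0)


def required_n(
    rho_observed: float,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "exact",
) -> int:
    """Smallest sample size whose two-sided correlation test reaches the target power.

    Parameters
    ----------
    rho_observed : float
        The attenuated (observable) correlation; must be nonzero.
    method : {"exact", "fisher"}
        "exact" evaluates the exact power function of the correlation
        t-test; "fisher" uses the Fisher-z normal approximation.
    """
    if rho_observed == 0.0:
        raise ValueError("rho_observed = 0 admits no finite sample size")
    if method == "fisher":
        return required_n_fisher(rho_observed, alpha=alpha, power=power)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    def achieved(n: int) -> float:
        return power_at_n(rho_observed, n, alpha=alpha)

    # bracket by doubling, then bisect on the monotone power curve
    lo, hi = 4, 8
    while achieved(hi) < power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:  # pragma: no cover
            raise RuntimeError("sample size search did not terminate")
    if achieved(lo) >= power:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def required_n_fisher(
    rho_observed: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Fisher-z closed-form sample size, ceiling-rounded (approximation)."""
    if rho_observed == 0.0:
        raise ValueError("rho_observed = 0 admits no finite sample size")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    zr = math.atanh(abs(rho_observed))
    n = ((z_a + z_b) / zr) ** 2 + 3
    return max(4, math.ceil(n))


def unexplained_variance(r: float) -> float:
    """Percent of variance left unexplained by a correlation r: 100*(1 - r^2).

    Rounded to the nearest integer percent, as conventionally reported.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    return round(100.0 * (1.0 - r * r))
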