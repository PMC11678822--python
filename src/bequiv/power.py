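"""Exact power and sample size for the two-one-sided-tests (TOST) procedure
in a 2x2x2 crossover on the ln scale.

The true within-subject ln-scale standard deviation is recovered from the
intra-subject CV via s^2 = ln(1 + CV^2); the point estimate of the ln ratio
is normal with standard error s*sqrt(2/n), and the pooled variance estimate
is s^2 * chi2_df / df with df = n - 2.  Both one-sided alpha-level t tests
reject — equivalently, the (1-2*alpha) CI falls inside the limits — iff

    ln(L) + t_{1-a,df}*shat*sqrt(2/n)  <=  thetahat  <=  ln(U) - t_{1-a,df}*shat*sqrt(2/n).

Power is the probability of that event, computed exactly by integrating the
conditional normal probability over the chi distribution of shat/s (the
Owen's-Q bivariate noncentral-t construction, evaluated by quadrature).
When shat is large the admissible interval is empty, which is why the TOST
size can fall well below alpha in small, highly variable studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .simulate import DesignError


@dataclass(frozen=True)
class PowerSpec:
    """Assumptions for a TOST power/sample-size calculation.

    CVs, GMR and limits are in percent (e.g. ``iscv_pct=50``,
    ``gmr_true_pct=105``); ``alpha`` is the one-sided level.
    """

    iscv_pct: float
    gmr_true_pct: float
    n_total: int | None = None
    alpha: float = 0.05
    limits_pct: tuple[float, float] = (80.00, 125.00)
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must lie in (0, 0.5)")
        lo, hi = self.limits_pct
        if not (lo < 100 < hi):
            raise ValueError("acceptance limits must straddle 100%")
        if self.iscv_pct <= 0:
            raise ValueError("iscv_pct must be positive")
        if self.n_total is not None and (self.n_total < 4 or self.n_total % 2):
            raise DesignError("n_total must be an even integer >= 4")


def tost_power(spec: PowerSpec) -> float:
    """Exact probability that both one-sided tests reject (fraction in [0, 1])."""
    if spec.n_total is None:
        raise DesignError("tost_power requires n_total")
    n, df = spec.n_total, spec.n_total - 2
    sigma = np.sqrt(np.log1p((spec.iscv_pct / 100.0) ** 2))
    sef = sigma * np.sqrt(2.0 / n)
    theta = np.log(spec.gmr_true_pct / 100.0)
    lnL, lnU = np.log(spec.limits_pct[0] / 100.0), np.log(spec.limits_pct[1] / 100.0)
    tcrit = stats.t.ppf(1 - spec.alpha, df)

    # u = shat/sigma; the admissible interval is non-empty only below u_max
    u_max = (lnU - lnL) / (2.0 * tcrit * sef)
    sdf = np.sqrt(df)

    def integrand(u):
        half = tcrit * u * sef
        p = stats.norm.cdf((lnU - half - theta) / sef) - stats.norm.cdf((lnL + half - theta) / sef)
        return max(p, 0.0) * stats.chi.pdf(u * sdf, df) * sdf

    val, _ = integrate.quad(integrand, 0.0, u_max, limit=200)
    return float(min(max(val, 0.0), 1.0))


def sample_size(spec: PowerSpec, n_max: int = 4000) -> int:
    """Smallest even total n with TOST power >= ``spec.target_power``.

    ``spec.gmr_true_pct`` may be a single ratio or a (lo, hi) range, in which
    case the endpoint with the lower power (worst case) is used.  Raises if
    the assumed GMR sits on or outside the acceptance limits (power can then
    never exceed alpha).
    """
    gmrs = np.atleast_1d(np.asarray(spec.gmr_true_pct, dtype=float))
    lo, hi = spec.limits_pct
    if ((gmrs <= lo) | (gmrs >= hi)).any():
        raise ValueError("assumed GMR must lie strictly inside the acceptance limits")
    if spec.target_power <= 0:
        return 4
    if spec.target_power >= 1:
        raise ValueError("target_power must be < 1")

    worst = gmrs[np.argmax(np.abs(np.log(gmrs / 100.0)))]

    def power_at(n: int) -> float:
        return tost_power(PowerSpec(iscv_pct=spec.iscv_pct, gmr_true_pct=float(worst),
                                    n_total=n, alpha=spec.alpha, limits_pct=spec.limits_pct))

    # bracket geometrically, then walk back to the smallest sufficient even n
    n = 4
    while n <= n_max and power_at(n) < spec.target_power:
        n *= 2
    if n > n_max:
        raise ValueError(f"target power not attainable with n <= {n_max}")
    lo_n = max(4, n // 2)
    for cand in range(lo_n, n + 2, 2):
        if power_at(cand) >= spec.target_power:
            return cand
    return n


def simulate_tost_pass_rate(spec: PowerSpec, n_reps: int, seed: int) -> float:
    """Monte-Carlo TOST pass rate under the ln-scale crossover sampling model.

    Draws the ln-ratio estimate and the residual variance from their exact
    sampling distributions (normal and scaled chi-square) and applies the
    CI-inclusion rule; an independent check on :func:`tost_power`.
    """
    if spec.n_total is None:
        raise DesignError("simulate_tost_pass_rate requires n_total")
    rng = np.random.default_rng(seed)
    n, df = spec.n_total, spec.n_total - 2
    sigma = np.sqrt(np.log1p((spec.iscv_pct / 100.0) ** 2))
    sef = sigma * np.sqrt(2.0 / n)
    theta_hat = rng.normal(np.log(spec.gmr_true_pct / 100.0), sef, n_reps)
    s_hat = sigma * np.sqrt(rng.chisquare(df, n_reps) / df)
    half = stats.t.ppf(1 - spec.alpha, df) * s_hat * np.sqrt(2.0 / n)
    lnL, lnU = np.log(spec.limits_pct[0] / 100.0), np.log(spec.limits_pct[1] / 100.0)
    return float(np.mean((theta_hat - half >= lnL) & (theta_hat + half <= lnU)))
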