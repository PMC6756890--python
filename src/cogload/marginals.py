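"""Published per-measure marginals and the quantile maps that realise them.

The cohort generator draws correlated standard-normal latents (a Gaussian
copula) and pushes each one through a monotone quantile map onto a bounded
marginal distribution whose mean, SD, minimum and maximum match the published
descriptive statistics of the study sample. Two marginal families are used:

* a truncated normal on ``[lo, hi]`` for roughly symmetric measures,
* a ``lo``-shifted truncated lognormal for strongly right-skewed measures
  (inflammation markers, triglycerides, heart-rate-variability indices, ...)
  whose SD cannot be reached by any truncated normal on the printed range, and
* its mirror image around ``hi`` for left-skewed, ceiling-compressed measures
  (the dementia rating scale).

For each measure the family parameters are solved numerically so that the
*truncated* distribution reproduces the printed (mean, SD) while respecting
the printed (min, max) exactly. The solved maps are cached process-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from ._errors import NoSolutionError

__all__ = [
    "Marginal",
    "MarginalMap",
    "solve_marginal",
    "TABLE1_MARGINALS",
    "TABLE2_MARGINALS",
    "DEFAULT_MARGINALS",
]

_EPS_U = 1e-12  # clip for copula uniforms
_REL_TOL = 0.005  # accepted relative moment error for a family fit


@dataclass(frozen=True)
class Marginal:
    """Printed summary of one measure: mean, SD and observed range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"marginal SD must be positive, got {self.sd}")
        if not (self.lo < self.hi):
            raise ValueError(f"marginal range must satisfy lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class MarginalMap:
    """A solved monotone map from a standard-normal latent to the marginal."""

    family: str  # "truncnorm" | "lognorm" | "lognorm_left"
    mu: float
    sigma: float
    lo: float
    hi: float
    moment_error: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws onto the bounded marginal (monotone)."""
        u = np.clip(stats.norm.cdf(z), _EPS_U, 1.0 - _EPS_U)
        if self.family == "truncnorm":
            a = (self.lo - self.mu) / self.sigma
            b = (self.hi - self.mu) / self.sigma
            x = stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)
        else:
            # shifted lognormal truncated to (0, hi - lo], optionally mirrored
            b = (np.log(self.hi - self.lo) - self.mu) / self.sigma
            pb = stats.norm.cdf(b)
            if self.family == "lognorm":
                x = self.lo + np.exp(self.mu + self.sigma * stats.norm.ppf(u * pb))
            else:  # mirror around hi, keeping the map increasing in z
                x = self.hi - np.exp(self.mu + self.sigma * stats.norm.ppf((1.0 - u) * pb))
        return np.clip(x, self.lo, self.hi)


def _truncnorm_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _trunclognorm_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    # moments of lo + Y, Y ~ LogNormal(mu, sigma) truncated to Y <= hi - lo
    b = (np.log(hi - lo) - mu) / sigma
    pb = stats.norm.cdf(b)
    if pb <= 0:
        return np.nan, np.nan
    with np.errstate(over="ignore", invalid="ignore"):
        m1 = np.exp(mu + 0.5 * sigma**2) * stats.norm.cdf(b - sigma) / pb
        m2 = np.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(b - 2 * sigma) / pb
        var = m2 - m1**2
    if not np.isfinite(var):
        return np.nan, np.nan
    if var <= 0:
        return lo + m1, 0.0
    return lo + float(m1), float(np.sqrt(var))


def _fit_family(marginal: Marginal, family: str) -> MarginalMap:
    m, s, lo, hi = marginal.mean, marginal.sd, marginal.lo, marginal.hi
    if family == "truncnorm":
        moments = _truncnorm_moments
        x0 = np.array([m, np.log(s)])
    else:
        if family == "lognorm":
            moments = _trunclognorm_moments
            mean_above = max(m - lo, 1e-6 * (hi - lo))
        else:

            def moments(mu: float, sigma: float, lo_: float, hi_: float) -> tuple[float, float]:
                mm, ss = _trunclognorm_moments(mu, sigma, lo_, hi_)
                return lo_ + hi_ - mm, ss

            mean_above = max(hi - m, 1e-6 * (hi - lo))
        cv2 = (s / mean_above) ** 2
        sig0 = np.sqrt(np.log1p(cv2))
        x0 = np.array([np.log(mean_above) - 0.5 * sig0**2, np.log(max(sig0, 1e-3))])

    def residuals(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        mm, ss = moments(mu, float(np.exp(log_sigma)), lo, hi)
        if not np.isfinite(mm) or not np.isfinite(ss):
            return np.array([1e3, 1e3])
        return np.array([(mm - m) / s, (ss - s) / s])

    sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    err = float(np.max(np.abs(residuals(sol.x))))
    return MarginalMap(
        family=family,
        mu=float(sol.x[0]),
        sigma=float(np.exp(sol.x[1])),
        lo=lo,
        hi=hi,
        moment_error=err,
    )


@lru_cache(maxsize=256)
def _solve_marginal_cached(mean: float, sd: float, lo: float, hi: float) -> MarginalMap:
    marginal = Marginal(mean, sd, lo, hi)
    best = _fit_family(marginal, "truncnorm")
    for family in ("lognorm", "lognorm_left"):
        if best.moment_error <= _REL_TOL:
            break
        alt = _fit_family(marginal, family)
        if alt.moment_error < best.moment_error:
            best = alt
    if best.moment_error > 0.10:
        raise NoSolutionError(
            f"no bounded marginal family reproduces mean={mean}, sd={sd} on [{lo}, {hi}] "
            f"(best relative moment error {best.moment_error:.3f})"
        )
    return best


def solve_marginal(marginal: Marginal) -> MarginalMap:
    """Solve (and cache) the quantile map realising a printed marginal."""
    return _solve_marginal_cached(marginal.mean, marginal.sd, marginal.lo, marginal.hi)


# Published descriptive statistics of the study sample (n = 81):
# demographics and the five PACC5 test scores.
TABLE1_MARGINALS: dict[str, Marginal] = {
    "age": Marginal(59.41, 5.41, 50.0, 69.0),
    "fcsrt": Marginal(80.90, 6.47, 63.0, 92.0),
    "logical_memory": Marginal(12.17, 4.00, 2.0, 22.0),
    "dsst": Marginal(71.94, 12.56, 39.0, 99.0),
    "fluency": Marginal(19.79, 3.58, 10.0, 29.0),
    "mattis": Marginal(142.38, 2.09, 134.0, 144.0),
}

# Raw constituents of the reserve, affective, allostatic-load and sleep
# composites (same sample).
TABLE2_MARGINALS: dict[str, Marginal] = {
    "education": Marginal(15.25, 3.11, 9.0, 25.0),
    "fnart": Marginal(29.06, 4.19, 13.0, 36.0),
    "occupation": Marginal(3815.27, 1675.39, 22.0, 7330.0),
    "sport": Marginal(22.31, 20.78, 0.0, 111.84),
    "leisure": Marginal(3718.43, 2393.50, 423.78, 11173.31),
    "bdi": Marginal(5.26, 4.50, 0.0, 17.0),
    "bai": Marginal(3.10, 3.33, 0.0, 17.0),
    "sbp": Marginal(119.07, 11.70, 92.5, 150.0),
    "heart_rate": Marginal(60.38, 9.12, 42.4, 84.5),
    "pulse_pressure": Marginal(45.44, 10.02, 25.0, 65.0),
    "sdann": Marginal(54.32, 39.08, 13.0, 224.0),
    "rmssd": Marginal(59.41, 60.45, 7.0, 324.0),
    "bmi": Marginal(24.78, 2.84, 19.37, 30.12),
    "whr": Marginal(0.99, 0.17, 0.67, 1.37),
    "ldl": Marginal(134.08, 32.40, 45.0, 237.0),
    "hdl": Marginal(66.17, 18.94, 28.0, 149.0),
    "triglycerides": Marginal(109.83, 54.31, 29.0, 339.2),
    "hba1c": Marginal(5.39, 0.29, 4.4, 6.3),
    "glucose": Marginal(90.88, 11.65, 72.0, 129.0),
    "crp": Marginal(1.90, 2.16, 0.16, 9.5),
    "il6": Marginal(2.91, 5.29, 0.70, 38.0),
    "dheas": Marginal(3.39, 1.75, 0.42, 10.57),
    "cortisol": Marginal(48.07, 23.60, 14.29, 138.75),
    "adrenaline": Marginal(9.43, 4.39, 3.06, 25.47),
    "noradrenaline": Marginal(40.34, 15.46, 11.22, 95.89),
    "iv": Marginal(0.43, 0.12, 0.26, 0.96),
    "psqi": Marginal(4.85, 2.94, 0.0, 13.0),
    "ess": Marginal(6.16, 4.04, 0.0, 16.0),
}

# Serum creatinine is needed to correct the urinary analytes for lean body
# mass but has no published marginal; a typical adult reference range is used.
_EXTRA_MARGINALS: dict[str, Marginal] = {
    "serum_creatinine": Marginal(0.85, 0.13, 0.5, 1.3),
}

DEFAULT_MARGINALS: dict[str, Marginal] = {
    **TABLE1_MARGINALS,
    **TABLE2_MARGINALS,
    **_EXTRA_MARGINALS,
}
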