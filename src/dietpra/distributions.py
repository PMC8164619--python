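"""Lognormal exposure-factor models fitted from arithmetic moments.

Exposure factors here (rice intake, body weight, cadmium concentration in
detected samples) are positive, right-skewed quantities reported only as an
arithmetic mean and standard deviation, sometimes with an observed range.
They are modelled as lognormals parameterized by the method of moments,

    sigma_log^2 = ln(1 + (sd/mean)^2),
    mu_log      = ln(mean) - sigma_log^2 / 2,

so that the untruncated model reproduces the reported mean and SD exactly.
Range bounds are applied as hard truncation at sampling time, via the
inverse CDF restricted to [F(lower), F(upper)]; the underlying mu/sigma are
NOT re-adjusted, so truncation introduces a small, quantified downward bias
in the realized mean relative to the reported one.

Concentration surveys are left-censored: a fraction of samples fall below
the detection threshold and are recorded as exactly zero.  That structure
is captured by a zero-inflated lognormal — a point mass at zero mixed with
a lognormal for the detected values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .config_io import ConcentrationRecord, ConcentrationSummary
from .errors import DegenerateModelError, DomainError, InfeasibleTruncationError

__all__ = [
    "LognormalSpec",
    "ZeroInflatedLognormal",
    "fit_lognormal_moments",
    "sample_truncated_lognormal",
    "fit_concentration_model",
    "from_summary",
]

#: minimum probability mass a truncation interval must retain
_MIN_TRUNCATION_MASS = 1e-12


def fit_lognormal_moments(arith_mean: float, arith_sd: float) -> tuple[float, float]:
    """Method-of-moments lognormal parameters from arithmetic mean and SD.

    Returns ``(mu_log, sigma_log)`` of the underlying normal.  The identities
    ``exp(mu + sigma^2/2) == mean`` and the matching SD identity hold to
    relative precision ~1e-15.  ``arith_sd == 0`` yields ``sigma_log == 0``,
    a point mass at the mean.
    """
    if arith_mean <= 0:
        raise DomainError(f"arithmetic mean must be positive, got {arith_mean}")
    if arith_sd < 0:
        raise DomainError(f"arithmetic SD must be non-negative, got {arith_sd}")
    cv2 = (arith_sd / arith_mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(arith_mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class LognormalSpec:
    """A positive exposure factor: lognormal in arithmetic parameterization.

    ``arith_mean``/``arith_sd`` are the natural-scale moments of the
    *untruncated* distribution; ``lower``/``upper`` are optional hard bounds
    (survey range) enforced at sampling time.  ``mu_log``/``sigma_log`` are
    derived, never passed.
    """

    arith_mean: float
    arith_sd: float
    lower: float = 0.0
    upper: float = math.inf
    mu_log: float = field(init=False)
    sigma_log: float = field(init=False)

    def __post_init__(self):
        if not 0 <= self.lower < self.upper:
            raise DomainError(
                f"need 0 <= lower < upper, got [{self.lower}, {self.upper}]"
            )
        mu, sigma = fit_lognormal_moments(self.arith_mean, self.arith_sd)
        object.__setattr__(self, "mu_log", mu)
        object.__setattr__(self, "sigma_log", sigma)

    @property
    def median(self) -> float:
        """Median of the untruncated distribution, exp(mu_log)."""
        return math.exp(self.mu_log)

    def _log_cdf_bounds(self) -> tuple[float, float]:
        if self.sigma_log == 0:
            raise DomainError("degenerate spec has no continuous CDF")
        lo = (
            0.0
            if self.lower == 0
            else special.ndtr((math.log(self.lower) - self.mu_log) / self.sigma_log)
        )
        hi = (
            1.0
            if math.isinf(self.upper)
            else special.ndtr((math.log(self.upper) - self.mu_log) / self.sigma_log)
        )
        return float(lo), float(hi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_truncated_lognormal(self, n, rng)


def sample_truncated_lognormal(
    spec: LognormalSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``spec`` restricted to [lower, upper].

    Inverse-CDF sampling on the uniform interval [F(lower), F(upper)]:
    deterministic for a given generator state and free of rejection loops.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if spec.sigma_log == 0:
        if not spec.lower <= spec.arith_mean <= spec.upper:
            raise InfeasibleTruncationError(
                f"point mass {spec.arith_mean} outside [{spec.lower}, {spec.upper}]"
            )
        rng.random(n)  # consume the stream so draw counts stay aligned
        return np.full(n, spec.arith_mean)
    lo, hi = spec._log_cdf_bounds()
    if hi - lo < _MIN_TRUNCATION_MASS:
        raise InfeasibleTruncationError(
            f"truncation [{spec.lower}, {spec.upper}] retains mass {hi - lo:.3g}"
        )
    u = lo + (hi - lo) * rng.random(n)
    return np.exp(spec.mu_log + spec.sigma_log * special.ndtri(u))


@dataclass(frozen=True)
class ZeroInflatedLognormal:
    """Point mass at zero (non-detects) mixed with a lognormal (detects).

    The overall (untruncated) mean is ``(1 - p_zero) * positive.arith_mean``.
    """

    p_zero: float
    positive: LognormalSpec

    def __post_init__(self):
        if not 0 <= self.p_zero <= 1:
            raise DomainError(f"p_zero must lie in [0,1], got {self.p_zero}")

    @property
    def mean(self) -> float:
        return (1.0 - self.p_zero) * self.positive.arith_mean

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; a share ``p_zero`` is exactly zero in expectation."""
        zero_mask = rng.random(n) < self.p_zero
        out = sample_truncated_lognormal(self.positive, n, rng)
        out[zero_mask] = 0.0
        return out


def fit_concentration_model(
    records: list[ConcentrationRecord],
    bounds: tuple[float, float] | None = None,
) -> ZeroInflatedLognormal:
    """Fit a zero-inflated lognormal to raw survey records.

    ``p_zero`` is the observed non-detect fraction; the positive part is
    moment-fitted to the detected values.  The upper truncation bound
    defaults to the observed maximum.
    """
    detected = np.array([r.value for r in records if r.detected], dtype=float)
    if detected.size < 2:
        raise DegenerateModelError(
            f"need >= 2 detected records, got {detected.size}"
        )
    p_zero = 1.0 - detected.size / len(records)
    if bounds is None:
        bounds = (0.0, float(detected.max()))
    positive = LognormalSpec(
        arith_mean=float(detected.mean()),
        arith_sd=float(detected.std(ddof=1)),
        lower=bounds[0],
        upper=bounds[1],
    )
    return ZeroInflatedLognormal(p_zero=p_zero, positive=positive)


def from_summary(summary: ConcentrationSummary) -> ZeroInflatedLognormal:
    """Build a concentration model directly from a printed summary row.

    The printed mean/SD describe the *mixture* (zeros included), so the
    positive part is solved from the mixture moments:

        m_pos  = mean / (1 - p_zero)
        E[X^2] = sd^2 + mean^2            (mixture second moment)
        s_pos^2 = E[X^2] / (1 - p_zero) - m_pos^2

    The positive part is truncated above at the printed maximum.  A summary
    with sd == 0 yields a point mass at the mean (not an error); if the
    implied positive-part variance is not positive the model degenerates to
    a point mass at ``m_pos``.
    """
    if summary.mean <= 0:
        raise DomainError(f"summary mean must be positive, got {summary.mean}")
    p_zero = 0.0 if summary.detect_rate is None else 1.0 - summary.detect_rate
    if p_zero >= 1.0:
        raise DegenerateModelError("detect_rate 0 leaves no positive part")
    frac = 1.0 - p_zero
    m_pos = summary.mean / frac
    second = summary.sd**2 + summary.mean**2
    s2_pos = second / frac - m_pos**2
    s_pos = math.sqrt(s2_pos) if s2_pos > 0 else 0.0
    positive = LognormalSpec(
        arith_mean=m_pos, arith_sd=s_pos, lower=0.0, upper=summary.max
    )
    return ZeroInflatedLognormal(p_zero=p_zero, positive=positive)
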