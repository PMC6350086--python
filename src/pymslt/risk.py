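"""BMI relative-risk model, population impact fractions, lags and decay.

The exposure model is the standard comparative-risk-assessment form: risk
is flat at 1 up to the theoretical minimum risk exposure level (TMREL) and
rises exponentially above it, ``RR(x) = rr_per_unit ** max(0, x - tmrel)``.
Population impact fractions compare the expected relative risk under a
baseline BMI distribution with the expectation after a location shift of
that distribution.  Disease-specific time lags convert the per-year
population BMI-change series into the windowed average that drives
incidence, and the decay model describes post-intervention weight regain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .errors import ConfigurationError, DomainError, NumericError


@dataclass(frozen=True)
class RiskFunction:
    """Exponential-above-threshold relative risk for BMI."""

    rr_per_unit: float
    tmrel: float = 21.0

    def __post_init__(self):
        if self.rr_per_unit < 1.0:
            raise ConfigurationError("rr_per_unit must be >= 1 (harmful exposure)")


@dataclass(frozen=True)
class LagWindow:
    """Inclusive window of past years whose mean BMI change drives incidence."""

    lower: int
    upper: int

    def __post_init__(self):
        if not (0 <= self.lower < self.upper):
            raise ConfigurationError("lag window requires 0 <= lower < upper")

    @property
    def length(self) -> int:
        return self.upper - self.lower + 1


@dataclass(frozen=True)
class DecayModel:
    """Post-intervention BMI regain, in BMI units per month."""

    rate: float = 0.03
    enabled: bool = True

    def __post_init__(self):
        if self.rate < 0.0:
            raise ConfigurationError("decay rate must be non-negative")


def relative_risk(bmi, rf: RiskFunction):
    """Relative risk at a BMI value (scalar or array)."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0.0):
        raise DomainError("bmi must be positive")
    out = rf.rr_per_unit ** np.maximum(0.0, bmi - rf.tmrel)
    return out if out.ndim else float(out)


#: tail mass excluded from the expectation on each side.  The exponential
#: relative-risk form has no finite raw expectation against log-normal-type
#: exposure tails, so the model works with the central 1 - 2e-12 mass (any
#: finite Monte Carlo sample is an implicit truncation of the same kind).
_TAIL_EPS = 1e-12


def _mean_rr(dist, rf: RiskFunction, rtol: float) -> float:
    """E[RR(X)] for a frozen scipy distribution or a point mass (float)."""
    if np.isscalar(dist) or isinstance(dist, (int, float, np.floating)):
        return float(relative_risk(float(dist), rf))
    lo = max(float(dist.ppf(_TAIL_EPS)), 1e-12)
    hi = float(dist.ppf(1.0 - _TAIL_EPS))
    points = [rf.tmrel] if lo < rf.tmrel < hi else None
    value, err = integrate.quad(
        lambda x: (rf.rr_per_unit ** max(0.0, x - rf.tmrel)) * dist.pdf(x),
        lo, hi, epsrel=rtol, epsabs=0.0, limit=200, points=points,
    )
    if not np.isfinite(value) or value <= 0.0:
        raise NumericError("expected relative risk did not converge")
    return value


def pif(baseline_dist, shifted_dist, rf: RiskFunction, rtol: float = 1e-8) -> float:
    """Population impact fraction 1 - E_shifted[RR] / E_baseline[RR].

    Distributions may be frozen scipy continuous distributions or floats
    (point masses).  Positive values mean the shift averts incidence.
    """
    e_base = _mean_rr(baseline_dist, rf, rtol)
    e_shift = _mean_rr(shifted_dist, rf, rtol)
    return 1.0 - e_shift / e_base


def shifted_lognormal(mean: float, sd: float, delta: float = 0.0):
    """Frozen log-normal BMI distribution (matched arithmetic mean/sd),
    location-shifted by ``delta`` BMI units (shape preserved)."""
    if mean <= 0 or sd <= 0:
        raise DomainError("BMI mean and sd must be positive")
    cv2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean) - sigma ** 2 / 2.0
    return stats.lognorm(s=sigma, scale=np.exp(mu), loc=delta)


def lagged_delta_bmi(history: np.ndarray, year: int, window: LagWindow) -> float:
    """Mean BMI change over the window [year-upper, year-lower], inclusive.

    ``history[t]`` is the population-mean BMI change in year ``t`` counted
    from the intervention year; years before the intervention (negative
    indices) and beyond the recorded horizon contribute zero.
    """
    history = np.asarray(history, dtype=float)
    total = 0.0
    for y in range(year - window.upper, year - window.lower + 1):
        if 0 <= y < history.size:
            total += history[y]
    return total / window.length


def lagged_series(history: np.ndarray, window: LagWindow) -> np.ndarray:
    """Vectorised :func:`lagged_delta_bmi` for every year of a 1-D or 2-D
    history (years on axis 0)."""
    history = np.asarray(history, dtype=float)
    squeeze = history.ndim == 1
    if squeeze:
        history = history[:, None]
    n = history.shape[0]
    csum = np.zeros((n + 1,) + history.shape[1:])
    np.cumsum(history, axis=0, out=csum[1:])
    out = np.empty_like(history)
    for t in range(n):
        lo = t - window.upper       # first contributing year
        hi = t - window.lower       # last contributing year
        lo_c = min(max(lo, 0), n)
        hi_c = min(max(hi + 1, 0), n)
        out[t] = (csum[hi_c] - csum[lo_c]) / window.length
    return out[:, 0] if squeeze else out


def decay_profile(initial_delta: float, decay: DecayModel, horizon: int) -> np.ndarray:
    """Per-year population BMI-change series for a one-off effect.

    Year 0 (the intervention year) carries the full ``initial_delta``;
    afterwards the deficit shrinks by ``decay.rate`` BMI units per month,
    never overshooting zero, and each later year's value is the mean of
    its 12 monthly values.  With decay disabled the loss is permanent.
    """
    if initial_delta > 0.0:
        raise DomainError("initial_delta must be a weight loss (<= 0)")
    if horizon < 1:
        raise ConfigurationError("horizon must be at least 1 year")
    if not decay.enabled or decay.rate == 0.0:
        return np.full(horizon, initial_delta, dtype=float)
    profile = np.zeros(horizon)
    profile[0] = initial_delta
    if horizon > 1:
        months = np.arange(1, 12 * (horizon - 1) + 1, dtype=float)
        monthly = np.minimum(initial_delta + decay.rate * months, 0.0)
        profile[1:] = monthly.reshape(horizon - 1, 12).mean(axis=1)
    return profile


def months_to_recovery(initial_delta: float, decay: DecayModel) -> int:
    """Number of post-intervention-year months with a nonzero deficit."""
    if initial_delta > 0.0:
        raise DomainError("initial_delta must be a weight loss (<= 0)")
    if not decay.enabled or decay.rate == 0.0:
        return -1  # never recovers
    k = 1
    months = 0
    while initial_delta + decay.rate * k < 0.0:
        months += 1
        k += 1
    return months


# ---------------------------------------------------------------------------
# fast quadrature backend used by the life-table engine
# ---------------------------------------------------------------------------

_N_NODES = 48
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_N_NODES)
#: quantile-space nodes/weights on (0, 1)
_U_NODES = 0.5 * (_GL_X + 1.0)
_U_WEIGHTS = 0.5 * _GL_W
from scipy.special import ndtri  # noqa: E402

_Z_NODES = ndtri(_U_NODES)


def mean_rr_lognormal(mean, sd, delta, log_rr, tmrel):
    """Vectorised E[RR(X + delta)] for log-normal BMI distributions.

    All arguments broadcast; the expectation is taken by fixed-order
    Gauss-Legendre quadrature in quantile space (accuracy validated
    against the adaptive integrator in the test suite).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    cv2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean) - sigma ** 2 / 2.0
    x = np.exp(mu[..., None] + sigma[..., None] * _Z_NODES)
    excess = np.maximum(0.0, x + np.asarray(delta)[..., None] - np.asarray(tmrel)[..., None])
    vals = np.exp(np.asarray(log_rr)[..., None] * excess)
    return vals @ _U_WEIGHTS
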