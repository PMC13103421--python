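"""Probit-regression limit of detection from a dilution series.

A dilution series mixes fusion-positive DNA into fusion-negative DNA at
fractions x (in percent) and records, per replicate library, whether the
fusion was detected (total fusion read pairs >= the detection
threshold).  The detection probability is modeled as

    P(detected | x) = Phi(a + b * x)

with Phi the standard normal CDF — a binomial GLM with probit link —
and the limit of detection at confidence level c (default 0.95) is the
fraction where the fitted probability reaches c:

    LoD = (Phi^{-1}(c) - a) / b        (b > 0)

Negative-control libraries enter as x = 0 observations by default.  The
fraction axis can alternatively be fit on log10 scale (zero-fraction
controls are then necessarily dropped); both scales and both
zero-handling choices are exposed, and :func:`lod_grid` reports all
combinations side by side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

__all__ = [
    "DilutionObservation",
    "ProbitFit",
    "LoDResult",
    "FitError",
    "fit_probit",
    "lod_at",
    "fit_lod",
    "lod_grid",
    "simulate_detection_curve",
]


class FitError(ValueError):
    """Degenerate dilution data (e.g. all outcomes identical)."""


@dataclass(frozen=True)
class DilutionObservation:
    """Detection outcomes at one dilution point.

    ``fraction`` is the fusion-positive DNA proportion in percent;
    ``detected`` of ``n`` replicate libraries met the detection
    threshold.
    """

    fraction: float
    n: int
    detected: int

    def __post_init__(self):
        if self.fraction < 0:
            raise ValueError(f"fraction must be >= 0, got {self.fraction}")
        if not 0 <= self.detected <= self.n:
            raise ValueError(f"detected must be in [0, n={self.n}], got {self.detected}")


@dataclass
class ProbitFit:
    intercept: float
    slope: float
    converged: bool
    separation: bool
    log_scale: bool
    n_obs: int


@dataclass
class LoDResult:
    fit: ProbitFit
    confidence: float
    lod: float
    identifiable: bool

    def as_dict(self) -> dict:
        return {
            "intercept": self.fit.intercept,
            "slope": self.fit.slope,
            "converged": self.fit.converged,
            "separation": self.fit.separation,
            "log_scale": self.fit.log_scale,
            "confidence": self.confidence,
            "lod_percent": self.lod,
            "identifiable": self.identifiable,
        }


def _prepare(
    observations: Sequence[DilutionObservation],
    log_scale: bool,
    include_zero: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = list(observations)
    if not include_zero or log_scale:
        dropped = [o for o in obs if o.fraction == 0]
        if log_scale and include_zero and dropped:
            logger.warning(
                "log-scale fit cannot include zero-fraction controls; "
                "dropping %d observation(s)", len(dropped),
            )
        obs = [o for o in obs if o.fraction > 0]
    if len({o.fraction for o in obs}) < 2:
        raise FitError("need >= 2 distinct fractions")
    x = np.array([o.fraction for o in obs], float)
    n = np.array([o.n for o in obs], float)
    d = np.array([o.detected for o in obs], float)
    if d.sum() == 0 or d.sum() == n.sum():
        raise FitError("all outcomes identical; detection curve unidentifiable")
    if log_scale:
        x = np.log10(x)
    return x, n, d


def _is_separated(x: np.ndarray, n: np.ndarray, d: np.ndarray) -> bool:
    """Complete separation: some threshold on x splits all-0 from all-n
    outcomes with no intermediate point."""
    if np.any((d > 0) & (d < n)):
        return False
    detected_x = x[d == n]
    undetected_x = x[d == 0]
    return detected_x.min() > undetected_x.max()


def _firth_probit(x: np.ndarray, n: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Bias-reduced probit MLE: maximize loglik + 0.5 log det I(theta)."""
    X = np.column_stack([np.ones_like(x), x])

    def neg_penalized(theta):
        eta = X @ theta
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        ll = np.sum(d * np.log(p) + (n - d) * np.log1p(-p))
        phi = stats.norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        info = X.T @ (w[:, None] * X)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return np.inf
        return -(ll + 0.5 * logdet)

    # start from the plain MLE when it is finite; the penalty surface is
    # smooth there and Nelder-Mead refines reliably
    starts = [np.array([-1.0, 0.1])]
    try:
        fam = sm.families.Binomial(sm.families.links.Probit())
        with np.errstate(all="ignore"):
            mle = sm.GLM(np.column_stack([d, n - d]), X, family=fam).fit(maxiter=200)
        if np.all(np.isfinite(mle.params)) and np.abs(mle.params).max() < 1e3:
            starts.insert(0, np.asarray(mle.params))
    except Exception:  # MLE may fail under separation; penalized fit cannot
        pass
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_penalized, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def fit_probit(
    observations: Sequence[DilutionObservation],
    log_scale: bool = False,
    include_zero: bool = True,
    firth: bool = False,
) -> ProbitFit:
    """Maximum-likelihood binomial probit regression of detection on
    fraction (deterministic; no randomness involved).

    Complete separation is detected and flagged (``separation=True``,
    ``converged=False``) rather than raised; all-identical outcomes
    raise :class:`FitError`.  ``firth=True`` switches to a Firth-type
    bias-reduced fit, which remains finite under quasi-separation.
    """
    x, n, d = _prepare(observations, log_scale, include_zero)
    separated = _is_separated(x, n, d)

    if firth:
        a, b = _firth_probit(x, n, d)
        return ProbitFit(float(a), float(b), True, separated, log_scale, x.size)

    X = sm.add_constant(x)
    fam = sm.families.Binomial(sm.families.links.Probit())
    endog = np.column_stack([d, n - d])
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # quasi-separation is detected and flagged explicitly above;
        # statsmodels' per-iteration warning adds only noise
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = sm.GLM(endog, X, family=fam).fit(maxiter=200)
    a, b = res.params
    converged = bool(res.converged) and not separated
    if separated:
        logger.warning(
            "complete separation in dilution data: probit parameters "
            "diverge; LoD is not identifiable from this design"
        )
    return ProbitFit(float(a), float(b), converged, separated, log_scale, x.size)


def lod_at(fit: ProbitFit, confidence: float = 0.95) -> float:
    """Fraction (percent) at which fitted detection probability reaches
    ``confidence``.  For a log-scale fit the result is back-transformed
    to the percent scale.  Requires a positive slope."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if fit.slope <= 0:
        raise FitError("non-identifiable LoD: fitted slope <= 0")
    z = stats.norm.ppf(confidence)
    val = (z - fit.intercept) / fit.slope
    return float(10**val) if fit.log_scale else float(val)


def fit_lod(
    observations: Sequence[DilutionObservation],
    confidence: float = 0.95,
    log_scale: bool = False,
    include_zero: bool = True,
    firth: bool = False,
) -> LoDResult:
    fit = fit_probit(observations, log_scale=log_scale, include_zero=include_zero,
                     firth=firth)
    identifiable = fit.slope > 0 and not fit.separation
    lod = lod_at(fit, confidence) if fit.slope > 0 else float("nan")
    if lod < 0:
        identifiable = False
    return LoDResult(fit=fit, confidence=confidence, lod=lod,
                     identifiable=identifiable)


def lod_grid(
    observations: Sequence[DilutionObservation],
    confidence: float = 0.95,
    firth: bool = False,
) -> dict[str, LoDResult]:
    """LoD under the four exposed fit configurations.

    Keys: ``linear_with_zero``, ``linear_without_zero``,
    ``log_with_zero``, ``log_without_zero``.  The log-scale fits drop
    zero-fraction controls out of necessity, so the two log cells
    coincide; both are reported for completeness.
    """
    out: dict[str, LoDResult] = {}
    for scale in ("linear", "log"):
        for zero in (True, False):
            key = f"{scale}_{'with' if zero else 'without'}_zero"
            try:
                out[key] = fit_lod(
                    observations, confidence=confidence,
                    log_scale=scale == "log", include_zero=zero, firth=firth,
                )
            except FitError as e:
                logger.warning("configuration %s failed: %s", key, e)
    return out


def simulate_detection_curve(
    a: float,
    b: float,
    fractions: Sequence[float],
    n: int,
    seed: int = 0,
) -> list[DilutionObservation]:
    """Binomial draws from the generating curve Phi(a + b x): the
    validation harness for :func:`fit_probit`."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for x in fractions:
        p = stats.norm.cdf(a + b * x)
        out.append(DilutionObservation(float(x), n, int(rng.binomial(n, p))))
    return out
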