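"""Lomax (Pareto type II) length-of-stay mathematics.

The Lomax distribution is a heavy-tailed distribution on ``[0, inf)`` with
shape ``alpha`` and scale ``beta`` (days):

    pdf      f(x) = (alpha/beta) * (1 + x/beta)^-(alpha+1)
    cdf      F(x) = 1 - (1 + x/beta)^-alpha
    survival S(x) = (1 + x/beta)^-alpha
    mean     E[X] = beta/(alpha - 1)        (defined only for alpha > 1)

Length-of-stay data are strongly right-skewed: most patients leave quickly
while a few stay very long, which is exactly the regime where the Lomax tail
outperforms exponential-type models.  This module provides the distribution
itself, the derivation of (alpha, beta) from two hospital rate parameters
``p`` (admission rate) and ``m`` (bed-stay ratio), the truncated-sum stay
score used to grade departments, and maximum-likelihood fitting plus
goodness-of-fit comparison against other heavy-tailed families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LomaxParams",
    "RateInputs",
    "FitResult",
    "GofResult",
    "UndefinedMeanError",
    "SingularRatesError",
    "FitError",
    "lomax_pdf",
    "lomax_cdf",
    "lomax_survival",
    "lomax_mean",
    "params_from_rates",
    "rates_from_counts",
    "rates_from_table",
    "stay_mass",
    "adjusted_plos",
    "fit_mle",
    "gof_compare",
    "GOF_FAMILIES",
]


class UndefinedMeanError(ValueError):
    """The Lomax mean beta/(alpha-1) requires shape alpha > 1."""


class SingularRatesError(ValueError):
    """Raised when p*m = 1, where the rate-to-parameter map is singular."""


class FitError(RuntimeError):
    """Maximum-likelihood fit failed to converge or the sample is degenerate."""


@dataclass(frozen=True)
class LomaxParams:
    """Shape ``alpha`` (dimensionless) and scale ``beta`` (days) of a Lomax law."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"Lomax parameters must be positive, got shape={self.shape}, "
                f"scale={self.scale}"
            )

    @property
    def has_mean(self) -> bool:
        return self.shape > 1


@dataclass(frozen=True)
class RateInputs:
    """Hospital rate parameters feeding the Lomax parameterization.

    ``p`` is an admission-rate parameter (1/days) and ``m`` a bed-stay
    parameter (dimensionless).  The map to (alpha, beta) is singular on the
    hyperbola p*m = 1.
    """

    p: float
    m: float

    def __post_init__(self) -> None:
        if not (self.p >= 0 and self.m > 0):
            raise ValueError(f"rates must be positive, got p={self.p}, m={self.m}")
        if math.isclose(self.p * self.m, 1.0, rel_tol=0.0, abs_tol=1e-12):
            raise SingularRatesError(
                f"p*m = {self.p * self.m} is (numerically) 1: the parameter "
                "derivation alpha=(1-p)/(1-p*m), beta=(m-1)/(1-p*m) is singular"
            )


def _validate_x(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("length of stay x must be nonnegative")
    return arr


def lomax_pdf(x, params: LomaxParams):
    """Density (alpha/beta) * (1 + x/beta)^-(alpha+1); strictly decreasing."""
    arr = _validate_x(x)
    a, b = params.shape, params.scale
    out = (a / b) * np.power(1.0 + arr / b, -(a + 1.0))
    return out if out.ndim else float(out)


def lomax_cdf(x, params: LomaxParams):
    """Distribution function 1 - (1 + x/beta)^-alpha."""
    arr = _validate_x(x)
    a, b = params.shape, params.scale
    out = 1.0 - np.power(1.0 + arr / b, -a)
    return out if out.ndim else float(out)


def lomax_survival(x, params: LomaxParams):
    """Exceedance probability P(X > x) = (1 + x/beta)^-alpha.

    This is the quantity behind statements like "probability the stay
    exceeds 10 days"; e.g. with alpha=2, beta=1 it gives
    S(10) = 11^-2 = 0.008264..., i.e. 0.0083 at four decimals.
    """
    arr = _validate_x(x)
    a, b = params.shape, params.scale
    out = np.power(1.0 + arr / b, -a)
    return out if out.ndim else float(out)


def lomax_mean(params: LomaxParams) -> float:
    """Mean beta/(alpha-1); raises :class:`UndefinedMeanError` if alpha <= 1."""
    if params.shape <= 1:
        raise UndefinedMeanError(
            f"Lomax mean undefined for shape={params.shape} <= 1"
        )
    return params.scale / (params.shape - 1.0)


def params_from_rates(rates: RateInputs) -> LomaxParams:
    """Derive Lomax parameters from hospital rates.

        alpha = (1 - p) / (1 - p*m)
        beta  = (m - 1) / (1 - p*m)

    The derivation equates the Lomax mean with 1/p and with m, so it is only
    meaningful away from the singularity p*m = 1, and it requires the
    resulting alpha and beta to be positive (m > 1 when p*m < 1).
    """
    denom = 1.0 - rates.p * rates.m
    alpha = (1.0 - rates.p) / denom
    beta = (rates.m - 1.0) / denom
    if alpha <= 0 or beta <= 0:
        raise ValueError(
            f"rates p={rates.p}, m={rates.m} yield non-positive Lomax "
            f"parameters alpha={alpha:.6g}, beta={beta:.6g}"
        )
    return LomaxParams(shape=alpha, scale=beta)


def rates_from_counts(
    admissions: float,
    patient_days: float,
    beds: float,
    convention: str = "reconstructed",
) -> RateInputs:
    """Build (p, m) from a department's annual admissions, patient-days and beds.

    Two conventions are supported:

    ``reconstructed`` (default)
        p = admissions / (100 * patient_days), m = patient_days / (100 * beds).
        This is the scaling that reproduces published department tables where
        p is printed at the 1e-3..1e-2 magnitude and m in the 1..6 range.

    ``literal``
        p = admissions / patient_days and m = (beds / patient_days) * ALOS
        = beds / admissions, i.e. the prose definitions taken at face value.
    """
    if patient_days <= 0 or beds <= 0 or admissions <= 0:
        raise ValueError("admissions, patient_days and beds must be positive")
    if convention == "reconstructed":
        return RateInputs(p=admissions / (100.0 * patient_days), m=patient_days / (100.0 * beds))
    if convention == "literal":
        alos = patient_days / admissions
        return RateInputs(p=admissions / patient_days, m=(beds / patient_days) * alos)
    raise ValueError(f"unknown rate convention {convention!r}")


def rates_from_table(record, convention: str = "reconstructed") -> RateInputs:
    """Rates for a department record (anything with admissions/patient_days/beds)."""
    return rates_from_counts(
        record.admissions, record.patient_days, record.beds, convention
    )


def stay_mass(
    params: LomaxParams, min_stay: int = 5, max_stay: int = 365
) -> float:
    """Sum of the Lomax density over whole days in ``[min_stay, max_stay]``.

    zeta = sum_{z=min_stay}^{max_stay} f(z).  The default window starts at 5
    days (short stays are not counted toward the bed-pressure score) and ends
    at one year.  The density is evaluated at integer days with no
    bin-integral correction.
    """
    if not (0 <= min_stay <= max_stay):
        raise ValueError(f"need 0 <= min_stay <= max_stay, got {min_stay}..{max_stay}")
    z = np.arange(min_stay, max_stay + 1, dtype=float)
    return float(np.sum(lomax_pdf(z, params)))


def adjusted_plos(zeta: float, beds: int, cap_fraction: float = 0.1) -> float:
    """Capacity-adjusted stay score P(LOS) = zeta * (1 + cap_fraction * beds).

    The raw mass ``zeta`` is scaled up by a term proportional to bed capacity
    (default 10% per bed), so that larger departments carry proportionally
    larger stay scores when converted into bed needs.
    """
    if zeta < 0:
        raise ValueError("zeta must be nonnegative")
    if beds < 1:
        raise ValueError("beds must be >= 1")
    return zeta * (1.0 + cap_fraction * beds)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting and goodness of fit
# ---------------------------------------------------------------------------

# family -> (frozen builder (shape, scale), fitter -> (shape|None, scale), k)
# loc is pinned at 0 throughout: stays live on [0, inf).
def _shape_scale(theta):
    return float(theta[0]), float(theta[-1])


_FAMILIES = {
    "lomax": (lambda sh, sc: stats.lomax(sh, loc=0.0, scale=sc),
              lambda x: _shape_scale(stats.lomax.fit(x, floc=0.0)), 2),
    "pareto": (lambda sh, sc: stats.pareto(sh, loc=0.0, scale=sc),
               lambda x: _shape_scale(stats.pareto.fit(x, floc=0.0)), 2),
    "powerlaw": (lambda sh, sc: stats.powerlaw(sh, loc=0.0, scale=sc),
                 lambda x: _shape_scale(stats.powerlaw.fit(x, floc=0.0)), 2),
    "exponential": (lambda sh, sc: stats.expon(loc=0.0, scale=sc),
                    lambda x: (None, float(stats.expon.fit(x, floc=0.0)[1])), 1),
}

GOF_FAMILIES = tuple(_FAMILIES)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to a length-of-stay sample."""

    family: str
    shape: float | None
    scale: float
    loglik: float
    n: int
    n_params: int

    def frozen(self):
        """The fitted scipy frozen distribution."""
        builder, _, _ = _FAMILIES[self.family]
        return builder(self.shape, self.scale)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "shape": self.shape,
            "scale": self.scale,
            "loglik": self.loglik,
            "n": self.n,
        }


@dataclass(frozen=True)
class GofResult:
    """K-S and information-criterion summary for one fitted family."""

    family: str
    ks_statistic: float
    ks_pvalue: float
    aic: float
    bic: float
    n: int
    fit: FitResult

    def to_dict(self) -> dict:
        d = self.fit.to_dict()
        d.update(ks=self.ks_statistic, ks_p=self.ks_pvalue, aic=self.aic, bic=self.bic)
        return d


def _as_sample(samples: Iterable[float]) -> np.ndarray:
    x = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                   dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("length-of-stay samples must be positive finite reals")
    return x


def fit_mle(samples: Sequence[float], family: str = "lomax") -> FitResult:
    """Fit one distribution family by maximum likelihood (location pinned at 0).

    Raises :class:`FitError` on degenerate (constant) samples and on
    non-convergence (non-finite log-likelihood at the reported optimum).
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {GOF_FAMILIES}")
    x = _as_sample(samples)
    if np.ptp(x) == 0.0:
        raise FitError(
            f"sample is constant ({x[0]}): the {family} likelihood has no "
            "interior maximum"
        )
    builder, fitter, k = _FAMILIES[family]
    try:
        shape, scale = fitter(x)
    except Exception as exc:  # scipy raises a mix of FitError/RuntimeError/ValueError
        raise FitError(f"{family} MLE failed: {exc}") from exc
    loglik = float(np.sum(builder(shape, scale).logpdf(x)))
    if not np.isfinite(loglik):
        raise FitError(
            f"{family} MLE did not converge: log-likelihood is {loglik} at "
            f"shape={shape}, scale={scale}"
        )
    return FitResult(family=family, shape=shape, scale=scale,
                     loglik=loglik, n=int(x.size), n_params=k)


def gof_compare(
    samples: Sequence[float], families: Sequence[str] = GOF_FAMILIES
) -> list[GofResult]:
    """Fit several families and rank them by AIC (best first).

    Per family: plain Kolmogorov-Smirnov statistic and p-value of the fitted
    CDF against the empirical CDF (no small-sample correction for estimated
    parameters), AIC = 2k - 2 ln L and BIC = k ln n - 2 ln L.  A family whose
    fit fails is skipped rather than aborting the whole table.
    """
    x = _as_sample(samples)
    results: list[GofResult] = []
    for family in families:
        try:
            fit = fit_mle(x, family)
        except FitError:
            continue
        ks = stats.kstest(x, fit.frozen().cdf)
        k, ll, n = fit.n_params, fit.loglik, fit.n
        results.append(
            GofResult(
                family=family,
                ks_statistic=float(ks.statistic),
                ks_pvalue=float(ks.pvalue),
                aic=2.0 * k - 2.0 * ll,
                bic=k * math.log(n) - 2.0 * ll,
                n=n,
                fit=fit,
            )
        )
    if not results:
        raise FitError("every requested family failed to fit")
    results.sort(key=lambda r: r.aic)
    return results
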