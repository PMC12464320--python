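"""Individual-MIC (iMIC) distribution model.

The fraction of singly encapsulated cells that still proliferate at
antibiotic concentration ``c`` is modelled by the Gompertz-type survival
function

    phi(c) = exp{-(c / p1)^p2}

where ``p1`` is the concentration at maximum slope (scale) and ``p2`` the
dimensionless slope parameter at ``c = p1`` (shape).  phi is exactly the
survival function of a Weibull(scale=p1, shape=p2) distribution, so the
per-cell iMIC density is the Weibull density

    p(c) = (p2 c^(p2-1) / p1^p2) exp{-(c/p1)^p2} = -dphi/dc

and every summary statistic (mode, mean, SD, skewness, kurtosis, threshold
concentrations, degree of heteroresistance) has a gamma-function closed
form.  This module fits phi to a normalized resistance profile and computes
the full statistic suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import integrate, optimize
from scipy.special import gammaln

from .profiles import CountTable, ResistanceProfile

__all__ = [
    "GompertzFit",
    "ThresholdPolicy",
    "Moments",
    "IMICSummary",
    "FitError",
    "gompertz_survival",
    "pdf_imic",
    "imic_mode",
    "closed_form_moments",
    "solve_threshold",
    "solve_shape_scale",
    "imic_exp",
    "fit_gompertz",
    "summarize",
    "degree_of_heteroresistance",
    "rmsd",
    "cov",
]


def _gamma(x: float) -> float:
    """Gamma function via log-gamma (avoids overflow for extreme shapes)."""
    return math.exp(gammaln(x))


# ---------------------------------------------------------------------------
# survival / density / mode


def gompertz_survival(c, p1: float, p2: float):
    """Surviving (still-proliferating) fraction phi(c) = exp{-(c/p1)^p2}.

    Parameters
    ----------
    c : float or array-like
        Antibiotic concentration(s), >= 0, in the same unit as ``p1``.
    p1 : float
        Concentration at maximum slope (Weibull scale), > 0.
    p2 : float
        Slope parameter at c = p1 (Weibull shape), > 0.
    """
    if p1 <= 0:
        raise ValueError(f"p1 must be > 0, got {p1}")
    if p2 <= 0:
        raise ValueError(f"p2 must be > 0, got {p2}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration c must be >= 0")
    out = np.exp(-((c / p1) ** p2))
    return float(out) if out.ndim == 0 else out


def pdf_imic(c, p1: float, p2: float):
    """iMIC probability density p(c) = (p2 c^(p2-1)/p1^p2) exp{-(c/p1)^p2}.

    Equals -dphi/dc; integrates to 1 on [0, inf).  For p2 < 1 the density
    diverges at the origin (still integrable); p(0) is returned as +inf
    there, 1/p1 for p2 == 1 and 0 for p2 > 1.
    """
    if p1 <= 0 or p2 <= 0:
        raise ValueError("p1 and p2 must be > 0")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration c must be >= 0")
    with np.errstate(divide="ignore"):
        out = (p2 * c ** (p2 - 1.0) / p1**p2) * np.exp(-((c / p1) ** p2))
    if p2 == 1.0:
        out = np.where(c == 0.0, 1.0 / p1, out)
    return float(out) if out.ndim == 0 else out


def imic_mode(p1: float, p2: float) -> float:
    """Most probable iMIC: the inflection point of the fitted curve.

    Solving d^2 phi / dc^2 = 0 gives  c_mode = p1 (1 - 1/p2)^(1/p2).
    For p2 <= 1 the density is monotone decreasing and the mode degenerates
    to the origin; 0.0 is returned with a warning.
    """
    if p1 <= 0 or p2 <= 0:
        raise ValueError("p1 and p2 must be > 0")
    if p2 <= 1.0:
        if p2 < 1.0:
            warnings.warn(
                f"p2={p2} <= 1: iMIC density has no interior mode; returning 0",
                stacklevel=2,
            )
        return 0.0
    return p1 * (1.0 - 1.0 / p2) ** (1.0 / p2)


# ---------------------------------------------------------------------------
# moments


@dataclass(frozen=True)
class Moments:
    """Closed-form Weibull moments with numerical-integration error estimates.

    ``errors`` holds |closed form - adaptive quadrature| per statistic; these
    play the role of the tiny "(+/- 3e-07)"-style annotations reported next
    to skewness and kurtosis.
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    errors: dict = field(default_factory=dict)


def _raw_moment(p1: float, p2: float, k: int) -> float:
    # E[c^k] = p1^k Gamma(1 + k/p2)
    return math.exp(k * math.log(p1) + gammaln(1.0 + k / p2))


def closed_form_moments(p1: float, p2: float, numerical_check: bool = True) -> Moments:
    """Mean, SD, skewness and (Pearson) kurtosis of the iMIC distribution.

    Closed forms from the Weibull raw moments E[c^k] = p1^k Gamma(1 + k/p2):

        mu    = (p1/p2) Gamma(1/p2) = p1 Gamma(1 + 1/p2)
        sigma = sqrt{ (2 p1^2/p2) Gamma(2/p2) - (p1^2/p2^2) Gamma^2(1/p2) }
        gamma = [ (3 p1^3/p2) Gamma(3/p2) - mu (3 sigma^2 + mu^2) ] / sigma^3
        kurt  = mu4 / sigma^4   (fourth central moment over variance squared)

    With ``numerical_check`` (default) each statistic is recomputed by
    adaptive quadrature of the density and the absolute discrepancies are
    stored in ``Moments.errors``.
    """
    if p1 <= 0 or p2 <= 0:
        raise ValueError("p1 and p2 must be > 0")
    m1, m2, m3, m4 = (_raw_moment(p1, p2, k) for k in (1, 2, 3, 4))
    var = m2 - m1 * m1
    sd = math.sqrt(var)
    mu3 = m3 - 3.0 * m1 * var - m1**3
    skew = mu3 / sd**3
    mu4 = m4 - 4.0 * m1 * m3 + 6.0 * m1 * m1 * m2 - 3.0 * m1**4
    kurt = mu4 / (var * var)

    errors: dict = {}
    if numerical_check:
        def central(k: int, mu: float) -> float:
            f = lambda c: (c - mu) ** k * pdf_imic(c, p1, p2)
            upper = p1 * (-math.log(1e-16)) ** (1.0 / p2)
            val, _ = integrate.quad(f, 0.0, upper, limit=200)
            return val

        n_mean, _ = integrate.quad(
            lambda c: c * pdf_imic(c, p1, p2),
            0.0,
            p1 * (-math.log(1e-16)) ** (1.0 / p2),
            limit=200,
        )
        n_var = central(2, n_mean)
        n_sd = math.sqrt(n_var)
        n_skew = central(3, n_mean) / n_sd**3
        n_kurt = central(4, n_mean) / n_var**2
        errors = {
            "mean": abs(m1 - n_mean),
            "sd": abs(sd - n_sd),
            "skewness": abs(skew - n_skew),
            "kurtosis": abs(kurt - n_kurt),
        }
    return Moments(mean=m1, sd=sd, skewness=skew, kurtosis=kurt, errors=errors)


# ---------------------------------------------------------------------------
# thresholds and shape/scale recovery


def solve_threshold(p1: float, p2: float, eps: float) -> float:
    """Concentration c at which the surviving fraction equals ``eps``.

    Closed-form inversion c = p1 (-ln eps)^(1/p2); phi(c) == eps to machine
    precision.  ``eps`` must lie strictly inside (0, 1).
    """
    if not 0.0 < eps < 1.0:
        raise ValueError(f"eps must be in (0, 1), got {eps}")
    if p1 <= 0 or p2 <= 0:
        raise ValueError("p1 and p2 must be > 0")
    return p1 * (-math.log(eps)) ** (1.0 / p2)


_MODE_MEAN_RATIO_PEAK = 6.4968593418394  # argmax of (1-1/p2)^(1/p2)/Gamma(1+1/p2)


def _mode_mean_ratio(p2: float) -> float:
    return (1.0 - 1.0 / p2) ** (1.0 / p2) / _gamma(1.0 + 1.0 / p2)


def solve_shape_scale(mode: float, mean: float, branch: str = "low") -> tuple[float, float]:
    """Recover (p1, p2) from a printed (mode, mean) pair.

    The ratio mode/mean = (1-1/p2)^(1/p2) / Gamma(1+1/p2) is not monotone in
    p2: it rises from 0 (p2 -> 1) to ~1.0460 at p2 ~ 6.50 and then falls back
    towards 1.  A ratio in (1, 1.0460) therefore has two solutions.  The
    default ``branch='low'`` takes the rising-branch (smaller p2) root, which
    is the one consistent with the broad, visibly dispersed iMIC
    distributions this model targets; ``branch='high'`` selects the other.
    """
    if mode <= 0 or mean <= 0:
        raise ValueError("mode and mean must be > 0")
    r = mode / mean
    peak_r = _mode_mean_ratio(_MODE_MEAN_RATIO_PEAK)
    if r >= peak_r:
        raise ValueError(
            f"mode/mean ratio {r:.4f} exceeds the attainable maximum {peak_r:.4f}"
        )
    if branch == "low":
        lo, hi = 1.0 + 1e-9, _MODE_MEAN_RATIO_PEAK
    elif branch == "high":
        lo, hi = _MODE_MEAN_RATIO_PEAK, 1e4
    else:
        raise ValueError("branch must be 'low' or 'high'")
    if branch == "high" and r <= 1.0:
        raise ValueError("high branch requires mode/mean > 1")
    p2 = optimize.brentq(lambda p: _mode_mean_ratio(p) - r, lo, hi, xtol=1e-12)
    p1 = mean / _gamma(1.0 + 1.0 / p2)
    return p1, p2


def imic_exp(tables: Sequence[CountTable]) -> float | None:
    """Experimentally observed complete-inhibition concentration.

    The smallest tested concentration at which no replicate shows a single
    positive droplet, there and at every higher tested concentration.
    Returns ``None`` when growth persists to the top of the grid
    ("not reached").
    """
    if not tables:
        raise ValueError("at least one count table is required")
    grids = [tuple(t.data["concentration"]) for t in tables]
    if len(set(grids)) != 1:
        raise ValueError("replicates must share the same concentration grid")
    conc = np.asarray(grids[0], dtype=float)
    pos = np.vstack([t.data["n_positive"].to_numpy() for t in tables])
    all_zero = (pos == 0).all(axis=0)
    # require zero from c upward (complete inhibition, not a transient dip)
    suffix_zero = np.flip(np.logical_and.accumulate(np.flip(all_zero)))
    idx = np.nonzero(suffix_zero)[0]
    if idx.size == 0:
        return None
    return float(conc[idx[0]])


# ---------------------------------------------------------------------------
# fitting


class FitError(RuntimeError):
    """Raised when the Gompertz fit fails; carries best-so-far parameters."""

    def __init__(self, message: str, p1: float, p2: float, rss: float):
        super().__init__(message)
        self.p1 = p1
        self.p2 = p2
        self.rss = rss


@dataclass(frozen=True)
class GompertzFit:
    """Result of least-squares fitting phi(c) to a resistance profile."""

    p1: float
    p2: float
    rss: float
    converged: bool
    c_max_tested: float
    n_points: int
    unit: str = ""
    extrapolated: bool = False  # p1 beyond the tested grid: fit is a tail guess

    def survival(self, c):
        return gompertz_survival(c, self.p1, self.p2)

    def pdf(self, c):
        return pdf_imic(c, self.p1, self.p2)


def fit_gompertz(
    profile: ResistanceProfile,
    weights: np.ndarray | None = None,
    p2_starts: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
) -> GompertzFit:
    """Fit phi(c) = exp{-(c/p1)^p2} to F_R(c) by least squares.

    Minimizes sum w(c) (F_R(c) - phi(c))^2 over p1, p2 > 0 with multi-start
    initialization: p1_0 is the grid concentration whose F_R is nearest 0.5
    (falling back to the median positive concentration) and p2_0 runs over
    ``p2_starts``; the lowest residual sum of squares wins, ties broken by
    the smaller p2.  The c = 0 point (F_R = 1 by construction) is included.

    Raises ``FitError`` if no start converges.  A profile whose F_R never
    drops below 0.5 triggers a warning (scale is then poorly constrained),
    and a fitted p1 beyond the tested grid is flagged via ``extrapolated``.
    """
    c = np.asarray(profile.concentration, dtype=float)
    y = np.asarray(profile.f_r, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 concentrations to fit")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must match the profile length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    sw = np.sqrt(w)

    if np.min(y) >= 0.5:
        warnings.warn(
            "no F_R value below 0.5 on the tested grid; the fitted scale p1 "
            "is poorly constrained",
            stacklevel=2,
        )

    pos = c[c > 0]
    below = np.abs(y - 0.5)
    p1_0 = float(c[np.argmin(below)]) if np.min(y) < 0.75 else float(np.median(pos))
    if p1_0 <= 0:
        p1_0 = float(np.median(pos))

    def residuals(theta):
        lp1, lp2 = theta
        return sw * (y - gompertz_survival(c, float(np.exp(lp1)), float(np.exp(lp2))))

    best = None
    for p2_0 in p2_starts:
        try:
            res = optimize.least_squares(
                residuals,
                x0=[math.log(p1_0), math.log(p2_0)],
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        cand = (rss, float(np.exp(res.x[1])), float(np.exp(res.x[0])), res.success)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitError("Gompertz fit failed from every start", math.nan, math.nan, math.inf)
    rss, p2, p1, success = best
    if not success or not (math.isfinite(p1) and math.isfinite(p2)):
        raise FitError("Gompertz fit did not converge", p1, p2, rss)
    c_max = float(np.max(c))
    return GompertzFit(
        p1=p1,
        p2=p2,
        rss=rss,
        converged=True,
        c_max_tested=c_max,
        n_points=int(c.size),
        unit=profile.unit,
        extrapolated=bool(p1 > c_max),
    )


# ---------------------------------------------------------------------------
# summary statistics


@dataclass(frozen=True)
class ThresholdPolicy:
    """Survival levels that define the threshold concentrations.

    ``eps_start`` (default 0.99): first detectable drop in the fitted growth
    fraction, (iMIC)_start.  ``eps_total`` (0.05): growth inhibited in > 95%
    of droplets, (iMIC)_total.  ``eps_all`` (0.001): operational "complete"
    inhibition, (iMIC)_all — complete inhibition is asymptotically
    unreachable on a Gompertz curve, so a near-zero survival level stands in.
    (iMIC)_all is reported as not determinable (ND) whenever the solved
    concentration exceeds the highest tested concentration.
    """

    eps_start: float = 0.99
    eps_total: float = 0.05
    eps_all: float = 0.001

    def __post_init__(self):
        if not (0.0 < self.eps_all < self.eps_total < self.eps_start < 1.0):
            raise ValueError("require 0 < eps_all < eps_total < eps_start < 1")


def degree_of_heteroresistance(imic_all: float, imic_start: float) -> float:
    """DoH: the ratio (iMIC)_all / (iMIC)_start.

    Measures how widely the iMIC distribution spreads along the
    concentration axis; when (iMIC)_all is not determinable from the fit the
    experimentally observed (iMIC)_exp is used in its place by ``summarize``.
    """
    if imic_start <= 0:
        raise ValueError("imic_start must be > 0 for DoH")
    if imic_all <= 0:
        raise ValueError("imic_all must be > 0 for DoH")
    return imic_all / imic_start


def rmsd(sd: float, mode: float) -> float:
    """Root-mean-square deviation: SD / (iMIC)_mode (dispersion vs the mode)."""
    if mode <= 0:
        raise ValueError("mode must be > 0 for RMSD")
    return sd / mode


def cov(sd: float, mean: float) -> float:
    """Coefficient of variation: SD / mean."""
    if mean <= 0:
        raise ValueError("mean must be > 0 for CoV")
    return sd / mean


@dataclass
class IMICSummary:
    """Full statistic suite of one sample's iMIC distribution."""

    p1: float
    p2: float
    imic_mode: float
    imic_mean: float
    imic_sd: float
    imic_skewness: float
    imic_kurtosis: float
    rmsd: float | None
    cov: float
    imic_start: float
    imic_total: float
    imic_all: float | None
    imic_all_status: str  # "determined" | "ND"
    imic_exp: float | None
    imic_exp_status: str  # "observed" | "not_reached" | "unavailable"
    doh: float | None
    doh_status: str  # "from_fit" | "from_exp" | "undefined"
    unit: str
    numerical_error_estimates: dict

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    fit: GompertzFit,
    policy: ThresholdPolicy | None = None,
    raw_tables: Sequence[CountTable] | None = None,
) -> IMICSummary:
    """Compute the complete iMIC statistic suite from a converged fit.

    Threshold concentrations come from the closed-form inversion at the
    policy's survival levels.  (iMIC)_all is flagged ND when its solved
    concentration lies beyond the highest tested concentration (the fitted
    tail is then an extrapolation, "infinitely long" on the tested axis);
    in that case (iMIC)_exp — the lowest tested concentration with zero
    positive droplets in every replicate — substitutes for it in the DoH.
    """
    if not fit.converged:
        raise ValueError("summarize requires a converged fit")
    policy = policy or ThresholdPolicy()

    mode = imic_mode(fit.p1, fit.p2)
    moments = closed_form_moments(fit.p1, fit.p2)
    c_start = solve_threshold(fit.p1, fit.p2, policy.eps_start)
    c_total = solve_threshold(fit.p1, fit.p2, policy.eps_total)
    c_all_solved = solve_threshold(fit.p1, fit.p2, policy.eps_all)

    if c_all_solved <= fit.c_max_tested:
        c_all, all_status = c_all_solved, "determined"
    else:
        c_all, all_status = None, "ND"

    if raw_tables is not None:
        c_exp = imic_exp(raw_tables)
        exp_status = "observed" if c_exp is not None else "not_reached"
    else:
        c_exp, exp_status = None, "unavailable"

    doh_value: float | None
    if c_start <= 0:
        doh_value, doh_status = None, "undefined"
    elif c_all is not None:
        doh_value, doh_status = degree_of_heteroresistance(c_all, c_start), "from_fit"
    elif c_exp is not None:
        doh_value, doh_status = degree_of_heteroresistance(c_exp, c_start), "from_exp"
    else:
        doh_value, doh_status = None, "undefined"

    return IMICSummary(
        p1=fit.p1,
        p2=fit.p2,
        imic_mode=mode,
        imic_mean=moments.mean,
        imic_sd=moments.sd,
        imic_skewness=moments.skewness,
        imic_kurtosis=moments.kurtosis,
        rmsd=rmsd(moments.sd, mode) if mode > 0 else None,
        cov=cov(moments.sd, moments.mean),
        imic_start=c_start,
        imic_total=c_total,
        imic_all=c_all,
        imic_all_status=all_status,
        imic_exp=c_exp,
        imic_exp_status=exp_status,
        doh=doh_value,
        doh_status=doh_status,
        unit=fit.unit,
        numerical_error_estimates=moments.errors,
    )
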