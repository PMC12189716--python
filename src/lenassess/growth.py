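"""Growth modelling: length-weight allometry, von Bertalanffy growth, and the
derived life-history quantities used for harvest advice.

The length-weight relation is the power law ``W = a L**b`` (b near 3 means
isometric growth).  Length-at-age follows the von Bertalanffy growth function
(VBGF) ``L_t = L_inf * (1 - exp(-k (t - t0)))`` and weight-at-age is obtained
by composing the two: ``W_t = W_inf * (1 - exp(-k (t - t0)))**b`` with
``W_inf = a * L_inf**b``.  From the fitted parameters the module derives

* growth rate and acceleration curves for length and weight (the first and
  second derivatives of the growth equations),
* the inflection-point age ``t_i = ln(b)/k + t0`` at which the weight growth
  rate peaks,
* the critical age ``t_c = [k t0 - ln M + ln(b k + M)] / k`` at which an
  unfished cohort's biomass peaks (M is the natural mortality rate), and
* the growth performance index ``phi = log10(k) + 2 log10(L_inf)`` used to
  compare growth across populations (L_inf in mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DomainError, FitError, InsufficientDataError
from .records import as_frame, validate_records

__all__ = [
    "LengthWeightParams",
    "VBGFParams",
    "WeightGrowthParams",
    "GrowthSummary",
    "fit_length_weight",
    "fit_vbgf_length",
    "derive_weight_growth",
    "length_at_age",
    "weight_at_age",
    "growth_rate_length",
    "growth_accel_length",
    "growth_rate_weight",
    "growth_accel_weight",
    "inflection_age",
    "critical_age",
    "growth_performance_index",
    "growth_summary",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthWeightParams:
    """Fitted ``W = a L**b`` coefficients for one group.

    ``a`` is on the linear scale (g / mm**b); ``se_b`` is the standard error
    of the exponent from the regression actually run.
    """

    a: float
    b: float
    n: int
    r_squared: float
    se_b: float

    def isometric(self, criterion: float = 0.08) -> bool:
        """True when b is within ``criterion`` of 3 (isometric growth)."""
        return abs(self.b - 3.0) <= criterion

    @property
    def b_t_statistic(self) -> float:
        """t statistic for H0: b = 3."""
        return (self.b - 3.0) / self.se_b


@dataclass(frozen=True)
class VBGFParams:
    """Von Bertalanffy length-growth parameters.

    L_inf in mm, k in 1/year, t0 in years.  Fit metadata (sample size,
    residual sum of squares, convergence flag) rides along when the
    parameters come from :func:`fit_vbgf_length`.
    """

    L_inf: float
    k: float
    t0: float
    n: int | None = None
    rss: float | None = None
    converged: bool = True


@dataclass(frozen=True)
class WeightGrowthParams:
    """Derived weight-growth parameters: W_inf = a * L_inf**b, with (k, t0, b)
    carried over unchanged from the length fits."""

    W_inf: float
    b: float
    k: float
    t0: float


@dataclass(frozen=True)
class GrowthSummary:
    """Inflection-point age, critical age, and growth performance index."""

    t_i: float
    t_c: float
    phi: float


# ---------------------------------------------------------------------------
# length-weight allometry
# ---------------------------------------------------------------------------

def fit_length_weight(records, method: str = "log10") -> LengthWeightParams:
    """Fit the power law ``W = a L**b``.

    Parameters
    ----------
    records
        FishRecord collection / DataFrame with positive ``length_mm`` and
        ``weight_g``; at least 3 distinct lengths.
    method
        ``"log10"`` (default): ordinary least squares of log10(W) on
        log10(L); ``a`` is back-transformed to the linear scale.
        ``"nls"``: direct nonlinear least squares on the raw scale
        (initialised from the log fit).  r_squared and se_b are reported on
        the scale of the regression run.
    """
    df = validate_records(as_frame(records))
    L = df["length_mm"].to_numpy(dtype=float)
    W = df["weight_g"].to_numpy(dtype=float)
    if np.unique(L).size < 3:
        raise InsufficientDataError(
            f"length-weight fit needs >= 3 distinct lengths, got {np.unique(L).size}")
    n = L.size

    x = np.log10(L)
    y = np.log10(W)
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    log10_a, b = beta
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = max(n - 2, 1)
    sigma2 = rss / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    se_b = math.sqrt(sigma2 / sxx)
    a = 10.0 ** log10_a

    if method == "log10":
        return LengthWeightParams(a=a, b=float(b), n=n, r_squared=float(r2), se_b=se_b)
    if method != "nls":
        raise ValueError(f"unknown method {method!r}")

    def model(params):
        la, bb = params
        return np.exp(la) * L ** bb - W

    sol = optimize.least_squares(model, x0=[math.log(a), b], method="lm")
    a_nls, b_nls = math.exp(sol.x[0]), float(sol.x[1])
    pred = a_nls * L ** b_nls
    rss_raw = float(((W - pred) ** 2).sum())
    tss_raw = float(((W - W.mean()) ** 2).sum())
    r2_raw = 1.0 - rss_raw / tss_raw if tss_raw > 0 else 1.0
    # se(b) from the Jacobian at the solution
    J = sol.jac
    cov = np.linalg.inv(J.T @ J) * rss_raw / dof
    return LengthWeightParams(a=a_nls, b=b_nls, n=n, r_squared=r2_raw,
                              se_b=float(math.sqrt(cov[1, 1])))


# ---------------------------------------------------------------------------
# von Bertalanffy length growth
# ---------------------------------------------------------------------------

def _vbgf(t, L_inf, k, t0):
    return L_inf * (1.0 - np.exp(-k * (t - t0)))


def fit_vbgf_length(records, use_age_means: bool = False) -> VBGFParams:
    """Fit the VBGF to length-at-age by nonlinear least squares.

    Levenberg-Marquardt with 5 multi-starts: L_inf starts at 1.05 x the
    largest observed length, t0 at -0.5, and k sweeps {0.05, 0.1, 0.2, 0.4,
    0.8} to guard against the well-known L_inf-k ridge.  The best residual
    wins; ties go to the start with the smallest |t0|.

    ``use_age_means=True`` fits age-class mean lengths instead of individual
    records (the default uses every fish).
    """
    df = validate_records(as_frame(records))
    if df["age"].nunique() < 4:
        raise InsufficientDataError(
            f"VBGF fit needs >= 4 distinct ages, got {df['age'].nunique()}")
    if use_age_means:
        g = df.groupby("age")["length_mm"].mean()
        t = g.index.to_numpy(dtype=float)
        L = g.to_numpy(dtype=float)
    else:
        t = df["age"].to_numpy(dtype=float)
        L = df["length_mm"].to_numpy(dtype=float)
    n = L.size
    L_max = float(L.max())

    def resid(p):
        return _vbgf(t, *p) - L

    best = None
    for k0 in (0.05, 0.1, 0.2, 0.4, 0.8):
        try:
            sol = optimize.least_squares(resid, x0=[1.05 * L_max, k0, -0.5], method="lm")
        except Exception:
            continue
        rss = float(sol.cost * 2.0)
        cand = (rss, abs(sol.x[2]), sol)
        if sol.success and (best is None or cand[:2] < best[:2]):
            best = cand
    if best is None:
        raise FitError("VBGF fit did not converge from any start")
    rss, _, sol = best
    L_inf, k, t0 = (float(v) for v in sol.x)
    if not (k > 0 and L_inf > 0):
        raise FitError("VBGF fit converged to a non-physical optimum",
                       params=(L_inf, k, t0), rss=rss)
    return VBGFParams(L_inf=L_inf, k=k, t0=t0, n=n, rss=rss, converged=True)


def derive_weight_growth(vbgf: VBGFParams, lw: LengthWeightParams) -> WeightGrowthParams:
    """Compose the fitted allometry with the VBGF: W_inf = a * L_inf**b.

    W_inf is derived exactly, never refit; (k, t0, b) are carried unchanged.
    """
    return WeightGrowthParams(W_inf=lw.a * vbgf.L_inf ** lw.b, b=lw.b,
                              k=vbgf.k, t0=vbgf.t0)


# ---------------------------------------------------------------------------
# growth curves and derivatives
# ---------------------------------------------------------------------------

def _check_age(t, t0):
    if np.any(np.asarray(t, dtype=float) < t0):
        raise DomainError(f"age t must be >= t0 = {t0}")


def length_at_age(vbgf: VBGFParams, t):
    """VBGF mean length (mm) at age t (years); t >= t0."""
    _check_age(t, vbgf.t0)
    return _vbgf(np.asarray(t, dtype=float), vbgf.L_inf, vbgf.k, vbgf.t0)


def weight_at_age(wg: WeightGrowthParams, t):
    """Mean weight (g) at age t: W_inf * (1 - exp(-k (t - t0)))**b."""
    _check_age(t, wg.t0)
    t = np.asarray(t, dtype=float)
    return wg.W_inf * (1.0 - np.exp(-wg.k * (t - wg.t0))) ** wg.b


def growth_rate_length(vbgf: VBGFParams, t):
    """dL/dt = L_inf k exp(-k (t - t0)), mm/year; strictly positive and
    decreasing."""
    _check_age(t, vbgf.t0)
    t = np.asarray(t, dtype=float)
    return vbgf.L_inf * vbgf.k * np.exp(-vbgf.k * (t - vbgf.t0))


def growth_accel_length(vbgf: VBGFParams, t):
    """d2L/dt2 = -L_inf k**2 exp(-k (t - t0)), mm/year**2; strictly negative."""
    _check_age(t, vbgf.t0)
    t = np.asarray(t, dtype=float)
    return -vbgf.L_inf * vbgf.k ** 2 * np.exp(-vbgf.k * (t - vbgf.t0))


def growth_rate_weight(wg: WeightGrowthParams, t):
    """dW/dt = b W_inf k exp(-k tau) (1 - exp(-k tau))**(b-1), g/year, with
    tau = t - t0; peaks at the inflection age t_i."""
    _check_age(t, wg.t0)
    t = np.asarray(t, dtype=float)
    e = np.exp(-wg.k * (t - wg.t0))
    return wg.b * wg.W_inf * wg.k * e * (1.0 - e) ** (wg.b - 1.0)


def growth_accel_weight(wg: WeightGrowthParams, t):
    """d2W/dt2 = b W_inf k**2 exp(-k tau) (1 - exp(-k tau))**(b-2)
    (b exp(-k tau) - 1), g/year**2; changes sign exactly once, at t_i."""
    _check_age(t, wg.t0)
    t = np.asarray(t, dtype=float)
    e = np.exp(-wg.k * (t - wg.t0))
    return wg.b * wg.W_inf * wg.k ** 2 * e * (1.0 - e) ** (wg.b - 2.0) * (wg.b * e - 1.0)


# ---------------------------------------------------------------------------
# derived life-history quantities (closed form)
# ---------------------------------------------------------------------------

def inflection_age(b: float, k: float, t0: float) -> float:
    """Age at maximum weight growth rate: t_i = ln(b)/k + t0 (needs b > 1)."""
    if b <= 1.0:
        raise DomainError(f"inflection age requires b > 1, got b = {b}")
    if k <= 0:
        raise DomainError(f"inflection age requires k > 0, got k = {k}")
    return math.log(b) / k + t0


def critical_age(k: float, t0: float, b: float, M: float) -> float:
    """Age at which an unfished cohort's biomass peaks:
    t_c = [k t0 - ln M + ln(b k + M)] / k, with M the natural mortality
    rate (1/year)."""
    if M <= 0:
        raise DomainError(f"critical age requires M > 0, got M = {M}")
    if k <= 0:
        raise DomainError(f"critical age requires k > 0, got k = {k}")
    return (k * t0 - math.log(M) + math.log(b * k + M)) / k


def growth_performance_index(k: float, L_inf: float) -> float:
    """phi = log10(k) + 2 log10(L_inf), with L_inf in mm.

    The index is reported on the mm scale throughout this package; using cm
    would shift it by exactly -2.
    """
    if k <= 0 or L_inf <= 0:
        raise DomainError("growth performance index requires k > 0 and L_inf > 0")
    return math.log10(k) + 2.0 * math.log10(L_inf)


def growth_summary(vbgf: VBGFParams, b: float, M: float) -> GrowthSummary:
    """Bundle t_i, t_c and phi for one group."""
    return GrowthSummary(
        t_i=inflection_age(b, vbgf.k, vbgf.t0),
        t_c=critical_age(vbgf.k, vbgf.t0, b, M),
        phi=growth_performance_index(vbgf.k, vbgf.L_inf),
    )
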