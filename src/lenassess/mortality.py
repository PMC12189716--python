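"""Mortality and exploitation: the mean-length total-mortality estimator,
Pauly's empirical natural mortality, and the reliability diagnostics.

Total mortality Z comes from the Beverton-Holt mean-length estimator

    Z = k (L_inf - L_mean) / (L_mean - L_c)

where L_mean is the mean length of fish at or above the length at first
capture L_c (the estimator's derivation assumes knife-edge selection at L_c
and an equilibrium population).  Natural mortality M comes from Pauly's
empirical regression on L_inf, k and mean annual water temperature T; fishing
mortality is F = Z - M and the exploitation rate E = F/Z (E > 0.5 is the
conventional overfishing signal).

Two Pauly variants are provided.  The default, ``"base10_cm"``, is the
standard published form: base-10 logarithms with L_inf in cm,

    log10 M = -0.0066 - 0.279 log10 L_inf(cm) + 0.6543 log10 k + 0.4634 log10 T.

``"natural_log_mm"`` evaluates the same coefficients as natural logarithms
with L_inf in mm, a form that appears in some secondary sources; it yields
very different (usually implausible) M and exists so the difference can be
demonstrated and the variant used is always explicit in output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DomainError

__all__ = [
    "MortalityInputs",
    "MortalityDiagnostics",
    "MortalityEstimates",
    "beverton_holt_Z",
    "pauly_M",
    "fishing_mortality",
    "exploitation_rate",
    "mortality_diagnostics",
    "estimate_lc",
    "estimate_mortality",
    "PAULY_VARIANTS",
]

PAULY_VARIANTS = ("base10_cm", "natural_log_mm")


@dataclass(frozen=True)
class MortalityInputs:
    """Inputs of the mean-length estimator for one group."""

    L_mean: float  # mean length of the retained catch, mm
    L_c: float  # length at first capture, mm
    T: float  # mean annual water temperature, degC


@dataclass(frozen=True)
class MortalityDiagnostics:
    """Reliability ratios and their interpretation flags.

    * ``exp_neg_k`` < 1 is the growth-equation reliability criterion (always
      true for k > 0, but the ratio itself is reported).
    * ``M_over_K`` in [1, 2.5] is the accepted band for a trustworthy
      natural-mortality estimate.
    * ``Z_over_K`` vs 3 separates natural-dominated (< 3) from
      fishing-dominated (> 3) mortality regimes.
    """

    exp_neg_k: float
    M_over_K: float
    Z_over_K: float
    growth_reliable: bool
    M_reliable: bool
    fishing_dominated: bool


@dataclass(frozen=True)
class MortalityEstimates:
    """Full mortality decomposition for one group (Z = M + F exactly)."""

    Z: float
    M: float
    F: float
    E: float
    inputs: MortalityInputs
    diagnostics: MortalityDiagnostics
    pauly_variant: str


def beverton_holt_Z(k: float, L_inf: float, L_mean: float, L_c: float) -> float:
    """Mean-length total mortality Z = k (L_inf - L_mean)/(L_mean - L_c).

    Requires L_c < L_mean < L_inf; the error message says which ordering
    failed.
    """
    if not L_c < L_mean:
        raise DomainError(f"need L_c < L_mean, got L_c = {L_c} >= L_mean = {L_mean}")
    if not L_mean < L_inf:
        raise DomainError(f"need L_mean < L_inf, got L_mean = {L_mean} >= L_inf = {L_inf}")
    return k * (L_inf - L_mean) / (L_mean - L_c)


def pauly_M(L_inf_mm: float, k: float, T: float, variant: str = "base10_cm") -> float:
    """Pauly's empirical natural mortality (1/year).

    ``L_inf_mm`` is always passed in mm; the default variant converts to cm
    internally as the regression requires.  See module docstring for the two
    variants.
    """
    if min(L_inf_mm, k, T) <= 0:
        raise DomainError("pauly_M requires positive L_inf, k and T")
    if variant == "base10_cm":
        log10_M = (-0.0066 - 0.279 * math.log10(L_inf_mm / 10.0)
                   + 0.6543 * math.log10(k) + 0.4634 * math.log10(T))
        return 10.0 ** log10_M
    if variant == "natural_log_mm":
        ln_M = (-0.0066 - 0.279 * math.log(L_inf_mm)
                + 0.6543 * math.log(k) + 0.4634 * math.log(T))
        return math.exp(ln_M)
    raise ValueError(f"unknown Pauly variant {variant!r}; choose from {PAULY_VARIANTS}")


def fishing_mortality(Z: float, M: float) -> float:
    """F = Z - M.  A negative F is returned (not clamped) with a warning —
    it signals inconsistent inputs."""
    if Z <= 0:
        raise DomainError(f"fishing_mortality requires Z > 0, got {Z}")
    F = Z - M
    if F < 0:
        warnings.warn(f"F = Z - M = {F:.4g} is negative: Z and M are inconsistent",
                      stacklevel=2)
    return F


def exploitation_rate(F: float, Z: float) -> float:
    """E = F / Z, the fraction of total deaths due to fishing."""
    if Z <= 0:
        raise DomainError(f"exploitation_rate requires Z > 0, got {Z}")
    return F / Z


def mortality_diagnostics(k: float, M: float, Z: float) -> MortalityDiagnostics:
    """Compute e^-k, M/K and Z/K with their reliability flags."""
    if min(k, M, Z) <= 0:
        raise DomainError("diagnostics require positive k, M, Z")
    enk = math.exp(-k)
    return MortalityDiagnostics(
        exp_neg_k=enk,
        M_over_K=M / k,
        Z_over_K=Z / k,
        growth_reliable=enk < 1.0,
        M_reliable=1.0 <= M / k <= 2.5,
        fishing_dominated=Z / k > 3.0,
    )


# ---------------------------------------------------------------------------
# length-at-first-capture estimation from catch data
# ---------------------------------------------------------------------------

def estimate_lc(lengths, method: str = "percentile", q: float = 5.0,
                n_bins: int = 40) -> float:
    """Estimate the length at first capture L_c from retained lengths.

    ``"percentile"`` (default): the q-th percentile of retained lengths,
    interpreted knife-edge.  ``"logistic"``: fit a logistic retention curve
    to the ascending limb of the length-frequency histogram (bins up to the
    modal bin, counts scaled by the modal count) and return the estimated
    50%-retention length L50.
    """
    L = np.asarray(lengths, dtype=float)
    if L.size == 0:
        raise DomainError("cannot estimate L_c from an empty catch")
    if method == "percentile":
        return float(np.percentile(L, q))
    if method != "logistic":
        raise ValueError(f"unknown L_c method {method!r}")
    counts, edges = np.histogram(L, bins=n_bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(counts))
    # ascending limb, modal bin included; retention proportion relative to mode
    x = mids[: mode + 1]
    p = counts[: mode + 1] / counts[mode]
    if x.size < 3:
        # histogram too coarse for a curve fit; fall back to the percentile rule
        return float(np.percentile(L, q))

    def f(xx, L50, s):
        return 1.0 / (1.0 + np.exp(-(xx - L50) / s))

    p0 = [float(np.median(x)), max(float(x[-1] - x[0]) / 4.0, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(f, x, p, p0=p0, maxfev=10000)
        return float(popt[0])
    except Exception:
        return float(np.percentile(L, q))


def estimate_mortality(lengths, vbgf, T: float, L_c: float | None = None,
                       pauly_variant: str = "base10_cm",
                       lc_method: str = "percentile") -> MortalityEstimates:
    """Run the full mortality chain for one group's catch lengths.

    L_c defaults to the 5th-percentile rule of :func:`estimate_lc`; L_mean is
    computed over fish with length >= L_c only, as the mean-length estimator
    assumes.  ``vbgf`` supplies L_inf and k.
    """
    L = np.asarray(lengths, dtype=float)
    if L_c is None:
        L_c = estimate_lc(L, method=lc_method)
    retained = L[L >= L_c]
    if retained.size == 0:
        raise DomainError(f"no fish at or above L_c = {L_c}")
    L_mean = float(retained.mean())
    Z = beverton_holt_Z(vbgf.k, vbgf.L_inf, L_mean, L_c)
    M = pauly_M(vbgf.L_inf, vbgf.k, T, variant=pauly_variant)
    F = fishing_mortality(Z, M)
    E = exploitation_rate(F, Z)
    return MortalityEstimates(
        Z=Z, M=M, F=F, E=E,
        inputs=MortalityInputs(L_mean=L_mean, L_c=float(L_c), T=T),
        diagnostics=mortality_diagnostics(vbgf.k, M, Z),
        pauly_variant=pauly_variant,
    )
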