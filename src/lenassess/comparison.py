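"""Cross-group homogeneity tests (ANCOVA as a nested-model F test).

Tests whether a relationship (e.g. length-weight on the log10-log10 scale,
or length/weight against age on the raw scale) shares a common slope across
groups: the full model fits a separate slope and intercept per group, the
reduced model a common slope with group intercepts, and the F statistic
compares their residual sums of squares

    F = [(RSS_reduced - RSS_full) / (g - 1)] / [RSS_full / (n - 2g)]

with g groups and n points.  A small p-value means the slopes differ and
per-group relationships are warranted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .records import as_frame

__all__ = ["AncovaResult", "ancova_slopes"]

TRANSFORMS = ("log10", "identity")


@dataclass(frozen=True)
class AncovaResult:
    """Homogeneity-of-slopes test result."""

    F_stat: float
    df_num: int
    df_den: int
    p_value: float
    per_group_slopes: dict[str, float]
    transform: str
    response: str
    covariate: str


def _design(x: np.ndarray, codes: np.ndarray, n_groups: int, interaction: bool):
    """Group-intercept design, optionally with per-group slopes."""
    n = x.size
    intercepts = np.zeros((n, n_groups))
    intercepts[np.arange(n), codes] = 1.0
    if not interaction:
        return np.column_stack([intercepts, x])
    slopes = np.zeros((n, n_groups))
    slopes[np.arange(n), codes] = x
    return np.column_stack([intercepts, slopes])


def ancova_slopes(records, response: str, covariate: str,
                  transform: str = "log10") -> AncovaResult:
    """Test homogeneity of slopes of ``response`` on ``covariate`` across
    ``group_id``.

    ``transform="log10"`` takes log10 of both variables (the length-weight
    convention; requires positive values); ``"identity"`` uses raw scales
    (the age-relationship convention).  Needs >= 2 groups with >= 3 points
    and >= 2 distinct covariate values each.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    df = as_frame(records) if not isinstance(records, pd.DataFrame) else records
    for col in (response, covariate, "group_id"):
        if col not in df.columns:
            raise ValidationError(f"records lack column {col!r}")

    y = df[response].to_numpy(dtype=float)
    x = df[covariate].to_numpy(dtype=float)
    if transform == "log10":
        if np.any(y <= 0) or np.any(x <= 0):
            raise ValidationError("log10 transform requires positive response and covariate")
        y, x = np.log10(y), np.log10(x)

    groups = df["group_id"].to_numpy()
    labels, codes = np.unique(groups, return_inverse=True)
    g = labels.size
    if g < 2:
        raise InsufficientDataError("ANCOVA needs >= 2 groups")
    for gi, lab in enumerate(labels):
        xi = x[codes == gi]
        if xi.size < 3:
            raise InsufficientDataError(f"group {lab!r} has fewer than 3 points")
        if np.unique(xi).size < 2:
            raise ValidationError(
                f"group {lab!r} has a rank-deficient design (constant covariate)")

    n = y.size
    full = sm.OLS(y, _design(x, codes, g, interaction=True)).fit()
    reduced = sm.OLS(y, _design(x, codes, g, interaction=False)).fit()
    df_num = g - 1
    df_den = n - 2 * g
    rss_full = float(full.ssr)
    rss_red = float(reduced.ssr)
    if df_den <= 0:
        raise InsufficientDataError("not enough points for the residual df")
    if rss_full <= 0:
        F = 0.0 if np.isclose(rss_red, rss_full) else np.inf
    else:
        F = max((rss_red - rss_full) / df_num / (rss_full / df_den), 0.0)
    p = float(stats.f.sf(F, df_num, df_den))
    slopes = {str(lab): float(full.params[g + gi]) for gi, lab in enumerate(labels)}
    return AncovaResult(F_stat=float(F), df_num=df_num, df_den=df_den, p_value=p,
                        per_group_slopes=slopes, transform=transform,
                        response=response, covariate=covariate)
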