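"""Published parameter sets bundled for worked examples and validation.

``yarlung_tributaries`` carries the reported growth and mortality
coefficients for *Schizopygopsis younghusbandi* in four tributaries of the
Yarlung Zangbo River (Duoxiong Zangbo, Lhasa, Niyang and Nianchu).  These
parameter sets circulate as growth-rate equations rather than raw VBGF
parameters, so the asymptotic length is recovered from the leading
coefficient of dL/dt = (L_inf k) exp(-k (t - t0)) as L_inf =
rate_coeff / k; likewise the weight-rate leading coefficient equals
W_inf k b.  Z and M are the reported total and natural mortality rates.
"""

from __future__ import annotations

import pandas as pd

from .growth import VBGFParams

__all__ = ["YARLUNG_TRIBUTARIES", "yarlung_tributaries", "tributary_vbgf"]

#: reported coefficients per tributary:
#: dL/dt leading coefficient (mm/yr), k (1/yr), t0 (yr), allometry exponent b,
#: dW/dt leading coefficient (g/yr), Z (1/yr), M (1/yr)
YARLUNG_TRIBUTARIES: dict[str, dict[str, float]] = {
    "Duoxiong Zangbo": dict(rate_coeff=63.838, k=0.154, t0=-0.556, b=2.9689,
                            weight_rate_coeff=540.037, Z=0.453, M=0.311),
    "Nianchu River": dict(rate_coeff=64.900, k=0.162, t0=-0.407, b=2.9697,
                          weight_rate_coeff=515.932, Z=0.693, M=0.331),
    "Lhasa River": dict(rate_coeff=67.491, k=0.174, t0=-0.695, b=2.9881,
                        weight_rate_coeff=565.268, Z=1.066, M=0.364),
    "Niyang River": dict(rate_coeff=67.763, k=0.172, t0=-0.668, b=3.0694,
                         weight_rate_coeff=488.768, Z=1.67, M=0.373),
}


def yarlung_tributaries() -> pd.DataFrame:
    """The bundled coefficients as a DataFrame indexed by tributary, with the
    derived asymptotic sizes added (L_inf_mm = rate_coeff / k and
    W_inf_g = weight_rate_coeff / (k b))."""
    df = pd.DataFrame.from_dict(YARLUNG_TRIBUTARIES, orient="index")
    df.index.name = "group_id"
    df["L_inf_mm"] = df["rate_coeff"] / df["k"]
    df["W_inf_g"] = df["weight_rate_coeff"] / (df["k"] * df["b"])
    return df


def tributary_vbgf(name: str) -> VBGFParams:
    """VBGF parameters for one tributary, L_inf recovered from the reported
    growth-rate coefficient."""
    p = YARLUNG_TRIBUTARIES[name]
    return VBGFParams(L_inf=p["rate_coeff"] / p["k"], k=p["k"], t0=p["t0"])
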