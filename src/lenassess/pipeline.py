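"""Configuration handling and full-assessment orchestration.

``run_full_assessment`` chains the stages in the order the analysis runs:
length-weight fit -> VBGF fit -> derived growth quantities -> cross-group
slope tests -> mortality/exploitation -> per-recruit analysis -> minimum
catchable length, and writes a report bundle (CSV tables + JSON summaries +
a machine-readable manifest) to the output directory.

A group can bypass fitting by *injecting* fitted parameters in its config
(key ``inject``): the downstream stages then run from those values, which is
how published parameter sets are pushed through the pipeline without the raw
records.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .comparison import AncovaResult, ancova_slopes
from .errors import InsufficientDataError, StageError, ValidationError
from .growth import (GrowthSummary, LengthWeightParams, VBGFParams,
                     WeightGrowthParams, derive_weight_growth, fit_length_weight,
                     fit_vbgf_length, growth_summary, length_at_age)
from .mortality import (PAULY_VARIANTS, MortalityEstimates, estimate_lc,
                        estimate_mortality, exploitation_rate, fishing_mortality,
                        mortality_diagnostics, MortalityInputs)
from .records import read_records
from .ypr import (YPRConfig, YPRResult, analyze_ypr, optimal_lc_at_ratio,
                  recommend_min_catch_length)

log = logging.getLogger("lenassess")

_GROUP_KEYS = {"temperature_celsius", "lc_mm", "pauly_variant", "inject"}
_INJECT_KEYS = {"L_inf", "k", "t0", "b", "a", "M", "Z"}
_TOP_KEYS = {"input", "output_dir", "seed", "pauly_variant", "e_step",
             "lc_ratio_bounds", "lc_steps", "lc_star_ratio", "groups", "verbosity"}


@dataclass
class GroupConfig:
    """Per-group configuration: environment inputs plus optional injected
    parameters that bypass fitting."""

    temperature_celsius: float | None = None
    lc_mm: float | None = None
    pauly_variant: str | None = None
    inject: dict | None = None

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "GroupConfig":
        unknown = set(d) - _GROUP_KEYS
        if unknown:
            raise ValidationError(f"group {name!r}: unknown config keys {sorted(unknown)}")
        inject = d.get("inject")
        if inject is not None:
            bad = set(inject) - _INJECT_KEYS
            if bad:
                raise ValidationError(f"group {name!r}: unknown inject keys {sorted(bad)}")
        return cls(temperature_celsius=d.get("temperature_celsius"),
                   lc_mm=d.get("lc_mm"),
                   pauly_variant=d.get("pauly_variant"),
                   inject=inject)


@dataclass
class RunConfig:
    """Whole-run configuration (parsed from YAML or built in code)."""

    groups: dict[str, GroupConfig]
    input: str | None = None
    output_dir: str = "lenassess_out"
    seed: int = 0
    pauly_variant: str = "base10_cm"
    e_step: float = 0.001
    lc_ratio_bounds: tuple[float, float] = (0.1, 0.6)
    lc_steps: int = 51
    lc_star_ratio: float = 0.6
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        if "groups" not in d or not d["groups"]:
            raise ValidationError("config must define at least one group")
        groups = {name: GroupConfig.from_dict(name, gd or {})
                  for name, gd in d["groups"].items()}
        kwargs = {k: v for k, v in d.items() if k != "groups"}
        if "lc_ratio_bounds" in kwargs:
            kwargs["lc_ratio_bounds"] = tuple(kwargs["lc_ratio_bounds"])
        cfg = cls(groups=groups, **kwargs)
        if cfg.pauly_variant not in PAULY_VARIANTS:
            raise ValidationError(f"pauly_variant must be one of {PAULY_VARIANTS}")
        if cfg.input is not None and not Path(cfg.input).exists():
            raise ValidationError(f"input path does not exist: {cfg.input}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lc_ratio_bounds"] = list(self.lc_ratio_bounds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class GroupAssessment:
    """Everything computed for one group; fields stay None when a stage had
    no inputs to run on (e.g. no records and no injected value)."""

    group_id: str
    lw: LengthWeightParams | None = None
    vbgf: VBGFParams | None = None
    wg: WeightGrowthParams | None = None
    b: float | None = None
    summary: GrowthSummary | None = None
    mortality: MortalityEstimates | None = None
    ypr: YPRResult | None = None
    lc_star: float | None = None
    recommended_length: float | None = None
    injected: bool = False


@dataclass
class AssessmentReport:
    """Report bundle: per-group assessments plus cross-group tests."""

    groups: dict[str, GroupAssessment]
    ancova: dict[str, AncovaResult]
    manifest: dict


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _stage(name):
    """Decorator-ish context: re-raise any stage failure as StageError."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False
    return _Ctx()


def _injected_params(name: str, inject: dict):
    vbgf = VBGFParams(L_inf=float(inject["L_inf"]), k=float(inject["k"]),
                      t0=float(inject["t0"]))
    b = float(inject["b"])
    return vbgf, b


def assess_group(name: str, gcfg: GroupConfig, records: pd.DataFrame | None,
                 run: RunConfig) -> GroupAssessment:
    """Run every computable stage for one group."""
    res = GroupAssessment(group_id=name)
    has_records = records is not None and len(records) > 0
    inject = gcfg.inject

    if not has_records and not inject:
        raise StageError("growth", f"group {name!r} has no records and no "
                                   "injected parameters (insufficient data)")

    with _stage("growth"):
        if inject:
            res.injected = True
            res.vbgf, res.b = _injected_params(name, inject)
            if "a" in inject:
                res.lw = LengthWeightParams(a=float(inject["a"]), b=res.b,
                                            n=0, r_squared=float("nan"),
                                            se_b=float("nan"))
        else:
            res.lw = fit_length_weight(records)
            res.vbgf = fit_vbgf_length(records)
            res.b = res.lw.b
        if res.lw is not None:
            res.wg = derive_weight_growth(res.vbgf, res.lw)

    with _stage("mortality"):
        variant = gcfg.pauly_variant or run.pauly_variant
        if inject and "M" in inject:
            M = float(inject["M"])
            if "Z" in inject:
                Z = float(inject["Z"])
                F = fishing_mortality(Z, M)
                E = exploitation_rate(F, Z)
                res.mortality = MortalityEstimates(
                    Z=Z, M=M, F=F, E=E,
                    inputs=MortalityInputs(L_mean=float("nan"),
                                           L_c=gcfg.lc_mm or float("nan"),
                                           T=gcfg.temperature_celsius or float("nan")),
                    diagnostics=mortality_diagnostics(res.vbgf.k, M, Z),
                    pauly_variant="injected",
                )
        elif has_records:
            if gcfg.temperature_celsius is None:
                raise ValidationError(f"group {name!r}: temperature_celsius is "
                                      "required to estimate natural mortality")
            res.mortality = estimate_mortality(
                records["length_mm"].to_numpy(), res.vbgf,
                T=gcfg.temperature_celsius, L_c=gcfg.lc_mm,
                pauly_variant=variant)

    with _stage("growth-summary"):
        M_for_tc = res.mortality.M if res.mortality else None
        if M_for_tc is not None:
            res.summary = growth_summary(res.vbgf, res.b, M_for_tc)

    with _stage("ypr"):
        res.lc_star = optimal_lc_at_ratio(res.vbgf.L_inf, run.lc_star_ratio)
        if res.mortality is not None:
            lc_now = gcfg.lc_mm
            if lc_now is None and has_records:
                lc_now = res.mortality.inputs.L_c
            if lc_now is not None and np.isfinite(lc_now):
                cfg = YPRConfig(M=res.mortality.M, k=res.vbgf.k, L_c=float(lc_now),
                                L_inf=res.vbgf.L_inf, e_step=run.e_step,
                                lc_ratio_bounds=run.lc_ratio_bounds,
                                lc_steps=run.lc_steps)
                res.ypr = analyze_ypr(cfg)
            if res.summary is not None:
                res.recommended_length = recommend_min_catch_length(
                    res.vbgf, res.summary, res.lc_star)

    return res


def _growth_equation_coefficients(res: GroupAssessment) -> dict:
    """Coefficient sets of the four derivative equations (rate/acceleration
    for length and weight), the machine form of a growth-equation table."""
    vb = res.vbgf
    out = {
        "length_rate": {"coeff": vb.L_inf * vb.k, "k": vb.k, "t0": vb.t0},
        "length_accel": {"coeff": -vb.L_inf * vb.k ** 2, "k": vb.k, "t0": vb.t0},
    }
    if res.wg is not None:
        wg = res.wg
        out["weight_rate"] = {"coeff": wg.b * wg.W_inf * wg.k, "k": wg.k,
                              "t0": wg.t0, "exponent": wg.b - 1.0}
        out["weight_accel"] = {"coeff": wg.b * wg.W_inf * wg.k ** 2, "k": wg.k,
                               "t0": wg.t0, "exponent": wg.b - 2.0, "b": wg.b}
    return out


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.12g")


def write_report(report: AssessmentReport, out_dir) -> None:
    """Write the report bundle (full-precision machine files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = report.groups

    rows = [{"group_id": g, "a": r.lw.a, "b": r.lw.b, "n": r.lw.n,
             "r_squared": r.lw.r_squared, "se_b": r.lw.se_b}
            for g, r in groups.items() if r.lw is not None]
    if rows:
        _write_csv(pd.DataFrame(rows), out / "length_weight.csv")

    rows = [{"group_id": g, "L_inf_mm": r.vbgf.L_inf, "k": r.vbgf.k,
             "t0": r.vbgf.t0, "n": r.vbgf.n, "rss": r.vbgf.rss}
            for g, r in groups.items() if r.vbgf is not None]
    _write_csv(pd.DataFrame(rows), out / "vbgf.csv")

    eqs = {g: _growth_equation_coefficients(r) for g, r in groups.items()
           if r.vbgf is not None}
    (out / "growth_equations.json").write_text(json.dumps(eqs, indent=2))

    rows = [{"group_id": g, "t_i_yr": r.summary.t_i, "t_c_yr": r.summary.t_c,
             "phi": r.summary.phi}
            for g, r in groups.items() if r.summary is not None]
    if rows:
        _write_csv(pd.DataFrame(rows), out / "growth_summary.csv")

    rows = []
    for g, r in groups.items():
        if r.mortality is None:
            continue
        m, d = r.mortality, r.mortality.diagnostics
        rows.append({"group_id": g, "Z": m.Z, "M": m.M, "F": m.F, "E": m.E,
                     "L_mean_mm": m.inputs.L_mean, "L_c_mm": m.inputs.L_c,
                     "T_celsius": m.inputs.T, "pauly_variant": m.pauly_variant,
                     "exp_neg_k": d.exp_neg_k, "M_over_K": d.M_over_K,
                     "Z_over_K": d.Z_over_K, "growth_reliable": d.growth_reliable,
                     "M_reliable": d.M_reliable,
                     "fishing_dominated": d.fishing_dominated})
    if rows:
        _write_csv(pd.DataFrame(rows), out / "mortality.csv")

    refs = {g: asdict(r.ypr.reference_points) for g, r in groups.items()
            if r.ypr is not None}
    if refs:
        (out / "ypr_reference_points.json").write_text(json.dumps(refs, indent=2))
    curves = [r.ypr.curve.assign(group_id=g) for g, r in groups.items()
              if r.ypr is not None]
    if curves:
        _write_csv(pd.concat(curves, ignore_index=True), out / "ypr_curves.csv")
    iso = [r.ypr.isopleth.to_frame().assign(group_id=g)
           for g, r in groups.items() if r.ypr is not None]
    if iso:
        _write_csv(pd.concat(iso, ignore_index=True), out / "isopleth.csv")

    rows = []
    for g, r in groups.items():
        if r.recommended_length is None:
            continue
        rows.append({"group_id": g, "lc_star_mm": r.lc_star,
                     "length_at_ti_mm": float(length_at_age(r.vbgf, r.summary.t_i)),
                     "length_at_tc_mm": float(length_at_age(r.vbgf, r.summary.t_c)),
                     "recommended_min_catch_length_mm": r.recommended_length})
    if rows:
        _write_csv(pd.DataFrame(rows), out / "recommendation.csv")

    if report.ancova:
        rows = [{"relationship": rel, "F": a.F_stat, "df_num": a.df_num,
                 "df_den": a.df_den, "p_value": a.p_value,
                 "transform": a.transform,
                 **{f"slope_{g}": s for g, s in a.per_group_slopes.items()}}
                for rel, a in report.ancova.items()]
        _write_csv(pd.DataFrame(rows), out / "group_comparison.csv")

    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))


# ---------------------------------------------------------------------------
# top-level entry point
# ---------------------------------------------------------------------------

_ANCOVA_SPECS = {
    "length_weight": ("weight_g", "length_mm", "log10"),
    "length_age": ("length_mm", "age", "identity"),
    "weight_age": ("weight_g", "age", "identity"),
}


def run_full_assessment(config: RunConfig, write: bool = True) -> AssessmentReport:
    """Run every stage for every configured group and (optionally) write the
    report bundle to ``config.output_dir``."""
    logging.basicConfig(level=logging.WARNING if config.verbosity < 2 else logging.INFO)
    records = None
    if config.input is not None:
        with _stage("read-records"):
            # groups in the file but not in the config are simply ignored,
            # so a run can be restricted to a subset of groups
            records = read_records(config.input)
            records = records[records["group_id"].isin(config.groups)]

    groups: dict[str, GroupAssessment] = {}
    for name, gcfg in config.groups.items():
        sub = None
        if records is not None:
            sub = records[records["group_id"] == name]
        log.info("assessing group %s", name)
        groups[name] = assess_group(name, gcfg, sub, config)

    ancova: dict[str, AncovaResult] = {}
    if records is not None and records["group_id"].nunique() >= 2:
        with _stage("group-comparison"):
            for rel, (resp, cov, transform) in _ANCOVA_SPECS.items():
                # age-based comparisons need >= 2 distinct ages per group
                try:
                    ancova[rel] = ancova_slopes(records, resp, cov, transform)
                except (InsufficientDataError, ValidationError) as err:
                    log.warning("skipping ANCOVA %s: %s", rel, err)

    manifest = {
        "package": "lenassess",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }
    report = AssessmentReport(groups=groups, ancova=ancova, manifest=manifest)
    if write:
        with _stage("write-report"):
            write_report(report, config.output_dir)
    return report
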