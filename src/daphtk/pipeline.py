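"""Pipeline orchestration: exposure QC → dose–response → toxicokinetics →
classification → risk, driven by a single validated config.

Every stage's outputs are pure functions of the inputs and config (the one
random element, the bootstrap, is seeded from the config), so two runs with
the same config produce identical report bodies.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import chem, classification, dose_response, exposure_qc, risk, toxicokinetics

REPORT_SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class RunOptions(BaseModel):
    f_lipid: float = toxicokinetics.DEFAULT_F_LIPID
    af: float = risk.DEFAULT_AF
    n_boot: int = 200
    seed: int = 1
    ecx_levels: list[float] = Field(default_factory=lambda: [10.0, 20.0, 50.0])
    #: per-chemical depuration time points (h) to exclude from the k2 fit
    exclusions: dict[str, list[float]] = Field(default_factory=dict)
    #: which species line supplies the B/vB k2 thresholds
    threshold_source: str = "daphnia"
    #: water concentration (µg/L) per chemical for the BAF calculation
    cw_ug_per_l: dict[str, float] = Field(default_factory=dict)
    #: measured environmental concentration (µg/L) per chemical, for RQs
    mec_ug_per_l: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    schema_version: str = REPORT_SCHEMA_VERSION
    chemicals_csv: str
    exposure_csv: Optional[str] = None
    reproduction_csv: Optional[str] = None
    body_burden_csv: Optional[str] = None
    species_csv: Optional[str] = None
    options: RunOptions = Field(default_factory=RunOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls.model_validate(raw)
        base = Path(path).parent
        # resolve relative input paths against the config file location
        for name in (
            "chemicals_csv", "exposure_csv", "reproduction_csv",
            "body_burden_csv", "species_csv",
        ):
            val = getattr(cfg, name)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, name, str(base / val))
        return cfg


def _require(path: Optional[str], stage: str) -> str:
    if path is None:
        raise PipelineError(stage, "no input file configured")
    if not Path(path).exists():
        raise PipelineError(stage, f"input file not found: {path}")
    return path


def _stage_exposure(cfg: RunConfig) -> Optional[dict]:
    if cfg.exposure_csv is None:
        return None
    try:
        df = exposure_qc.read_exposure_csv(_require(cfg.exposure_csv, "exposure_qc"))
        summaries = exposure_qc.summarize_exposure(df)
        stability = [
            exposure_qc.stability_test(df, level_id=s.level_id,
                                       chemical_id=s.chemical_id)
            for s in summaries
            if not s.flagged
        ]
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError("exposure_qc", str(exc)) from exc
    return {
        "summaries": [asdict(s) for s in summaries],
        "stability": [asdict(s) for s in stability],
    }


def _stage_dose_response(cfg: RunConfig, registry: dict) -> Optional[dict]:
    if cfg.reproduction_csv is None:
        return None
    opts = cfg.options
    out: dict = {}
    try:
        df = dose_response.read_reproduction_csv(
            _require(cfg.reproduction_csv, "dose_response")
        )
        for chem_id, grp in df.groupby("chemical_id"):
            validity = dose_response.validity_check(grp)
            inh = dose_response.percent_inhibition(grp)
            fit = dose_response.fit_4pl(inh, ecx_levels=opts.ecx_levels)
            entry: dict = {
                "validity": asdict(validity),
                "converged": fit.converged,
                "params": list(fit.params),
                "r2": fit.r2,
                "ecx": {},
            }
            if fit.converged:
                for level in opts.ecx_levels:
                    est = dose_response.ecx_ci(
                        fit, grp, level, n_boot=opts.n_boot, seed=opts.seed
                    )
                    entry["ecx"][str(level)] = asdict(est)
                ec10 = fit.ecx[10.0].estimate if 10.0 in fit.ecx else None
                chem_obj = registry.get(str(chem_id))
                if ec10 and chem_obj:
                    ec10_mmol = ec10 / chem_obj.mw / 1000.0
                    entry["ctlbb_umol_per_g"] = dose_response.ctlbb(
                        ec10_mmol, chem_obj.log_kow
                    )
                    s_l = chem.subcooled_solubility(chem_obj.sw, chem_obj.tm)
                    ec50 = fit.ecx.get(50.0)
                    if ec50 and ec50.estimate > 0 and s_l > 0:
                        act = chem.effective_activity(
                            chem.to_molar(ec50.estimate, chem_obj.mw),
                            s_l, endpoint="chronic", chemical_id=str(chem_id),
                        )
                        entry["ea50"] = {"ea": act.ea, "band": act.band}
            out[str(chem_id)] = entry
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dose_response", str(exc)) from exc
    return out


def _stage_toxicokinetics(cfg: RunConfig) -> Optional[dict]:
    if cfg.body_burden_csv is None:
        return None
    opts = cfg.options
    out: dict = {}
    try:
        df = toxicokinetics.read_body_burden_csv(
            _require(cfg.body_burden_csv, "toxicokinetics")
        )
        for chem_id, grp in df.groupby("chemical_id"):
            excl = opts.exclusions.get(str(chem_id), [])
            fit = toxicokinetics.complete_tk_fit(grp, exclusions=excl)
            plateau = toxicokinetics.detect_plateau(grp)
            entry = {
                "k2": fit.k2, "k2_se": fit.k2_se, "kg": fit.kg,
                "k2g": fit.k2g, "t50": fit.t50, "t95": fit.t95,
                "k_for_ss": fit.k_for_ss, "r2": fit.r2,
                "n_points": fit.n_points, "valid": fit.valid,
                "flags": fit.flags,
                "excluded_points": fit.excluded_points,
                "plateau_suggestions": plateau,
            }
            cw = opts.cw_ug_per_l.get(str(chem_id))
            if cw:
                up = grp[grp["phase"] == "uptake"]
                t_end = up["time_h"].max()
                cd_end = float(
                    up.loc[up["time_h"] == t_end, "cd_ug_per_kg"].mean()
                )
                b = toxicokinetics.baf(cd_end, cw, f_lipid=opts.f_lipid)
                entry["baf"] = asdict(b)
            out[str(chem_id)] = entry
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("toxicokinetics", str(exc)) from exc
    return out


def _stage_classification(cfg: RunConfig, tk_report: Optional[dict]) -> dict:
    opts = cfg.options
    try:
        source = opts.threshold_source
        if cfg.species_csv is not None:
            df = classification.read_species_csv(
                _require(cfg.species_csv, "classification")
            )
            sub = df[df["species_group"] == source]
            line = classification.fit_loglinear(sub, "log_k2", "log_bcf_l5")
        elif source == "daphnia":
            line = classification.DAPHNIA_BCF_K2_LINE
        elif source == "hyalella":
            line = classification.HYALELLA_BCF_K2_LINE
        elif source == "fish":
            line = None  # UK-EA literature thresholds are the fish default
        else:
            raise PipelineError("classification", f"unknown source {source!r}")
        if line is not None:
            thresholds = classification.derive_thresholds(line, source)
            line_info = asdict(line)
        else:
            thresholds = classification.FISH_THRESHOLDS
            line_info = None
        result = {
            "threshold_source": source,
            "regression": line_info,
            "thresholds": asdict(thresholds),
            "classifications": {},
        }
        if tk_report:
            for chem_id, entry in tk_report.items():
                k2 = entry.get("k2g") or entry.get("k2")
                if k2 and k2 > 0:
                    result["classifications"][chem_id] = classification.classify_k2(
                        k2, thresholds
                    )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classification", str(exc)) from exc
    return result


def _stage_risk(cfg: RunConfig, dr_report: Optional[dict], registry: dict) -> dict:
    opts = cfg.options
    out: dict = {}
    try:
        if dr_report:
            for chem_id, entry in dr_report.items():
                ec10 = entry.get("ecx", {}).get("10.0", {}).get("estimate")
                if not ec10 or not ec10 > 0:
                    continue
                chem_obj = registry.get(chem_id)
                assessment = risk.assess(
                    chem_id, ec10, af=opts.af,
                    mec_ug_per_l=opts.mec_ug_per_l.get(chem_id),
                    mw=chem_obj.mw if chem_obj else None,
                )
                out[chem_id] = asdict(assessment)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("risk", str(exc)) from exc
    return out


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages in order and return the report dict."""
    try:
        registry = chem.load_chemicals(_require(config.chemicals_csv, "chemicals"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("chemicals", str(exc)) from exc
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.options.seed,
        "chemicals": sorted(registry),
    }
    report["exposure_qc"] = _stage_exposure(config)
    report["dose_response"] = _stage_dose_response(config, registry)
    report["toxicokinetics"] = _stage_toxicokinetics(config)
    report["classification"] = _stage_classification(
        config, report["toxicokinetics"]
    )
    report["risk"] = _stage_risk(config, report["dose_response"], registry)
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=str)


def report_to_markdown(report: dict) -> str:
    """Compact human-readable summary of a pipeline report."""
    lines = ["# daphtk pipeline report", ""]
    lines.append(f"Chemicals: {', '.join(report.get('chemicals', []))}")
    dr = report.get("dose_response") or {}
    if dr:
        lines += ["", "## Dose–response", ""]
        for cid, entry in sorted(dr.items()):
            v = entry["validity"]
            lines.append(
                f"- **{cid}**: valid={v['valid']}, "
                f"control mean {v['control_mean_offspring']:.1f}"
            )
            for level, est in sorted(entry.get("ecx", {}).items()):
                ci = ""
                if est.get("ci_low") is not None:
                    ci = f" [{est['ci_low']:.3g}, {est['ci_high']:.3g}]"
                lines.append(f"  - EC{float(level):g} = {est['estimate']:.3g} µg/L{ci}")
    tk = report.get("toxicokinetics") or {}
    if tk:
        lines += ["", "## Toxicokinetics", ""]
        for cid, e in sorted(tk.items()):
            lines.append(
                f"- **{cid}**: k2={e['k2']:.4g} /h, kg={e['kg']:.4g} /h, "
                f"k2g={e['k2g']:.4g} /h, t50={e['t50']:.3g} h, t95={e['t95']:.3g} h"
                if e.get("k2g") is not None
                else f"- **{cid}**: k2={e['k2']:.4g} /h (invalid fit)"
            )
            if "baf" in e:
                lines.append(f"  - log BAF*_L5% = {e['baf']['log_baf_l5']:.2f}")
    cls = report.get("classification") or {}
    if cls:
        th = cls["thresholds"]
        lines += [
            "", "## Classification", "",
            f"- thresholds ({cls['threshold_source']}): "
            f"k2(B)={th['k2_b']:.3g} /h, k2(vB)={th['k2_vb']:.3g} /h",
        ]
        for cid, label in sorted(cls.get("classifications", {}).items()):
            lines.append(f"- **{cid}**: {label}")
    rk = report.get("risk") or {}
    if rk:
        lines += ["", "## Risk screening", ""]
        for cid, e in sorted(rk.items()):
            rq = f", RQ={e['rq']:.3g}" if e.get("rq") is not None else ""
            lines.append(
                f"- **{cid}**: PNEC={e['pnec_ug_per_l']:.3g} µg/L, "
                f"REACH toxic={e['reach_toxic']}{rq}"
            )
    return "\n".join(lines) + "\n"
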