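"""Result assembly and report writing.

:func:`evaluate_calibration` turns a calibration into the headline numbers
(per-group and combined net benefits, cohort total, ROI); :func:`write_report`
writes a machine-readable ``results.json`` (full resolved configuration
echoed, monetary values rounded to whole cents, deterministic byte-for-byte
under identical config and seed) and a human-readable ``summary.txt``, plus
optional CSV matrices and plots for surfaces and PSA draws.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .calibration import CalibrationResult
from .config import RunConfig
from .errors import StewardCostError
from .model import (
    cohort_net_benefit,
    per_patient_net_benefit,
    roi,
)
from .sensitivity import PSAResult, SensitivityGrid

__all__ = ["evaluate_calibration", "write_report"]


def _eur(x: float) -> float:
    return round(float(x), 2)


def evaluate_calibration(result: CalibrationResult,
                         n_audit: float | None = None,
                         implementation_cost: float | None = None) -> dict:
    """Headline economics of a calibrated model.

    Per group: the per-patient and cohort net benefit of that group's
    parameters.  Combined: both groups' share-weighted savings minus the
    audit cost at ``n_audit`` audits per patient (default cohort-wide mean),
    scaled to the audited cohort, with ROI = total benefit / total audit
    cost (and, if given, / implementation cost).
    """
    if not result.parameters:
        raise StewardCostError("calibration produced no group parameters")
    per_group = {}
    for group, params in result.parameters.items():
        per_group[str(group)] = {
            "per_patient_net_benefit_eur": _eur(per_patient_net_benefit(params)),
            "cohort_net_benefit_eur": _eur(cohort_net_benefit(params)),
            "parameters": {k: (round(v, 6) if isinstance(v, float) else v)
                           for k, v in params.__dict__.items()},
        }
    n_aud = result.n_audit_overall if n_audit is None else n_audit
    some = next(iter(result.parameters.values()))
    per_patient = result.combined_per_patient_net_benefit(n_aud)
    total = per_patient * result.n_intervention
    audit_total = some.c_audit * n_aud * result.n_intervention
    out = {
        "per_group": per_group,
        "combined": {
            "n_patients": result.n_intervention,
            "n_audit_per_patient": round(n_aud, 6),
            "per_patient_net_benefit_eur": _eur(per_patient),
            "cohort_net_benefit_eur": _eur(total),
            "total_audit_cost_eur": _eur(audit_total),
            "roi_vs_audit_cost": round(roi(total, audit_total), 4)
            if audit_total > 0 else None,
        },
    }
    if implementation_cost is not None and implementation_cost > 0:
        out["combined"]["roi_vs_implementation_cost"] = round(
            roi(total, implementation_cost), 4)
    return out


def _calibration_block(result: CalibrationResult) -> dict:
    summaries = {}
    for group, arms in result.summaries.items():
        summaries[str(group)] = {
            arm: {
                outcome: {
                    "n": s.n,
                    "mean": round(s.mean, 4),
                    "ci95_halfwidth": round(s.ci95_halfwidth, 4),
                    "is_proportion": s.is_proportion,
                    "n_missing": s.n_missing,
                } for outcome, s in outcomes.items()
            } for arm, outcomes in arms.items()
        }
    effects = {}
    for group, outcome_effects in result.effects.items():
        effects[str(group)] = {
            outcome: {
                "delta": round(e.delta, 4),
                "test": e.test_name,
                "p_value": round(e.p_value, 6),
                "included": e.included,
            } for outcome, e in outcome_effects.items()
        }
    return {
        "n_intervention": result.n_intervention,
        "n_control": result.n_control,
        "alpha": result.alpha,
        "test_map": dict(sorted(result.test_map.items())),
        "summaries": summaries,
        "effects": effects,
    }


def _psa_block(psa: PSAResult) -> dict:
    s = psa.summary
    return {
        "n_draws": int(psa.draws.size),
        "seed": psa.seed,
        "median_eur": _eur(s.median),
        "mean_eur": _eur(s.mean),
        "p2_5_eur": _eur(s.p2_5),
        "p97_5_eur": _eur(s.p97_5),
        "min_eur": _eur(s.minimum),
        "max_eur": _eur(s.maximum),
        "prob_net_benefit_positive": round(s.prob_positive, 4),
        "baseline": {k: (round(v, 6) if isinstance(v, float) else v)
                     for k, v in psa.baseline.__dict__.items()},
    }


def write_report(out_dir: str | Path,
                 config: RunConfig,
                 calibration: CalibrationResult,
                 psa: PSAResult | None = None,
                 surfaces: Sequence[SensitivityGrid] = (),
                 make_plots: bool = False) -> dict:
    """Write ``results.json`` + ``summary.txt`` (+ CSVs and optional plots).

    Returns the results dictionary that was serialised.  Identical
    configuration and seeds produce byte-identical ``results.json``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise StewardCostError(f"cannot create output directory {out}: {err}")

    results = {
        "config": config.to_dict(),
        "calibration": _calibration_block(calibration),
        "economics": evaluate_calibration(
            calibration, n_audit=config.n_audit,
            implementation_cost=config.implementation_cost),
    }
    if psa is not None:
        results["psa"] = _psa_block(psa)
        draws_path = out / "psa_draws.csv"
        with draws_path.open("w", encoding="utf-8") as fh:
            fh.write("net_benefit_eur\n")
            fh.writelines(f"{d:.6f}\n" for d in psa.draws)
    for k, grid in enumerate(surfaces):
        grid.to_dataframe().to_csv(out / f"surface_{k}.csv",
                                   float_format="%.6f")
    results["surfaces"] = [
        {"axis1": grid.axis1.parameter_name, "axis2": grid.axis2.parameter_name,
         "shape": list(grid.values.shape), "file": f"surface_{k}.csv"}
        for k, grid in enumerate(surfaces)
    ]

    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (out / "summary.txt").write_text(_summary_text(results), encoding="utf-8")

    if make_plots:
        from . import plots

        if surfaces:
            for k, grid in enumerate(surfaces):
                plots.plot_surface(grid, out / f"surface_{k}.png")
        if psa is not None:
            plots.plot_psa(psa, out / "psa_histogram.png")
    return results


def _summary_text(results: dict) -> str:
    lines = ["Day-2 case-audit cost-minimization model — run summary",
             "=" * 56, ""]
    cal = results["calibration"]
    lines.append(f"Cohorts: {cal['n_intervention']} audited patients, "
                 f"{cal['n_control']} historic controls "
                 f"(alpha = {cal['alpha']})")
    for group, effs in sorted(cal["effects"].items()):
        lines.append(f"  DRG group {group}:")
        for outcome, e in effs.items():
            gate = "included" if e["included"] else "gated out"
            lines.append(f"    {outcome:12s} delta={e['delta']:>10.4f}  "
                         f"p={e['p_value']:.4f} ({e['test']}) -> {gate}")
    eco = results["economics"]["combined"]
    lines += [
        "",
        f"Net benefit per audited patient: EUR {eco['per_patient_net_benefit_eur']:.2f}",
        f"Cohort net benefit ({eco['n_patients']} patients): "
        f"EUR {eco['cohort_net_benefit_eur']:.2f}",
        f"Total audit cost: EUR {eco['total_audit_cost_eur']:.2f} "
        f"({eco['n_audit_per_patient']:.4f} audits/patient)",
    ]
    if eco.get("roi_vs_audit_cost") is not None:
        lines.append(f"ROI vs audit cost: {eco['roi_vs_audit_cost']:.2f}")
    if "roi_vs_implementation_cost" in eco:
        lines.append("ROI vs implementation cost: "
                     f"{eco['roi_vs_implementation_cost']:.2f}")
    if "psa" in results:
        p = results["psa"]
        lines += [
            "",
            f"PSA ({p['n_draws']} draws, seed {p['seed']}): "
            f"median EUR {p['median_eur']:.2f}, "
            f"95% interval [EUR {p['p2_5_eur']:.2f}, EUR {p['p97_5_eur']:.2f}], "
            f"range [EUR {p['min_eur']:.2f}, EUR {p['max_eur']:.2f}], "
            f"P(>0) = {p['prob_net_benefit_positive']:.3f}",
        ]
    return "\n".join(lines) + "\n"
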