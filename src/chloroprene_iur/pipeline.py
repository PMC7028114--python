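"""End-to-end pipeline: bioassay records to unit risk and reality check.

``run_full_pipeline`` chains every stage — model fit under both
unknown-context policies, profile BMDL, internal-dose to human-equivalent
conversion, IUR computation, the tumor-site independence screen, and the
occupational excess-cancer reality check — and emits a machine-readable
report plus a provenance log recording every constant, seed and tolerance
each stage consumed.  Where published summary arithmetic is internally
inconsistent (the lifetime mean-concentration column), the report carries
both the printed-input and recomputed-input variants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import conversion, epi, independence, msw, unit_risk
from .bioassay import (
    ConstantsTable,
    ntp_female_mouse_tumor_pairs,
    read_animal_records,
    write_animal_records,
)
from .simulate import default_ntp_design, simulate_bioassay

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration; the defaults reproduce the headline
    analysis (2-stage model, BMR 1%, one-sided 95% BMDL, no ADAF)."""

    records_csv: str | None = None  # simulate when absent
    k: int = 2
    c_bounds: tuple[float, float] = msw.DEFAULT_C_BOUNDS
    t_star: float = 104.0
    conf_level: float = 0.95
    bmr: float = 0.01
    n_starts: int = 20
    seed: int = 0
    apply_adaf: bool = False
    # reality-check inputs: occupational cumulative exposures (ppm-years)
    # and cohort size
    median_ppm_years: float = 18.35
    mean_ppm_years: float = 80.35
    printed_mean_conc_ugm3: float | None = 1423.0
    n_exposed: int = 5468
    scenario: conversion.ExposureScenario = field(
        default_factory=conversion.ExposureScenario
    )
    constants: ConstantsTable = field(default_factory=ConstantsTable)
    output_dir: str | None = None


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; nested scenario/constants keys override defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = conversion.ExposureScenario(**raw.pop("scenario", {}))
    constants_raw = raw.pop("constants", {})
    if "internal_dose_map" in constants_raw:
        constants_raw["internal_dose_map"] = tuple(
            tuple(pair) for pair in constants_raw["internal_dose_map"]
        )
    constants = ConstantsTable(**constants_raw)
    if "c_bounds" in raw:
        raw["c_bounds"] = tuple(raw["c_bounds"])
    return PipelineConfig(scenario=scenario, constants=constants, **raw)


class _Provenance:
    def __init__(self) -> None:
        self.entries: list[dict[str, Any]] = []

    def log(self, stage: str, inputs: dict[str, Any], outputs: dict[str, Any]) -> None:
        self.entries.append({"stage": stage, "inputs": inputs, "outputs": outputs})


def _fit_branch(
    records, config: PipelineConfig, policy: msw.UnknownPolicy, prov: _Provenance
) -> dict[str, Any]:
    try:
        fit_result = msw.fit(
            records,
            k=config.k,
            unknown_policy=policy,
            n_starts=config.n_starts,
            seed=config.seed,
            c_bounds=config.c_bounds,
        )
    except Exception as exc:  # noqa: BLE001 - re-tag with stage name
        raise PipelineError("fit", str(exc)) from exc
    try:
        bmd_result = msw.bmdl_profile(
            records,
            fit_result,
            bmr=config.bmr,
            t_star=config.t_star,
            conf_level=config.conf_level,
            unknown_policy=policy,
            c_bounds=config.c_bounds,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("bmdl", str(exc)) from exc
    branch = {
        "policy": policy.value,
        "b": list(fit_result.params.b),
        "c": fit_result.params.c,
        "loglik": fit_result.loglik,
        "converged": fit_result.converged,
        "records_used": fit_result.records_used,
        "bmd": bmd_result.bmd,
        "bmdl": bmd_result.bmdl,
    }
    prov.log(
        "fit+bmdl",
        {
            "policy": policy.value,
            "k": config.k,
            "c_bounds": list(config.c_bounds),
            "bmr": config.bmr,
            "t_star": config.t_star,
            "conf_level": config.conf_level,
            "n_starts": config.n_starts,
            "seed": config.seed,
            "loglik_tol": msw.LOGLIK_TOL,
        },
        branch,
    )
    return branch


def run_full_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the report bundle.

    When ``config.output_dir`` is set, writes ``report.json``,
    ``report.md`` and ``provenance.jsonl`` there.
    """
    prov = _Provenance()
    constants = config.constants

    # --- records -----------------------------------------------------------
    if config.records_csv is not None:
        try:
            records = read_animal_records(config.records_csv)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("read", str(exc)) from exc
        source = str(config.records_csv)
    else:
        design = default_ntp_design(seed=config.seed)
        records = simulate_bioassay(design)
        source = f"simulated(default_ntp_design, seed={config.seed})"
    prov.log("records", {"source": source}, {"n_records": len(records)})

    # --- fit + BMDL under both unknown-context policies --------------------
    branches = {
        "included": _fit_branch(records, config, msw.UnknownPolicy.AS_INCIDENTAL, prov),
        "excluded": _fit_branch(records, config, msw.UnknownPolicy.EXCLUDE, prov),
    }

    # --- conversion + IUR (headline branch: unknown animal included) -------
    rows = {}
    for name, branch in branches.items():
        try:
            pod_ppm = conversion.internal_to_human_ppm(
                branch["bmdl"], constants.human_conversion_factor
            )
            iur_result = unit_risk.compute_iur(
                config.bmr, pod_ppm, constants.ppm_to_ugm3
            )
            if config.apply_adaf:
                iur_result = unit_risk.apply_adaf(iur_result)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("iur", str(exc)) from exc
        row = {
            "bmdl": branch["bmdl"],
            "pod_ppm": iur_result.pod_ppm,
            "pod_ugm3": iur_result.pod_ugm3,
            "iur_per_ppm": iur_result.iur_per_ppm,
            "iur_per_ugm3": iur_result.iur_per_ugm3,
            "adaf_applied": iur_result.adaf_applied,
            "adaf_factor": iur_result.adaf_factor,
        }
        prov.log(
            "conversion+iur",
            {
                "branch": name,
                "bmdl": branch["bmdl"],
                "human_conversion_factor": constants.human_conversion_factor,
                "ppm_to_ugm3": constants.ppm_to_ugm3,
                "bmr": config.bmr,
                "apply_adaf": config.apply_adaf,
            },
            row,
        )
        rows[name] = row
    headline_iur = rows["included"]["iur_per_ugm3"]
    ratio = unit_risk.potency_ratio(constants.epa_2010_iur, headline_iur)
    prov.log(
        "potency_ratio",
        {"reference_iur": constants.epa_2010_iur, "new_iur": headline_iur},
        {"ratio": ratio},
    )

    # --- tumor-site independence screen ------------------------------------
    try:
        screen = independence.independence_screen(
            independence.pairs_from_marginals(ntp_female_mouse_tumor_pairs())
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("independence", str(exc)) from exc
    screen_rows = [
        {
            "label": row.label,
            "rho": None if row.result is None else row.result.rho,
            "p_value": None if row.result is None else row.result.p_value,
            "positive_correlation": row.positive_correlation,
            "significant": row.significant,
            "error": row.error,
        }
        for row in screen
    ]
    prov.log("independence", {"n_pairs": len(screen_rows)}, {"rows": screen_rows})

    # --- occupational reality check ----------------------------------------
    scenario = config.scenario
    median_conc = conversion.lifetime_concentration(config.median_ppm_years, scenario)
    mean_conc = conversion.lifetime_concentration(config.mean_ppm_years, scenario)
    reality: dict[str, Any] = {
        "median_conc_ugm3": median_conc,
        "mean_conc_ugm3_recomputed": mean_conc,
        "mean_conc_ugm3_printed": config.printed_mean_conc_ugm3,
        "projections": {},
    }
    iurs = {"reference": constants.epa_2010_iur, "recalculated": headline_iur}
    for iur_name, iur_value in iurs.items():
        concs = {"median": median_conc, "mean_recomputed": mean_conc}
        if config.printed_mean_conc_ugm3 is not None:
            concs["mean_printed"] = config.printed_mean_conc_ugm3
        for conc_name, conc in concs.items():
            proj = epi.excess_cases(iur_value, conc, config.n_exposed)
            reality["projections"][f"{iur_name}:{conc_name}"] = proj.excess_cases
    prov.log(
        "reality_check",
        {
            "median_ppm_years": config.median_ppm_years,
            "mean_ppm_years": config.mean_ppm_years,
            "printed_mean_conc_ugm3": config.printed_mean_conc_ugm3,
            "n_exposed": config.n_exposed,
            "scenario": dataclasses.asdict(scenario),
            "iurs": iurs,
        },
        reality,
    )

    report = {
        "config": {
            "k": config.k,
            "bmr": config.bmr,
            "t_star": config.t_star,
            "conf_level": config.conf_level,
            "seed": config.seed,
            "records": source,
        },
        "unit_risk_table": rows,
        "potency_ratio_vs_reference": ratio,
        "independence_screen": screen_rows,
        "reality_check": reality,
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        with open(out / "provenance.jsonl", "w") as fh:
            for entry in prov.entries:
                fh.write(json.dumps(entry) + "\n")
        (out / "report.md").write_text(_render_markdown(report))
    report["provenance"] = prov.entries
    return report


def _fmt_sig(x: float, sig: int = 3) -> str:
    return f"{x:.{sig}g}"


def _render_markdown(report: dict[str, Any]) -> str:
    rows = report["unit_risk_table"]
    lines = [
        "# Unit risk derivation",
        "",
        "| Branch | BMDL (µmole/g-lung/day) | External conc (ppm) | IUR (per ppm) "
        "| External conc (µg/m³) | IUR (per µg/m³) |",
        "|---|---|---|---|---|---|",
    ]
    for name, row in rows.items():
        lines.append(
            f"| unknown animal {name} | {_fmt_sig(row['bmdl'], 2)} "
            f"| {_fmt_sig(row['pod_ppm'])} | {_fmt_sig(row['iur_per_ppm'])} "
            f"| {row['pod_ugm3']:.0f} | {_fmt_sig(row['iur_per_ugm3'], 2)} |"
        )
    lines += [
        "",
        f"Reference unit risk is {_fmt_sig(report['potency_ratio_vs_reference'], 3)}x "
        "the recalculated one.",
        "",
        "# Tumor-site independence screen",
        "",
        "| Tumor type | rho | p-value | positive | significant |",
        "|---|---|---|---|---|",
    ]
    for row in report["independence_screen"]:
        rho = "error" if row["rho"] is None else f"{row['rho']:.3f}"
        p = "" if row["p_value"] is None else f"{row['p_value']:.4f}"
        lines.append(
            f"| {row['label']} | {rho} | {p} | {row['positive_correlation']} "
            f"| {row['significant']} |"
        )
    reality = report["reality_check"]
    lines += [
        "",
        "# Occupational excess-cancer reality check",
        "",
        f"Median lifetime concentration: {reality['median_conc_ugm3']:.0f} µg/m³; "
        f"mean (recomputed): {reality['mean_conc_ugm3_recomputed']:.0f} µg/m³"
        + (
            f"; mean (printed input): {reality['mean_conc_ugm3_printed']:.0f} µg/m³"
            if reality["mean_conc_ugm3_printed"] is not None
            else ""
        ),
        "",
        "| Unit risk | Scenario | Excess cases |",
        "|---|---|---|",
    ]
    for key, value in reality["projections"].items():
        iur_name, conc_name = key.split(":")
        lines.append(f"| {iur_name} | {conc_name} | {value:.0f} |")
    return "\n".join(lines) + "\n"
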