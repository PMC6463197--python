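"""Pipeline orchestration and report rendering.

``run_pipeline`` ties the stages together: load (or simulate) a
measurement batch, fit matrix-matched calibrations, evaluate matrix
effects, quantify the QC / limits / SRM analyses against the calibration
and the recovery spikes by single-point standard addition, derive the
validation metrics and top-down uncertainty budgets, and attach the
Eco-Scale score.  Computation keeps full precision; rounding to reporting
style happens only in the rendered tables.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    Analyte,
    MeasurementRecord,
    Role,
    SampleType,
    QcSeries,
    default_method_path,
    read_measurements,
    read_method_definition,
)
from .ecoscale import EcoScaleLedger
from .quantify import (
    StandardAdditionPair,
    fit_calibration,
    matrix_effect,
    response_ratio,
    standard_addition_conc,
)
from .simulate import default_sim_config, make_validation_batch
from .uncertainty import UncertaintyBudget, build_budget
from .validate import (
    limits_from_replicates,
    precision_inter,
    precision_intra,
    recovery,
    srm_compare,
    trueness,
)

logger = logging.getLogger("halovalid")

__all__ = [
    "PipelineError",
    "ValidationReport",
    "run_pipeline",
    "group_analyses",
    "determine_by_calibration",
    "determine_by_standard_addition",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# --------------------------------------------------------------------------
# Record bookkeeping

def group_analyses(
    records: Sequence[MeasurementRecord],
) -> dict[tuple[str, int], dict[str, MeasurementRecord]]:
    """Group records into analyses (injections) keyed by (batch, run)."""
    analyses: dict[tuple[str, int], dict[str, MeasurementRecord]] = defaultdict(dict)
    for rec in records:
        analyses[(rec.batch_id, rec.run_index)][rec.analyte] = rec
    return dict(analyses)


def _blank_areas(
    analyses: dict, analyte_names: Sequence[str]
) -> dict[str, float]:
    """Mean analyte peak area over blank analyses (0 when none present)."""
    per: dict[str, list[float]] = {name: [] for name in analyte_names}
    for runs in analyses.values():
        recs = list(runs.values())
        if recs and recs[0].sample_type is SampleType.BLANK:
            for name in analyte_names:
                if name in runs:
                    per[name].append(runs[name].peak_area)
    return {
        name: (float(np.mean(vals)) if vals else 0.0)
        for name, vals in per.items()
    }


def _ratio(
    runs: dict[str, MeasurementRecord],
    analyte: Analyte,
    blank_area: float = 0.0,
) -> float:
    is_rec = runs.get(analyte.is_ref)
    if is_rec is None:
        raise PipelineError(
            f"quantify: analysis lacks internal standard {analyte.is_ref!r} "
            f"for {analyte.name}"
        )
    return response_ratio(runs[analyte.name].peak_area, is_rec.peak_area, blank_area)


def _batch_runs(analyses: dict, batch_id: str) -> list[dict]:
    keys = sorted(k for k in analyses if k[0] == batch_id)
    return [analyses[k] for k in keys]


def determine_by_calibration(
    runs: dict[str, MeasurementRecord],
    analyte: Analyte,
    calibration,
    blank_area: float = 0.0,
) -> float:
    """Concentration of one analysis from the matrix-matched calibration.

    Uses the mean relative response factor, c = ratio * c_IS / RRF:
    exact for the proportional response the calibration verifies, and —
    unlike inverting the fitted line — free of the intercept leverage the
    highest calibration level exerts on low-concentration read-outs.
    """
    if calibration.rrf_mean <= 0:
        raise PipelineError(
            f"quantify[{analyte.name}]: non-positive mean RRF"
        )
    ratio = _ratio(runs, analyte, blank_area)
    return ratio * calibration.is_conc / calibration.rrf_mean


def determine_by_standard_addition(
    unknown_runs: dict[str, MeasurementRecord],
    addition_runs: dict[str, MeasurementRecord],
    analyte: Analyte,
    blank_area: float = 0.0,
) -> float:
    """Concentration from an unknown/addition analysis pair."""
    add_rec = addition_runs[analyte.name]
    if add_rec.addition_conc is None:
        raise PipelineError(
            f"quantify: addition analysis for {analyte.name} lacks "
            f"addition_conc"
        )
    pair = StandardAdditionPair(
        analyte=analyte.name,
        c_ad=add_rec.addition_conc,
        ratio_unknown=_ratio(unknown_runs, analyte, blank_area),
        ratio_added=_ratio(addition_runs, analyte, blank_area),
    )
    return standard_addition_conc(pair)


# --------------------------------------------------------------------------
# Report container

@dataclass
class ValidationReport:
    rows: list[dict]                      # one per analyte
    matrix_effects: list[dict]
    budgets: list[UncertaintyBudget]
    ecoscale: EcoScaleLedger
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "matrix_effects": self.matrix_effects,
            "budgets": [b.to_dict() for b in self.budgets],
            "ecoscale": self.ecoscale.to_dict(),
            "provenance": self.provenance,
        }

    def table(self) -> pd.DataFrame:
        """Per-analyte summary table (full precision)."""
        return pd.DataFrame(self.rows)

    def budget_table(self) -> pd.DataFrame:
        return pd.DataFrame([b.to_dict() for b in self.budgets])

    def rounded_table(self) -> pd.DataFrame:
        """Reporting-style rounding: 2 significant figures for limits,
        whole percent for recoveries; computation stays full-precision."""
        def sig2(x):
            return float(f"{x:.2g}") if pd.notna(x) else x

        t = self.table().copy()
        for col in ("lod", "loq"):
            t[col] = t[col].map(sig2)
        for col in ("recovery_pct", "trueness_recovery_pct"):
            if col in t:
                t[col] = t[col].round(0)
        t["r_squared"] = t["r_squared"].round(5)
        return t

    def summary_text(self) -> str:
        lines = [
            f"halovalid {self.provenance.get('version', '?')} validation summary",
            f"analytes: {len(self.rows)}",
        ]
        u_max = max((b.U_r_tot_pct for b in self.budgets), default=float("nan"))
        u_min = min((b.U_r_tot_pct for b in self.budgets), default=float("nan"))
        lines.append(
            f"expanded combined uncertainty range: "
            f"{u_min:.1f}-{u_max:.1f} %"
        )
        lines.append(
            f"Eco-Scale score: {self.ecoscale.score} "
            f"({self.ecoscale.classification})"
        )
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=False)
        self.table().to_csv(out / "report_table.csv", index=False)
        self.budget_table().to_csv(out / "budgets.csv", index=False)
        (out / "summary.txt").write_text(self.summary_text())
        logger.info("report written to %s", out)


# --------------------------------------------------------------------------
# Pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise PipelineError("config: top level must be a mapping")
        return loaded
    return dict(config or {})


def run_pipeline(config=None) -> ValidationReport:
    """Run the full validation pipeline from a config mapping or file.

    Config keys: ``method`` (path, default bundled), ``seed`` (int),
    ``measurements`` (CSV path; omitted -> a batch is simulated with
    ``simulation`` overrides), ``out_dir`` (written when present).
    Deterministic given inputs and seed.
    """
    cfg = _load_config(config)
    method_path = Path(cfg.get("method") or default_method_path())
    seed = int(cfg.get("seed", 0))

    try:
        panel, srm_certified, eco_ledger = read_method_definition(method_path)
    except Exception as exc:
        raise PipelineError(f"method-definition: {exc}") from exc
    panel_map = {a.name: a for a in panel}
    analytes = [a for a in panel if a.role is Role.ANALYTE]

    meas_path = cfg.get("measurements")
    try:
        if meas_path:
            records = read_measurements(meas_path, panel)
            meas_hash = _sha256(Path(meas_path))
        else:
            sim_cfg = default_sim_config(
                panel, seed=seed, srm_certified=srm_certified,
                **(cfg.get("simulation") or {}),
            )
            records = make_validation_batch(sim_cfg)
            meas_hash = "simulated"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"measurements: {exc}") from exc

    analyses = group_analyses(records)
    blanks = _blank_areas(analyses, [a.name for a in analytes])
    is_conc_map = cfg.get("is_conc") or {
        "Tetrachloro-m-xylene": 10.0, "BDE-77": 20.0,
    }

    # --- calibration + matrix effect -------------------------------------
    calibrations = {}
    me_results = []
    cal_runs = _batch_runs(analyses, "cal")
    me_matrix = _batch_runs(analyses, "me_matrix")
    me_solvent = _batch_runs(analyses, "me_solvent")
    for analyte in analytes:
        try:
            if cal_runs:
                levels = [
                    (runs[analyte.name].spike_conc,
                     _ratio(runs, analyte, blanks[analyte.name]))
                    for runs in cal_runs
                ]
                calibrations[analyte.name] = fit_calibration(
                    levels, is_conc_map[analyte.is_ref], analyte=analyte.name
                )
            if me_matrix and me_solvent:
                me_results.append(
                    matrix_effect(
                        [r[analyte.name].peak_area for r in me_matrix],
                        [r[analyte.name].peak_area for r in me_solvent],
                        analyte=analyte.name,
                    )
                )
        except Exception as exc:
            raise PipelineError(f"quantify[{analyte.name}]: {exc}") from exc

    # --- determinations ---------------------------------------------------
    def cal_determinations(batch_id: str, analyte: Analyte) -> list[float]:
        return [
            determine_by_calibration(
                runs, analyte, calibrations[analyte.name], blanks[analyte.name]
            )
            for runs in _batch_runs(analyses, batch_id)
        ]

    recovery_batches = sorted(
        {b for b, _ in analyses if b.startswith("rec_")},
        key=lambda b: float(b.split("_", 1)[1]),
    )
    qc_day_batches = sorted({b for b, _ in analyses if b.startswith("qc_day")})

    rows = []
    budgets = []
    for analyte in analytes:
        cal = calibrations.get(analyte.name)
        try:
            # recovery via standard addition, per level
            recs = []
            for batch in recovery_batches:
                runs = _batch_runs(analyses, batch)
                unknowns = [
                    r for r in runs
                    if r[analyte.name].sample_type is SampleType.SPIKED_SAMPLE
                ]
                additions = [
                    r for r in runs
                    if r[analyte.name].sample_type is SampleType.STANDARD_ADDITION
                ]
                if not unknowns or len(unknowns) != len(additions):
                    raise PipelineError(
                        f"validate[{analyte.name}]: unpaired standard-addition "
                        f"batch {batch!r}"
                    )
                level = unknowns[0][analyte.name].spike_conc
                determined = [
                    determine_by_standard_addition(
                        u, a, analyte, blanks[analyte.name]
                    )
                    for u, a in zip(unknowns, additions)
                ]
                recs.append(recovery(determined, level, analyte=analyte.name))

            limits = None
            if cal is not None and _batch_runs(analyses, "loq"):
                loq_det = cal_determinations("loq", analyte)
                spike = _batch_runs(analyses, "loq")[0][analyte.name].spike_conc
                limits = limits_from_replicates(loq_det, spike, analyte.name)

            intra = inter = true_rec = true_bias = float("nan")
            qc_nominal = None
            bias_values: list[float] = []
            if cal is not None and _batch_runs(analyses, "qc_intra"):
                bias_values = cal_determinations("qc_intra", analyte)
                intra = precision_intra(bias_values)
                qc_nominal = _batch_runs(analyses, "qc_intra")[0][
                    analyte.name
                ].spike_conc
                true_rec, true_bias = trueness(
                    float(np.mean(bias_values)), qc_nominal
                )
            if cal is not None and qc_day_batches:
                inter = precision_inter(
                    [cal_determinations(b, analyte) for b in qc_day_batches]
                )

            srm_result = None
            cert = next(
                (s for s in srm_certified if s.analyte == analyte.name), None
            )
            if cal is not None and cert and _batch_runs(analyses, "srm"):
                srm_det = cal_determinations("srm", analyte)
                srm_result = srm_compare(srm_det, cert)

            if cal is not None and _batch_runs(analyses, "qc_chart") and bias_values:
                chart = QcSeries(
                    analyte=analyte.name,
                    nominal_conc=qc_nominal,
                    values=tuple(cal_determinations("qc_chart", analyte)),
                )
                budgets.append(
                    build_budget(analyte, chart, bias_values, c_ref=qc_nominal)
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"validate[{analyte.name}]: {exc}") from exc

        mean_rec = (
            float(np.mean([r.recovery_pct for r in recs])) if recs else float("nan")
        )
        rows.append(
            {
                "analyte": analyte.name,
                "linear_range": cal.linear_range if cal else "",
                "r_squared": cal.r_squared if cal else float("nan"),
                "rrf": cal.rrf_mean if cal else float("nan"),
                "rrf_rsd_pct": cal.rrf_rsd_pct if cal else float("nan"),
                "lod": limits.lod if limits else float("nan"),
                "loq": limits.loq if limits else float("nan"),
                "pre_intra_rsd_pct": intra,
                "pre_inter_rsd_pct": inter,
                "recovery_pct": mean_rec,
                "recovery_by_level": {
                    f"{r.spike_level:g}": r.recovery_pct for r in recs
                },
                "trueness_recovery_pct": true_rec,
                "b_r_pct": true_bias,
                "srm_trueness_pct": srm_result.trueness_pct if srm_result else None,
                "srm_in_certified_range": (
                    srm_result.in_certified_range if srm_result else None
                ),
            }
        )

    provenance = {
        "version": __version__,
        "seed": seed,
        "method_sha256": _sha256(method_path),
        "measurements_sha256": meas_hash,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    report = ValidationReport(
        rows=rows,
        matrix_effects=[
            {"analyte": m.analyte, "me_pct": m.me_pct, "sd_pct_points": m.rsd_pct,
             "n": m.n}
            for m in me_results
        ],
        budgets=budgets,
        ecoscale=eco_ledger,
        provenance=provenance,
    )
    out_dir = cfg.get("out_dir")
    if out_dir:
        report.write(out_dir)
    return report
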