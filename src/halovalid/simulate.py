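"""Synthetic peak-area batches with the statistical structure the
validation stages assume, so every stage is testable without instrument
data.

The generator emulates a targeted MRM batch on spiked fish homogenate:

* per-analyte relative response factors and signed matrix effects;
* a process-recovery factor applied to analyte present in the homogenate
  (incurred content and validation spikes); the single-point
  standard-addition spike is modelled as quantitatively recovered
  (matrix-matched post-extraction addition), which is what makes the
  injected recovery identifiable by the standard-addition estimator;
* exponential lipid-dependent signal suppression applied equally to
  analytes and internal standards (real high-fat matrices attenuate the
  IS peak; equal application preserves response ratios, demonstrating why
  ratio-based quantification tolerates it).  The factor is anchored at the
  reference matrix lipid content (``lipid_ref_pct``, the matrix used for
  the matrix-effect study), exp(-coeff * (lipid - lipid_ref)), so the
  per-analyte ``me_true_pct`` is the *total* area effect of that matrix
  relative to neat solvent and extra fat only attenuates further;
* replicate noise.  The internal-standard area carries the injection-level
  noise; each analyte area is generated from its true analyte/IS ratio
  times the realised IS area with an independent error whose SD is the
  quadrature sum of a relative term (``noise_cv_pct``) and an additive
  concentration-equivalent floor (``noise_floor_conc``).  The response
  ratio therefore has CV = ``noise_cv_pct`` at concentrations well above
  the floor — the quantity the validation RSDs measure — while the floor
  dominates near the limits of the method, making LOD/LOQ spike-level
  dependent.

All randomness flows from the single ``seed``; batches are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .datamodel import (
    Analyte,
    MeasurementRecord,
    Role,
    SampleType,
    SrmCertifiedValue,
)

logger = logging.getLogger("halovalid")

__all__ = ["SimConfig", "default_sim_config", "simulate_area", "make_validation_batch"]

#: Matrix-matched calibration levels, ug/kg (seven levels spanning 0.1-60).
DEFAULT_CAL_LEVELS = (0.1, 0.5, 1.0, 5.0, 15.0, 30.0, 60.0)
#: Recovery spike levels, ug/kg.
DEFAULT_RECOVERY_LEVELS = (1.0, 5.0, 15.0, 30.0, 60.0)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters and batch plan for one synthetic batch."""

    panel: tuple[Analyte, ...]
    rrf_true: dict[str, float]            # per panel member (IS included)
    me_true_pct: dict[str, float]         # signed; + enhancement
    recovery_true_pct: dict[str, float]   # analytes only
    is_conc: dict[str, float]             # ug/kg per internal standard
    seed: int = 0
    base_scale: float = 10_000.0          # counts per ug/kg at zero lipid
    noise_cv_pct: float = 2.0             # CV of the response ratio
    noise_floor_conc: float = 0.009       # additive floor, ug/kg-equiv. SD
    lipid_suppression_coeff: float = 0.04  # per percent lipid
    lipid_ref_pct: float = 5.2            # anchor of the lipid factor
    addition_conc: float = 10.0           # standard-addition spike, ug/kg
    calibration_lipid_pct: float = 1.9
    qc_lipid_pct: float = 5.2
    srm_lipid_pct: float = 10.2
    # batch plan
    calibration_levels: tuple[float, ...] = DEFAULT_CAL_LEVELS
    recovery_levels: tuple[float, ...] = DEFAULT_RECOVERY_LEVELS
    recovery_reps: int = 5
    loq_spike: float = 0.1
    loq_reps: int = 10
    qc_conc: float = 5.0
    qc_chart_n: int = 24
    qc_intra_reps: int = 10
    qc_inter_days: int = 4
    qc_inter_reps_per_day: int = 4
    me_conc: float = 5.0
    me_reps: int = 5
    n_blanks: int = 3
    srm_reps: int = 3
    srm_true_conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_cv_pct < 0:
            raise ValueError("noise CV must be >= 0")
        for name, rec in self.recovery_true_pct.items():
            if not 0 < rec <= 150:
                raise ValueError(f"{name}: recovery {rec} outside (0, 150]")

    @property
    def analytes(self) -> tuple[Analyte, ...]:
        return tuple(a for a in self.panel if a.role is Role.ANALYTE)

    @property
    def internal_standards(self) -> tuple[Analyte, ...]:
        return tuple(a for a in self.panel if a.role is Role.INTERNAL_STANDARD)


def default_sim_config(
    panel: Sequence[Analyte],
    seed: int = 0,
    srm_certified: Sequence[SrmCertifiedValue] = (),
    **overrides,
) -> SimConfig:
    """Build a :class:`SimConfig` from the bundled defaults.

    Per-analyte response factors, matrix effects and process recoveries
    mirror the validated method's performance figures; any field of
    :class:`SimConfig` may be overridden by keyword.
    """
    path = resources.files("halovalid").joinpath("data/sim_defaults.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)

    rrf = {}
    me = {}
    rec = {}
    for name, entry in raw["analytes"].items():
        rrf[name] = float(entry["rrf_true"])
        me[name] = float(entry["me_true_pct"])
        rec[name] = float(entry["recovery_true_pct"])
    for name, entry in raw["internal_standards"].items():
        rrf[name] = float(entry["rrf_true"])
        me[name] = float(entry["me_true_pct"])

    missing = [a.name for a in panel if a.name not in rrf]
    if missing:
        raise ValueError(f"no simulation defaults for panel members {missing}")

    cfg = SimConfig(
        panel=tuple(panel),
        rrf_true=rrf,
        me_true_pct=me,
        recovery_true_pct=rec,
        is_conc={k: float(v) for k, v in raw["is_conc"].items()},
        seed=seed,
        base_scale=float(raw["base_scale"]),
        noise_cv_pct=float(raw["noise_cv_pct"]),
        noise_floor_conc=float(raw.get("noise_floor_conc", 0.0)),
        lipid_suppression_coeff=float(raw["lipid_suppression_coeff"]),
        lipid_ref_pct=float(raw.get("lipid_ref_pct", 5.2)),
        addition_conc=float(raw["addition_conc"]),
        calibration_lipid_pct=float(raw["calibration_lipid_pct"]),
        qc_lipid_pct=float(raw["qc_lipid_pct"]),
        srm_true_conc={s.analyte: s.certified_conc for s in srm_certified},
    )
    return replace(cfg, **overrides) if overrides else cfg


def _noise(rng: np.random.Generator, cv_pct: float) -> float:
    """Multiplicative noise factor 1 + eps, eps ~ N(0, cv), truncated at -1."""
    if cv_pct == 0:
        return 1.0
    return max(0.0, 1.0 + rng.normal(0.0, cv_pct / 100.0))


def simulate_area(
    conc: float,
    cfg: SimConfig,
    analyte: str,
    lipid_pct: float,
    rng: np.random.Generator,
    in_matrix: bool = True,
    recovery_pct: Optional[float] = None,
) -> float:
    """One noisy peak area for ``conc`` ug/kg of ``analyte``.

    area = base_scale * rrf * conc * (recovery/100) * (1 + ME/100)
           * exp(-lipid_coeff * (lipid% - lipid_ref%)) * (1 + eps)

    ``recovery_pct`` defaults to the configured process recovery for
    analytes and 100 % for internal standards; solvent standards
    (``in_matrix=False``) see neither matrix effect nor lipid suppression.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if recovery_pct is None:
        recovery_pct = cfg.recovery_true_pct.get(analyte, 100.0)
    me = cfg.me_true_pct.get(analyte, 0.0) if in_matrix else 0.0
    lipid_factor = (
        math.exp(-cfg.lipid_suppression_coeff * (lipid_pct - cfg.lipid_ref_pct))
        if in_matrix
        else 1.0
    )
    mean = (
        cfg.base_scale
        * cfg.rrf_true[analyte]
        * conc
        * (recovery_pct / 100.0)
        * (1.0 + me / 100.0)
        * lipid_factor
    )
    return mean * _noise(rng, cfg.noise_cv_pct)


def _analysis_records(
    cfg: SimConfig,
    extract_conc: dict[str, float],
    batch_id: str,
    run_index: int,
    sample_type: SampleType,
    rng: np.random.Generator,
    lipid_pct: Optional[float],
    in_matrix: bool = True,
    spike_conc: dict[str, float] | float = 0.0,
    addition_conc: Optional[float] = None,
) -> list[MeasurementRecord]:
    """Records for one injection: every panel member gets one peak area.

    ``extract_conc`` holds the analyte concentration actually present in
    the final extract (recovery already applied where it acts); internal
    standards are always at their nominal concentration with 100 %
    recovery.  Analyte areas are generated from the true analyte/IS ratio
    times the realised IS area with an independent relative error, so the
    per-injection response ratio has CV = ``noise_cv_pct`` exactly.
    """
    records: list[MeasurementRecord] = []
    is_areas: dict[str, float] = {}
    for std in cfg.internal_standards:
        area = simulate_area(
            cfg.is_conc[std.name], cfg, std.name, lipid_pct or 0.0, rng,
            in_matrix=in_matrix, recovery_pct=100.0,
        )
        is_areas[std.name] = area
        records.append(
            MeasurementRecord(
                analyte=std.name,
                batch_id=batch_id,
                run_index=run_index,
                sample_type=sample_type,
                peak_area=area,
                spike_conc=0.0,
                addition_conc=addition_conc,
                lipid_pct=lipid_pct,
            )
        )
    for analyte in cfg.analytes:
        conc = extract_conc.get(analyte.name, 0.0)
        std = analyte.is_ref
        me_a = cfg.me_true_pct.get(analyte.name, 0.0) if in_matrix else 0.0
        me_is = cfg.me_true_pct.get(std, 0.0) if in_matrix else 0.0
        ratio_per_conc = (
            cfg.rrf_true[analyte.name] * (1.0 + me_a / 100.0)
        ) / (cfg.rrf_true[std] * cfg.is_conc[std] * (1.0 + me_is / 100.0))
        true_ratio = ratio_per_conc * conc
        # a true blank carries no detected peak, hence zero integrated
        # area; the floor models integration variability of real peaks
        sd = 0.0 if conc == 0 else math.hypot(
            cfg.noise_cv_pct / 100.0 * true_ratio,
            cfg.noise_floor_conc * ratio_per_conc,
        )
        ratio = true_ratio if sd == 0 else max(0.0, true_ratio + rng.normal(0.0, sd))
        area = ratio * is_areas[std]
        level = (
            spike_conc.get(analyte.name, 0.0)
            if isinstance(spike_conc, dict)
            else float(spike_conc)
        )
        records.append(
            MeasurementRecord(
                analyte=analyte.name,
                batch_id=batch_id,
                run_index=run_index,
                sample_type=sample_type,
                peak_area=area,
                spike_conc=level,
                addition_conc=addition_conc,
                lipid_pct=lipid_pct,
            )
        )
    return records


def make_validation_batch(cfg: SimConfig) -> list[MeasurementRecord]:
    """Emit the full validation-study batch as tidy measurement records.

    The plan mirrors the reference design: blanks, a seven-level
    matrix-matched calibration (0.1-60 ug/kg), matrix-matched vs solvent
    standards for the matrix-effect study, recovery spikes at five levels
    (n = 5) each quantified by a paired standard-addition analysis,
    low-level spike replicates for the limits (n = 10 at 0.1 ug/kg),
    intra-day (n = 10) and inter-day (4 days x 4) QC replicates, a QC
    chart series (n >= 20 at 5 ug/kg) and SRM-like replicates at the
    certified concentrations.
    """
    rng = np.random.default_rng(cfg.seed)
    rec_of = lambda name: cfg.recovery_true_pct.get(name, 100.0) / 100.0
    records: list[MeasurementRecord] = []
    run = 0

    def emit(extract_conc, batch_id, sample_type, **kw):
        nonlocal run
        run += 1
        records.extend(
            _analysis_records(
                cfg, extract_conc, batch_id, run, sample_type, rng, **kw
            )
        )

    # blanks (matrix without analytes)
    for _ in range(cfg.n_blanks):
        emit({}, "blank", SampleType.BLANK,
             lipid_pct=cfg.calibration_lipid_pct)

    # matrix-matched calibration: post-extraction spike, no process loss
    for level in cfg.calibration_levels:
        conc = {a.name: level for a in cfg.analytes}
        emit(conc, "cal", SampleType.MATRIX_MATCHED_STANDARD,
             lipid_pct=cfg.calibration_lipid_pct, spike_conc=level)

    # matrix-effect study: matrix-matched vs neat-solvent standards
    for _ in range(cfg.me_reps):
        conc = {a.name: cfg.me_conc for a in cfg.analytes}
        emit(conc, "me_matrix", SampleType.MATRIX_MATCHED_STANDARD,
             lipid_pct=cfg.qc_lipid_pct, spike_conc=cfg.me_conc)
    for _ in range(cfg.me_reps):
        conc = {a.name: cfg.me_conc for a in cfg.analytes}
        emit(conc, "me_solvent", SampleType.SOLVENT_STANDARD,
             lipid_pct=None, in_matrix=False, spike_conc=cfg.me_conc)

    # recovery spikes, quantified by single-point standard addition:
    # the spike experiences the process recovery, the addition does not
    for level in cfg.recovery_levels:
        for _ in range(cfg.recovery_reps):
            unknown = {a.name: level * rec_of(a.name) for a in cfg.analytes}
            added = {
                a.name: level * rec_of(a.name) + cfg.addition_conc
                for a in cfg.analytes
            }
            emit(unknown, f"rec_{level:g}", SampleType.SPIKED_SAMPLE,
                 lipid_pct=cfg.calibration_lipid_pct, spike_conc=level)
            emit(added, f"rec_{level:g}", SampleType.STANDARD_ADDITION,
                 lipid_pct=cfg.calibration_lipid_pct, spike_conc=level,
                 addition_conc=cfg.addition_conc)

    # low-level spike replicates for LOD/LOQ
    for _ in range(cfg.loq_reps):
        conc = {a.name: cfg.loq_spike * rec_of(a.name) for a in cfg.analytes}
        emit(conc, "loq", SampleType.SPIKED_SAMPLE,
             lipid_pct=cfg.calibration_lipid_pct, spike_conc=cfg.loq_spike)

    # QC replicates: intra-day, inter-day and the QC chart
    qc_conc = lambda: {
        a.name: cfg.qc_conc * rec_of(a.name) for a in cfg.analytes
    }
    for _ in range(cfg.qc_intra_reps):
        emit(qc_conc(), "qc_intra", SampleType.QC,
             lipid_pct=cfg.qc_lipid_pct, spike_conc=cfg.qc_conc)
    for day in range(1, cfg.qc_inter_days + 1):
        for _ in range(cfg.qc_inter_reps_per_day):
            emit(qc_conc(), f"qc_day{day}", SampleType.QC,
                 lipid_pct=cfg.qc_lipid_pct, spike_conc=cfg.qc_conc)
    for _ in range(cfg.qc_chart_n):
        emit(qc_conc(), "qc_chart", SampleType.QC,
             lipid_pct=cfg.qc_lipid_pct, spike_conc=cfg.qc_conc)

    # SRM-like replicates at the certified concentrations
    if cfg.srm_true_conc:
        for _ in range(cfg.srm_reps):
            conc = {
                name: c * rec_of(name)
                for name, c in cfg.srm_true_conc.items()
            }
            emit(conc, "srm", SampleType.SRM, lipid_pct=cfg.srm_lipid_pct,
                 spike_conc=0.0)

    logger.info(
        "simulated batch: %d analyses, %d records (seed %d)",
        run, len(records), cfg.seed,
    )
    return records
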