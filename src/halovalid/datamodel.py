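"""Domain types and readers/writers shared by all pipeline stages.

The central objects are the analyte panel (MRM metadata, internal-standard
assignment, standard purity information) and the long/tidy measurement
table (one peak area per row).  Concentrations are stored and reported on
a wet-weight basis in ug/kg throughout.  MRM transitions are metadata only;
no spectral processing happens in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .ecoscale import EcoScaleLedger, PenaltyCategory, PenaltyItem

logger = logging.getLogger("halovalid")

__all__ = [
    "Role",
    "SampleType",
    "MrmTransition",
    "Analyte",
    "MeasurementRecord",
    "SrmCertifiedValue",
    "QcSeries",
    "MethodDefinitionError",
    "MeasurementTableError",
    "read_method_definition",
    "read_measurements",
    "write_measurements",
    "measurements_to_frame",
    "default_method_path",
]


class MethodDefinitionError(ValueError):
    """Invalid or inconsistent method-definition file."""


class MeasurementTableError(ValueError):
    """Invalid measurement table (bad schema, value, or unknown analyte)."""


class Role(str, Enum):
    ANALYTE = "analyte"
    INTERNAL_STANDARD = "internal_standard"


class SampleType(str, Enum):
    BLANK = "blank"
    SOLVENT_STANDARD = "solvent_standard"
    MATRIX_MATCHED_STANDARD = "matrix_matched_standard"
    SPIKED_SAMPLE = "spiked_sample"
    UNKNOWN = "unknown"
    STANDARD_ADDITION = "standard_addition"
    QC = "qc"
    SRM = "srm"


@dataclass(frozen=True)
class MrmTransition:
    """Precursor -> product transition with collision energy (volts)."""

    precursor: float
    product: float
    ce_v: float


@dataclass(frozen=True)
class Analyte:
    """Panel entry: identity, MRM metadata and standard-purity information.

    ``cert_expanded_u_pct`` is the expanded relative uncertainty of the
    standard purity from the manufacturer's certificate (coverage factor
    ``cert_coverage_k``); when absent, the purity-based rectangular-
    distribution estimate drives the reference-standard uncertainty.
    """

    name: str
    role: Role
    rt_min: float
    quant_transition: MrmTransition
    qual_transition: MrmTransition
    purity_pct: float
    is_ref: str = ""
    cert_expanded_u_pct: Optional[float] = None
    cert_coverage_k: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.purity_pct <= 100:
            raise MethodDefinitionError(
                f"{self.name}: purity {self.purity_pct} outside (0, 100]"
            )
        if self.role is Role.ANALYTE and not self.is_ref:
            raise MethodDefinitionError(
                f"{self.name}: analyte row lacks an internal-standard reference"
            )
        if self.cert_coverage_k <= 0:
            raise MethodDefinitionError(
                f"{self.name}: coverage factor must be positive"
            )


@dataclass(frozen=True)
class MeasurementRecord:
    """One peak area: analyte, run context, spike level, matrix descriptors."""

    analyte: str
    batch_id: str
    run_index: int
    sample_type: SampleType
    peak_area: float
    spike_conc: float = 0.0
    addition_conc: Optional[float] = None
    lipid_pct: Optional[float] = None
    moisture_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise MeasurementTableError(
                f"{self.analyte} ({self.batch_id}/{self.run_index}): "
                f"negative peak area {self.peak_area}"
            )
        if self.spike_conc < 0:
            raise MeasurementTableError(
                f"{self.analyte}: negative spike concentration {self.spike_conc}"
            )
        if self.sample_type is SampleType.STANDARD_ADDITION and (
            self.addition_conc is None or self.addition_conc <= 0
        ):
            raise MeasurementTableError(
                f"{self.analyte}: standard-addition record needs addition_conc > 0"
            )


@dataclass(frozen=True)
class SrmCertifiedValue:
    """Certified concentration of a reference material, ug/kg wet weight."""

    analyte: str
    certified_conc: float
    certified_expanded_u: float

    def __post_init__(self) -> None:
        if self.certified_conc <= 0:
            raise MethodDefinitionError(
                f"{self.analyte}: certified concentration must be positive"
            )


@dataclass(frozen=True)
class QcSeries:
    """Ordered QC-chart determinations for one analyte at one nominal level."""

    analyte: str
    nominal_conc: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(not (v > 0) for v in vals):
            raise ValueError(
                f"{self.analyte}: QC series values must be finite and > 0"
            )


# --------------------------------------------------------------------------
# Method-definition reader

def default_method_path() -> Path:
    """Path of the bundled method definition (panel, SRM values, Eco-Scale)."""
    return Path(str(resources.files("halovalid").joinpath("data/method.yaml")))


def _parse_transition(raw: dict, analyte: str, which: str) -> MrmTransition:
    try:
        return MrmTransition(
            precursor=float(raw["precursor"]),
            product=float(raw["product"]),
            ce_v=float(raw["ce_v"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise MethodDefinitionError(
            f"{analyte}: malformed {which} transition: {raw!r}"
        ) from exc


def read_method_definition(
    path: str | Path,
) -> tuple[list[Analyte], list[SrmCertifiedValue], EcoScaleLedger]:
    """Load and cross-link a method definition (YAML or JSON).

    Returns the analyte panel, SRM certified values and the Eco-Scale
    penalty ledger.  Raises :class:`MethodDefinitionError` for duplicate
    analyte names, unresolved internal-standard references, or purities
    outside (0, 100].
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MethodDefinitionError(f"{path}: not a mapping")

    panel_raw = raw.get("panel") or []
    if not panel_raw:
        raise MethodDefinitionError(f"{path}: no analytes")

    panel: list[Analyte] = []
    seen: set[str] = set()
    for entry in panel_raw:
        name = str(entry["name"])
        if name in seen:
            raise MethodDefinitionError(f"duplicate analyte name: {name!r}")
        seen.add(name)
        role = Role(entry.get("role", "analyte"))
        cert_u = entry.get("cert_expanded_u_pct")
        analyte = Analyte(
            name=name,
            role=role,
            is_ref=str(entry.get("is_ref", "") or ""),
            rt_min=float(entry.get("rt_min", float("nan"))),
            quant_transition=_parse_transition(
                entry["quant_transition"], name, "quantifier"
            ),
            qual_transition=_parse_transition(
                entry["qual_transition"], name, "qualifier"
            ),
            purity_pct=float(entry["purity_pct"]),
            cert_expanded_u_pct=None if cert_u is None else float(cert_u),
            cert_coverage_k=float(entry.get("cert_coverage_k", 2.0)),
        )
        if analyte.cert_expanded_u_pct is None:
            logger.debug(
                "%s: no purity certificate; rectangular-distribution estimate "
                "will be used for u_r,ref",
                name,
            )
        panel.append(analyte)

    is_names = {a.name for a in panel if a.role is Role.INTERNAL_STANDARD}
    for analyte in panel:
        if analyte.role is Role.ANALYTE and analyte.is_ref not in is_names:
            raise MethodDefinitionError(
                f"{analyte.name}: internal standard {analyte.is_ref!r} "
                f"not in panel"
            )

    srm = [
        SrmCertifiedValue(
            analyte=str(e["analyte"]),
            certified_conc=float(e["certified_conc"]),
            certified_expanded_u=float(e["certified_expanded_u"]),
        )
        for e in raw.get("srm_certified", [])
    ]

    ledger = EcoScaleLedger(
        items=[
            PenaltyItem(
                category=PenaltyCategory(e["category"]),
                label=str(e["label"]),
                amount_note=str(e.get("amount_note", "") or ""),
                penalty_points=int(e["penalty_points"]),
            )
            for e in raw.get("ecoscale", [])
        ]
    )

    logger.info(
        "method definition %s: %d panel rows (%d internal standards), "
        "%d SRM certified values, %d Eco-Scale items",
        path.name, len(panel), len(is_names), len(srm), len(ledger.items),
    )
    return panel, srm, ledger


# --------------------------------------------------------------------------
# Measurement-table reader/writer (long/tidy CSV, one peak area per row)

_MEAS_COLUMNS = [
    "analyte",
    "batch_id",
    "run_index",
    "sample_type",
    "spike_conc",
    "addition_conc",
    "peak_area",
    "lipid_pct",
    "moisture_pct",
]


def measurements_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = [
        {
            "analyte": r.analyte,
            "batch_id": r.batch_id,
            "run_index": r.run_index,
            "sample_type": r.sample_type.value,
            "spike_conc": r.spike_conc,
            "addition_conc": r.addition_conc,
            "peak_area": r.peak_area,
            "lipid_pct": r.lipid_pct,
            "moisture_pct": r.moisture_pct,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_MEAS_COLUMNS)


def write_measurements(
    records: Iterable[MeasurementRecord], path: str | Path
) -> None:
    """Write records as CSV with the documented long-format header."""
    measurements_to_frame(records).to_csv(path, index=False)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_measurements(
    path: str | Path, panel: Sequence[Analyte]
) -> list[MeasurementRecord]:
    """Read a long-format measurement CSV, validating against the panel.

    Rows naming analytes outside the panel are rejected with their row
    numbers; negative peak areas and unparseable numerics raise
    :class:`MeasurementTableError` naming the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in ("analyte", "sample_type", "peak_area") if c not in frame]
    if missing:
        raise MeasurementTableError(f"{path}: missing columns {missing}")

    known = {a.name for a in panel}
    unknown_rows = [
        i + 2  # header line + 1-based
        for i, name in enumerate(frame["analyte"])
        if str(name) not in known
    ]
    if unknown_rows:
        names = sorted(
            {str(n) for n in frame["analyte"] if str(n) not in known}
        )
        raise MeasurementTableError(
            f"{path}: unknown analytes {names} in rows {unknown_rows}"
        )

    records: list[MeasurementRecord] = []
    for i, row in frame.iterrows():
        rowno = int(i) + 2
        try:
            records.append(
                MeasurementRecord(
                    analyte=str(row["analyte"]),
                    batch_id=str(row.get("batch_id", "")),
                    run_index=int(row.get("run_index", 0)),
                    sample_type=SampleType(str(row["sample_type"])),
                    peak_area=float(row["peak_area"]),
                    spike_conc=float(row.get("spike_conc", 0.0) or 0.0),
                    addition_conc=_opt_float(row.get("addition_conc")),
                    lipid_pct=_opt_float(row.get("lipid_pct")),
                    moisture_pct=_opt_float(row.get("moisture_pct")),
                )
            )
        except (MeasurementTableError, ValueError) as exc:
            raise MeasurementTableError(f"{path} row {rowno}: {exc}") from exc
    logger.info("read %d measurement records from %s", len(records), path.name)
    return records
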