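"""Top-down combined measurement-uncertainty budgets.

The budget combines four relative components, all expressed in percent of
the same reference concentration:

* ``u_r,repro`` — within-lab reproducibility: sample RSD of >= 20
  consecutive QC-chart determinations;
* ``B_r`` — relative bias of the QC replicate mean against the reference
  concentration (signed; entered squared and uncorrected — bias is
  reported inside the uncertainty rather than corrected for);
* ``u_r,cm`` — uncertainty of the systematic error: SD/sqrt(n) of the QC
  replicates, relative to the reference;
* ``u_r,ref`` — uncertainty of the standard purity, from the certificate
  (expanded value divided by its coverage factor) or, absent a
  certificate, from a rectangular distribution on the purity:
  0.5 * (100 - y) / sqrt(3).

The combined value is the root sum of squares; the expanded uncertainty
multiplies it by a coverage factor of 2 (~95 % confidence).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import Analyte, QcSeries
from .quantify import sample_rsd_pct

logger = logging.getLogger("halovalid")

__all__ = [
    "UncertaintyBudget",
    "u_repro_from_qc",
    "bias_components",
    "u_ref_from_certificate",
    "u_ref_from_purity",
    "u_ref_for_analyte",
    "combine_budget",
    "build_budget",
]

DEFAULT_COVERAGE_K = 2.0


@dataclass(frozen=True)
class UncertaintyBudget:
    analyte: str
    u_r_repro_pct: float
    b_r_pct: float              # signed
    u_r_cm_pct: float
    u_r_ref_pct: float
    u_r_tot_pct: float
    U_r_tot_pct: float
    c_ref: float                # ug/kg; base of every relative component
    n_qc: int
    n_bias: int

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "u_r_repro_pct": self.u_r_repro_pct,
            "b_r_pct": self.b_r_pct,
            "u_r_cm_pct": self.u_r_cm_pct,
            "u_r_ref_pct": self.u_r_ref_pct,
            "u_r_tot_pct": self.u_r_tot_pct,
            "U_r_tot_pct": self.U_r_tot_pct,
            "c_ref": self.c_ref,
            "n_qc": self.n_qc,
            "n_bias": self.n_bias,
        }


def u_repro_from_qc(series: QcSeries) -> float:
    """Within-lab reproducibility: RSD% of the QC-chart determinations.

    The design calls for at least 20 independent consecutive values; 10-19
    only warns, fewer than 2 raises.
    """
    n = len(series.values)
    if n < 2:
        raise ValueError(f"{series.analyte}: QC series needs >= 2 values")
    if n < 20:
        warnings.warn(
            f"{series.analyte}: {n} QC values (< 20); reproducibility "
            f"estimate will be imprecise", stacklevel=2,
        )
    return sample_rsd_pct(series.values)


def bias_components(
    qc_values: Sequence[float], c_ref: float, analyte: str = ""
) -> tuple[float, float]:
    """Relative bias and uncertainty of the systematic error, in percent.

    B_r = (mean - c_ref)/c_ref * 100; u_cm = SD/sqrt(n);
    u_r,cm = u_cm/c_ref * 100.  Warns below the design minimum of 10
    replicates.
    """
    if c_ref <= 0:
        raise ValueError("reference concentration must be > 0")
    arr = np.asarray(qc_values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicate determinations")
    if arr.size < 10:
        warnings.warn(
            f"{analyte or 'bias'}: {arr.size} replicates (< 10) for the "
            f"systematic-error estimate", stacklevel=2,
        )
    b_r = float((arr.mean() - c_ref) / c_ref * 100.0)
    u_cm = float(arr.std(ddof=1) / math.sqrt(arr.size))
    u_r_cm = u_cm / c_ref * 100.0
    return b_r, u_r_cm


def u_ref_from_certificate(U_r_ref_pct: float, k: float = DEFAULT_COVERAGE_K) -> float:
    """Standard uncertainty of purity from a certificate's expanded value."""
    if U_r_ref_pct < 0:
        raise ValueError("expanded uncertainty must be >= 0")
    if k <= 0:
        raise ValueError("coverage factor must be > 0")
    return U_r_ref_pct / k


def u_ref_from_purity(purity_pct: float) -> float:
    """Rectangular-distribution purity uncertainty: 0.5*(100 - y)/sqrt(3)."""
    if not 0 < purity_pct <= 100:
        raise ValueError(f"purity {purity_pct} outside (0, 100]")
    return 0.5 * (100.0 - purity_pct) / math.sqrt(3.0)


def u_ref_for_analyte(analyte: Analyte) -> float:
    """Choose the purity-uncertainty route for a panel entry.

    A certificate expanded uncertainty takes precedence; the purity-based
    rectangular estimate is the fallback.
    """
    if analyte.cert_expanded_u_pct is not None:
        return u_ref_from_certificate(
            analyte.cert_expanded_u_pct, analyte.cert_coverage_k
        )
    return u_ref_from_purity(analyte.purity_pct)


def combine_budget(
    u_repro: float,
    b_r: float,
    u_cm: float,
    u_ref: float,
    coverage_k: float = DEFAULT_COVERAGE_K,
) -> tuple[float, float]:
    """Root-sum-of-squares combination of the four relative components.

    Returns ``(u_r_tot_pct, U_r_tot_pct)``; the bias enters squared, so
    its sign does not matter.  The expanded value uses ``coverage_k``
    (default 2, ~95 % confidence).
    """
    for name, val in (("u_repro", u_repro), ("u_cm", u_cm), ("u_ref", u_ref)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    u_tot = math.sqrt(u_repro**2 + b_r**2 + u_cm**2 + u_ref**2)
    return u_tot, coverage_k * u_tot


def build_budget(
    analyte: Analyte,
    qc_chart: QcSeries,
    bias_values: Sequence[float],
    c_ref: Optional[float] = None,
    coverage_k: float = DEFAULT_COVERAGE_K,
) -> UncertaintyBudget:
    """Assemble the full budget for one analyte.

    ``qc_chart`` supplies the reproducibility component; ``bias_values``
    (repeatability-condition QC replicates) supply B_r and u_r,cm against
    ``c_ref`` (defaults to the QC chart's nominal concentration, keeping
    every relative component on the same base).
    """
    if c_ref is None:
        c_ref = qc_chart.nominal_conc
    if c_ref != qc_chart.nominal_conc:
        raise ValueError(
            f"{analyte.name}: bias reference ({c_ref}) differs from the QC "
            f"chart nominal ({qc_chart.nominal_conc}); components would mix "
            f"bases"
        )
    u_repro = u_repro_from_qc(qc_chart)
    b_r, u_r_cm = bias_components(bias_values, c_ref, analyte.name)
    u_ref = u_ref_for_analyte(analyte)
    u_tot, U_tot = combine_budget(u_repro, b_r, u_r_cm, u_ref, coverage_k)
    return UncertaintyBudget(
        analyte=analyte.name,
        u_r_repro_pct=u_repro,
        b_r_pct=b_r,
        u_r_cm_pct=u_r_cm,
        u_r_ref_pct=u_ref,
        u_r_tot_pct=u_tot,
        U_r_tot_pct=U_tot,
        c_ref=float(c_ref),
        n_qc=len(qc_chart.values),
        n_bias=len(list(bias_values)),
    )
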