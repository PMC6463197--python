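"""Calibration, single-point standard addition and matrix-effect evaluation.

Quantification rests on internal-standard response ratios: each analyte
peak area is divided by the area of its assigned internal standard from
the same injection, cancelling common-mode injection and matrix-loading
variation.  Three routes are provided:

* a blank-corrected matrix-matched calibration line (response ratio vs
  concentration, ordinary least squares) with relative response factors
  (RRF) per level — their across-level RSD measures linearity;
* single-point standard addition: the unknown is analysed once as-is and
  once after adding a known concentration, and the analyte content follows
  from the two response ratios — immune to proportional matrix effects;
* matrix effect: signed percent enhancement/suppression of the analyte
  signal in matrix extract relative to neat solvent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("halovalid")

__all__ = [
    "CalibrationResult",
    "StandardAdditionPair",
    "MatrixEffectResult",
    "response_ratio",
    "fit_calibration",
    "standard_addition_conc",
    "matrix_effect",
    "sample_rsd_pct",
]


def sample_rsd_pct(values: Sequence[float]) -> float:
    """Relative standard deviation in percent, n-1 denominator."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(arr.std(ddof=1) / abs(mean) * 100.0)


@dataclass(frozen=True)
class CalibrationResult:
    analyte: str
    levels: tuple[tuple[float, float], ...]  # (conc ug/kg, response ratio)
    slope: float
    intercept: float
    r_squared: float
    rrf_mean: float
    rrf_rsd_pct: float
    is_conc: float

    @property
    def linear_range(self) -> str:
        concs = [c for c, _ in self.levels]
        return f"{min(concs):g}-{max(concs):g}"

    def predict_conc(self, ratio: float) -> float:
        """Invert the calibration line for one blank-corrected ratio."""
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: non-positive calibration slope")
        return (ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class StandardAdditionPair:
    """Response ratios from the unknown and the standard-addition analysis."""

    analyte: str
    c_ad: float                 # added concentration, ug/kg
    ratio_unknown: float        # A_i / A_IS from the unknown analysis
    ratio_added: float          # A_i+ad / A_ISsa from the addition analysis

    def __post_init__(self) -> None:
        if self.c_ad <= 0:
            raise ValueError(f"{self.analyte}: addition must be > 0")


@dataclass(frozen=True)
class MatrixEffectResult:
    analyte: str
    me_pct: float               # signed: + enhancement, - suppression
    rsd_pct: float
    n: int
    paired: bool = True


def response_ratio(
    area_analyte: float, area_is: float, area_blank: float = 0.0
) -> float:
    """Blank-corrected analyte/IS response ratio.

    Returns ``(area_analyte - area_blank) / area_is``; a negative result
    (blank exceeding the signal) is returned as-is with a warning.
    Raises ``ZeroDivisionError`` when the IS area is zero.
    """
    if area_is == 0:
        raise ZeroDivisionError("internal-standard area is zero: ratio undefined")
    if area_blank < 0:
        raise ValueError("blank area must be >= 0")
    ratio = (area_analyte - area_blank) / area_is
    if ratio < 0:
        logger.warning(
            "blank (%.3g) exceeds analyte signal (%.3g); negative ratio %.3g",
            area_blank, area_analyte, ratio,
        )
    return ratio


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    is_conc: float,
    analyte: str = "",
    weighted: bool = False,
) -> CalibrationResult:
    """Fit the calibration line of response ratio vs concentration.

    ``levels`` are (concentration ug/kg, blank-corrected response ratio)
    pairs; at least three distinct concentrations are required.  The RRF at
    each level is ``ratio * is_conc / conc`` and the across-level sample
    RSD of the RRFs is reported alongside R^2.

    The default fit is unweighted ordinary least squares; ``weighted=True``
    applies 1/x^2 weights (constant relative error).
    """
    if is_conc <= 0:
        raise ValueError("internal-standard concentration must be > 0")
    conc = np.asarray([c for c, _ in levels], dtype=float)
    ratio = np.asarray([r for _, r in levels], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be > 0")
    if np.unique(conc).size < 3:
        raise ValueError("need at least three distinct concentration levels")

    if weighted:
        w = 1.0 / conc**2
        W = np.diag(w)
        X = np.column_stack([conc, np.ones_like(conc)])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ratio)
        slope, intercept = float(beta[0]), float(beta[1])
        fitted = slope * conc + intercept
        ss_res = float(np.sum(w * (ratio - fitted) ** 2))
        ybar = float(np.sum(w * ratio) / np.sum(w))
        ss_tot = float(np.sum(w * (ratio - ybar) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(conc, ratio)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue**2)

    rrf = ratio * is_conc / conc
    rrf_mean = float(rrf.mean())
    if rrf_mean == 0:
        rrf_rsd = float("nan")
    else:
        rrf_rsd = float(rrf.std(ddof=1) / abs(rrf_mean) * 100.0)
    return CalibrationResult(
        analyte=analyte,
        levels=tuple((float(c), float(r)) for c, r in levels),
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r_squared, 0.0), 1.0),
        rrf_mean=rrf_mean,
        rrf_rsd_pct=rrf_rsd,
        is_conc=float(is_conc),
    )


def standard_addition_conc(pair: StandardAdditionPair) -> float:
    """Analyte concentration from a single-point standard addition.

    c_i = c_ad * (A_i/A_IS) / ((A_i+ad/A_ISsa) - (A_i/A_IS))

    The result is scale-invariant in the two ratios, so any proportional
    matrix effect or suppression common to both analyses cancels.  Raises
    ``ValueError`` when the addition did not increase the response
    (denominator <= 0), which makes the sample non-quantifiable.
    """
    denom = pair.ratio_added - pair.ratio_unknown
    if denom <= 0:
        raise ValueError(
            f"{pair.analyte}: standard addition did not increase the response "
            f"(ratio {pair.ratio_unknown:.4g} -> {pair.ratio_added:.4g})"
        )
    return pair.c_ad * pair.ratio_unknown / denom


def matrix_effect(
    areas_matrix: Sequence[float],
    areas_solvent: Sequence[float],
    analyte: str = "",
    convention: str = "matrix",
) -> MatrixEffectResult:
    """Signed percent matrix effect from matrix-matched vs solvent standards.

    The convention names the denominator. The default ``"matrix"`` puts
    the matrix-matched area there:

        ME% = (matrix - solvent) / matrix * 100

    so enhancement is positive and suppression negative;
    ``convention="solvent"`` divides by the solvent area instead.

    Equal-length inputs are paired by replicate order; unequal lengths fall
    back to comparing each matrix replicate with the solvent mean (logged
    as unpaired mode).  ``rsd_pct`` is the sample standard deviation of the
    per-replicate ME values, in percentage points (ME is itself a percent
    and may average near zero, so a ratio-to-mean RSD would be unstable).
    """
    mat = np.asarray(areas_matrix, dtype=float)
    sol = np.asarray(areas_solvent, dtype=float)
    if mat.size == 0 or sol.size == 0:
        raise ValueError("matrix and solvent replicate lists must be non-empty")
    if np.any(mat == 0):
        raise ValueError("matrix-matched area of zero: ME undefined")
    if convention not in ("matrix", "solvent"):
        raise ValueError(f"unknown ME convention {convention!r}")

    paired = mat.size == sol.size
    if paired:
        pairs = zip(mat, sol)
    else:
        logger.info(
            "%s: unpaired matrix-effect mode (%d matrix vs %d solvent "
            "replicates); comparing against the solvent mean",
            analyte or "<analyte>", mat.size, sol.size,
        )
        pairs = ((m, sol.mean()) for m in mat)

    per_rep = []
    for m, s in pairs:
        if convention == "matrix":
            per_rep.append((m - s) / m * 100.0)
        else:
            per_rep.append((m - s) / s * 100.0)
    per_rep = np.asarray(per_rep)
    me = float(per_rep.mean())
    rsd = float(per_rep.std(ddof=1)) if per_rep.size >= 2 else float("nan")
    return MatrixEffectResult(
        analyte=analyte, me_pct=me, rsd_pct=rsd, n=int(mat.size), paired=paired
    )
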