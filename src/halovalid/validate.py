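"""Validation metrics: limits, recovery, precision, trueness, SRM scoring.

Limits of detection and quantification follow the replicate-SD convention:
LOD = 3*SD and LOQ = 10*SD of the determined concentrations of low-level
spike replicates (n = 10 at 0.1 ug/kg in the reference design).  Recovery
acceptability follows the SANTE pesticide-residue rule: a mean recovery is
acceptable when it lies in 30-140 % with replicate RSD <= 20 % (the
routine target band being 70-120 %).  Trueness against a reference value
is expressed both as percent recovery and as signed relative bias
B_r = (mean - reference)/reference * 100, so recovery - 100 = B_r exactly.

All RSDs use the n-1 sample standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import SrmCertifiedValue
from .quantify import sample_rsd_pct

logger = logging.getLogger("halovalid")

__all__ = [
    "LimitResult",
    "RecoveryResult",
    "AccuracyResult",
    "SrmComparison",
    "limits_from_replicates",
    "recovery",
    "precision_intra",
    "precision_inter",
    "trueness",
    "srm_compare",
    "format_censored",
]

# SANTE acceptability rule for recoveries
SANTE_RECOVERY_MIN = 30.0
SANTE_RECOVERY_MAX = 140.0
SANTE_RSD_MAX = 20.0


@dataclass(frozen=True)
class LimitResult:
    analyte: str
    sd_at_spike: float          # ug/kg
    lod: float                  # 3 * SD
    loq: float                  # 10 * SD
    spike_level: float
    n: int


@dataclass(frozen=True)
class RecoveryResult:
    analyte: str
    spike_level: float
    recovery_pct: float
    rsd_pct: float
    n: int

    @property
    def acceptable(self) -> bool:
        return (
            SANTE_RECOVERY_MIN <= self.recovery_pct <= SANTE_RECOVERY_MAX
            and self.rsd_pct <= SANTE_RSD_MAX
        )


@dataclass(frozen=True)
class AccuracyResult:
    analyte: str
    pre_intra_rsd_pct: float
    pre_inter_rsd_pct: float
    mean_recovery_pct: float
    rel_bias_pct: float


@dataclass(frozen=True)
class SrmComparison:
    analyte: str
    trueness_pct: float
    rel_bias_pct: float
    rsd_pct: float
    in_certified_range: bool
    determined_mean: float
    certified_conc: float


def limits_from_replicates(
    determined: Sequence[float], spike_level: float, analyte: str = ""
) -> LimitResult:
    """LOD/LOQ from replicate determinations of a low-level spike.

    Uses the n-1 sample SD of the determined concentrations;
    LOD = 3*SD, LOQ = 10*SD (hence LOQ/LOD = 10/3 exactly).
    Warns below 10 replicates; requires at least 2.
    """
    arr = np.asarray(determined, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicate determinations")
    if arr.size < 6:
        warnings.warn(
            f"{analyte or 'limits'}: only {arr.size} replicates "
            f"(design calls for 10)", stacklevel=2,
        )
    elif arr.size < 10:
        logger.warning(
            "%s: %d replicates for limit estimation (design calls for 10)",
            analyte or "<analyte>", arr.size,
        )
    sd = float(arr.std(ddof=1))
    return LimitResult(
        analyte=analyte,
        sd_at_spike=sd,
        lod=3.0 * sd,
        loq=10.0 * sd,
        spike_level=float(spike_level),
        n=int(arr.size),
    )


def recovery(
    determined: Sequence[float], spike_level: float, analyte: str = ""
) -> RecoveryResult:
    """Percent recovery of a spike with replicate RSD and SANTE flag."""
    if spike_level <= 0:
        raise ValueError("spike level must be > 0")
    arr = np.asarray(determined, dtype=float)
    if arr.size == 0:
        raise ValueError("empty determination list")
    rec = float(arr.mean() / spike_level * 100.0)
    rsd = sample_rsd_pct(arr) if arr.size >= 2 else float("nan")
    return RecoveryResult(
        analyte=analyte,
        spike_level=float(spike_level),
        recovery_pct=rec,
        rsd_pct=rsd,
        n=int(arr.size),
    )


def precision_intra(determined: Sequence[float]) -> float:
    """Intra-day precision: sample RSD (%) of same-day QC determinations."""
    return sample_rsd_pct(determined)


def precision_inter(
    by_day: Sequence[Sequence[float]], method: str = "pooled"
) -> float:
    """Inter-day precision RSD (%) from a days x replicates design.

    ``method="pooled"`` (default) treats all day x replicate values as one
    sample and returns its RSD — identical to :func:`precision_intra` on
    the pooled values.  ``method="anova"`` performs a one-way random-effects
    decomposition and returns the intermediate-precision RSD
    sqrt(s_within^2 + s_between^2)/grand mean (between-day variance clipped
    at zero when the mean square between falls below the within).
    """
    if len(by_day) < 2:
        raise ValueError("need at least two days")
    days = [np.asarray(d, dtype=float) for d in by_day]
    if any(d.size == 0 for d in days):
        raise ValueError("empty day in inter-day design")
    pooled = np.concatenate(days)
    grand = pooled.mean()
    if grand == 0:
        raise ValueError("RSD undefined for zero mean")

    if method == "pooled":
        return sample_rsd_pct(pooled)
    if method != "anova":
        raise ValueError(f"unknown inter-day method {method!r}")

    if any(d.size < 2 for d in days):
        raise ValueError("ANOVA decomposition needs >= 2 replicates per day")
    k = len(days)
    n_i = np.array([d.size for d in days], dtype=float)
    means = np.array([d.mean() for d in days])
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in days)
    ms_within = ss_within / (pooled.size - k)
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ms_between = ss_between / (k - 1)
    n0 = (pooled.size - (n_i**2).sum() / pooled.size) / (k - 1)
    s2_between = max(0.0, (ms_between - ms_within) / n0)
    return float(np.sqrt(ms_within + s2_between) / abs(grand) * 100.0)


def trueness(mean_measured: float, reference: float) -> tuple[float, float]:
    """Percent recovery and signed relative bias against a reference value.

    Returns ``(recovery_pct, rel_bias_pct)`` with
    recovery = mean/reference * 100 and B_r = (mean - reference)/reference
    * 100; the identity recovery - 100 = B_r holds exactly.
    """
    if reference <= 0:
        raise ValueError("reference concentration must be > 0")
    rec = mean_measured / reference * 100.0
    return float(rec), float(rec - 100.0)


def srm_compare(
    determined: Sequence[float],
    cert: SrmCertifiedValue,
    determined_expanded_u: Optional[float] = None,
) -> SrmComparison:
    """Score replicate SRM determinations against a certified value.

    Trueness and bias come from :func:`trueness` on the replicate mean.
    The range check uses the certified interval [c - U, c + U] (inclusive):
    when ``determined_expanded_u`` is given the check is whether
    mean +/- that expanded uncertainty overlaps the certified interval,
    otherwise whether the mean itself falls inside it.
    """
    arr = np.asarray(determined, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two SRM determinations")
    mean = float(arr.mean())
    rec, bias = trueness(mean, cert.certified_conc)
    # inclusive interval with a numeric guard so a mean sitting exactly on
    # a certified bound ("at the border") is not expelled by rounding
    tol = 1e-9 * max(1.0, cert.certified_conc)
    lo = cert.certified_conc - cert.certified_expanded_u - tol
    hi = cert.certified_conc + cert.certified_expanded_u + tol
    if determined_expanded_u is not None:
        in_range = (mean - determined_expanded_u) <= hi and (
            mean + determined_expanded_u
        ) >= lo
    else:
        in_range = lo <= mean <= hi
    return SrmComparison(
        analyte=cert.analyte,
        trueness_pct=rec,
        rel_bias_pct=bias,
        rsd_pct=sample_rsd_pct(arr),
        in_certified_range=bool(in_range),
        determined_mean=mean,
        certified_conc=cert.certified_conc,
    )


def format_censored(value: float, loq: float, sig: int = 2) -> str:
    """Report a concentration, censoring below-LOQ values as '<LOQ' strings.

    Mirrors the survey-table style ('<0.09'): the numeric LOQ is attached,
    rounded to ``sig`` significant figures; quantifiable values are
    formatted at the same precision.
    """
    def _sig(x: float) -> str:
        if x == 0:
            return "0"
        return f"{x:.{sig}g}"

    if value < loq:
        return f"<{_sig(loq)}"
    return _sig(value)
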