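"""qRT-PCR quantification: calibration curves, Ct-to-copies, %IS conversion.

Calibration fits cycle threshold against log10(copies/uL) by least squares
over individual wells (not replicate means — this preserves degrees of
freedom in the fit quality statistic).  Copy numbers for unknown samples are
extrapolated by inverting the fitted line; duplicate wells are summed per
target before the fusion/control ratio is scaled to the percent
international scale.

Notes on conventions:

* An undetermined (absent/NaN) Ct maps to 0 copies for the fusion target —
  non-detection — but invalidates the sample when both control-gene wells
  are undetermined, since a failed control gene leaves no denominator.
* The lab-specific IS conversion factor defaults to 0.542.  (Source texts
  disagree between 0.542 in prose and 0.5 in a displayed formula; the factor
  is deliberately a required, configurable input.)
* Amplification efficiency is ``10**(-1/slope) - 1``; a value outside
  [0.9, 1.1] raises :class:`~mpxval.errors.EfficiencyWarning` without
  affecting the computation.
* No limit-of-quantification truncation is applied to %IS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, EfficiencyWarning, InsufficientDataError, InvalidSampleError, SchemaError

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "SampleQuant",
    "DEFAULT_CONVERSION_FACTOR",
    "DEFAULT_ABL1_FLOOR",
    "fit_calibration",
    "ct_to_copies",
    "percent_is",
    "quantify_sample",
    "read_calibration_csv",
    "read_sample_ct_csv",
    "quantify_table",
]

DEFAULT_CONVERSION_FACTOR = 0.542
#: Minimum summed control-gene copies for a sample to count as valid.
#: A common molecular-monitoring QC floor, not a measured constant.
DEFAULT_ABL1_FLOOR = 10_000.0

EFFICIENCY_QC_WINDOW = (0.9, 1.1)


@dataclass(frozen=True)
class CalibrationStandard:
    """One plasmid reference level: known concentration and replicate Cts."""

    copies_per_ul: float
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.copies_per_ul <= 0:
            raise ValueError(f"copies_per_ul must be positive, got {self.copies_per_ul}")
        if not any(math.isfinite(c) for c in self.ct_values):
            raise ValueError("at least one finite Ct value required per standard")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(f"calibration slope must be negative, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    @property
    def efficiency(self) -> float:
        """Fractional per-cycle amplification efficiency, 10**(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class SampleQuant:
    sample_id: str
    bcr_abl1_copies: float
    abl1_copies: float
    percent_is: float
    conversion_factor: float
    valid: bool


def fit_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationCurve:
    """Least-squares fit of Ct on log10(copies/uL) over individual wells.

    Requires at least three distinct concentration levels.  A non-negative
    slope (copies not inversely related to Ct) is a calibration failure.
    """
    levels = {s.copies_per_ul for s in standards}
    if len(levels) < 3:
        raise InsufficientDataError(
            f"calibration needs >= 3 distinct concentration levels, got {len(levels)}"
        )
    x, y = [], []
    for s in standards:
        for ct in s.ct_values:
            if math.isfinite(ct):
                x.append(math.log10(s.copies_per_ul))
                y.append(float(ct))
    if len(x) < 3:
        raise InsufficientDataError("fewer than 3 finite calibration wells")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise CalibrationError(
            f"calibration failure: non-negative slope {res.slope:.4g} (Ct must fall with copies)"
        )
    r2 = min(1.0, float(res.rvalue) ** 2)
    curve = CalibrationCurve(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2, n_points=len(x)
    )
    lo, hi = EFFICIENCY_QC_WINDOW
    if not lo <= curve.efficiency <= hi:
        warnings.warn(
            f"amplification efficiency {curve.efficiency:.3f} outside QC window [{lo}, {hi}]",
            EfficiencyWarning,
            stacklevel=2,
        )
    return curve


def ct_to_copies(curve: CalibrationCurve, ct: float | None) -> float:
    """Invert the calibration line: copies = 10**((ct - intercept) / slope).

    An undetermined Ct (None or NaN) maps to 0 copies (non-detection).
    """
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return 0.0
    return 10.0 ** ((float(ct) - curve.intercept) / curve.slope)


def percent_is(
    bcr_abl1_copies: float,
    abl1_copies: float,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
) -> float:
    """(fusion copies / control copies) x 100 x conversion factor."""
    if conversion_factor <= 0:
        raise ValueError(f"conversion_factor must be positive, got {conversion_factor}")
    if abl1_copies <= 0:
        raise InvalidSampleError("control gene yielded no copies; sample cannot be normalized")
    if bcr_abl1_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    return (bcr_abl1_copies / abl1_copies) * 100.0 * conversion_factor


def quantify_sample(
    bcr_abl1_cts: Iterable[float | None],
    abl1_cts: Iterable[float | None],
    bcr_abl1_curve: CalibrationCurve,
    abl1_curve: CalibrationCurve,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
    abl1_floor: float = DEFAULT_ABL1_FLOOR,
    sample_id: str = "",
) -> SampleQuant:
    """Quantify one sample from duplicate Ct observations per target.

    Each well's Ct is converted to copies via its target's curve and the
    duplicates are summed per target before the ratio is taken.  Undetermined
    fusion-gene wells count 0 copies; a sample with every control-gene well
    undetermined is invalid (raises).  The ``valid`` flag is false when the
    summed control copies fall below ``abl1_floor``.
    """
    abl1_cts = list(abl1_cts)
    bcr_abl1_cts = list(bcr_abl1_cts)
    if all(c is None or (isinstance(c, float) and math.isnan(c)) for c in abl1_cts):
        raise InvalidSampleError(
            f"sample {sample_id or '<unnamed>'}: all control-gene wells undetermined"
        )
    bcr_sum = sum(ct_to_copies(bcr_abl1_curve, c) for c in bcr_abl1_cts)
    abl_sum = sum(ct_to_copies(abl1_curve, c) for c in abl1_cts)
    return SampleQuant(
        sample_id=sample_id,
        bcr_abl1_copies=bcr_sum,
        abl1_copies=abl_sum,
        percent_is=percent_is(bcr_sum, abl_sum, conversion_factor),
        conversion_factor=conversion_factor,
        valid=abl_sum >= abl1_floor,
    )


# ---------------------------------------------------------------------------
# tabular I/O

_UNDETERMINED_TOKENS = {"", "undetermined", "undet", "na", "nan", "none"}


def _parse_ct(token: object) -> float:
    s = str(token).strip().lower()
    if s in _UNDETERMINED_TOKENS:
        return math.nan
    return float(token)


def read_calibration_csv(path) -> dict[str, list[CalibrationStandard]]:
    """Read calibration wells (columns: target, copies_per_ul, ct) grouped by target."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"target", "copies_per_ul", "ct"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, list[CalibrationStandard]] = {}
    for (target, conc), grp in frame.groupby(["target", "copies_per_ul"], sort=True):
        cts = tuple(_parse_ct(v) for v in grp["ct"])
        out.setdefault(str(target), []).append(
            CalibrationStandard(copies_per_ul=float(conc), ct_values=cts)
        )
    return out


def read_sample_ct_csv(path) -> dict[str, dict[str, list[float]]]:
    """Read per-well sample Cts (columns: sample_id, target, replicate, ct)."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"sample_id", "target", "replicate", "ct"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, dict[str, list[float]]] = {}
    for row in frame.sort_values(["sample_id", "target", "replicate"]).itertuples(index=False):
        out.setdefault(str(row.sample_id), {}).setdefault(str(row.target), []).append(
            _parse_ct(row.ct)
        )
    return out


def quantify_table(
    sample_cts: dict[str, dict[str, list[float]]],
    bcr_abl1_curve: CalibrationCurve,
    abl1_curve: CalibrationCurve,
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR,
    abl1_floor: float = DEFAULT_ABL1_FLOOR,
    bcr_abl1_target: str = "BCR_ABL1",
    abl1_target: str = "ABL1",
):
    """Quantify every sample; returns a DataFrame sorted by sample_id."""
    import pandas as pd

    rows = []
    for sid in sorted(sample_cts):
        targets = sample_cts[sid]
        quant = quantify_sample(
            targets.get(bcr_abl1_target, [math.nan, math.nan]),
            targets.get(abl1_target, []),
            bcr_abl1_curve,
            abl1_curve,
            conversion_factor=conversion_factor,
            abl1_floor=abl1_floor,
            sample_id=sid,
        )
        rows.append(
            {
                "sample_id": quant.sample_id,
                "bcr_abl1_copies": quant.bcr_abl1_copies,
                "abl1_copies": quant.abl1_copies,
                "percent_is": quant.percent_is,
                "valid": quant.valid,
            }
        )
    return pd.DataFrame(rows)
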