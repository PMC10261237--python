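"""Deterministic interpretation of multiplex-PCR gel band patterns.

Observed fragment lengths are matched to the expected amplicon sizes of the
fusion-transcript variants (310 bp b2a2, 385 bp b3a2, 481 bp e1a2, 927 bp
e19a2, 1125 bp e6a2, 1319 bp e8a2) and the 808 bp wild-type internal
control.  A lane with neither a fusion band nor the control is an
amplification failure (invalid); control-only lanes are valid negatives.

Default size tolerance is +/-3% of the expected size: the closest expected
pair (310 vs 385 bp) is ~22% apart, so 3% can never be ambiguous, but the
ambiguity guard is kept for wider tolerances.  By default a fusion band
without the control band is scored positive-and-valid — the fusion
amplification itself demonstrates the reaction worked; ``strict_control``
switches that lane to invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import AmbiguousBandError, MultipleFusionBandsWarning, SchemaError

__all__ = [
    "BandPattern",
    "TranscriptCall",
    "EXPECTED_FUSION_SIZES",
    "CONTROL_SIZE",
    "DEFAULT_TOLERANCE",
    "classify_bands",
    "cohort_validity_rate",
    "read_band_csv",
    "classify_table",
]

#: Expected fusion amplicon sizes (bp) -> transcript variant.
EXPECTED_FUSION_SIZES: dict[int, str] = {
    310: "b2a2",
    385: "b3a2",
    481: "e1a2",
    927: "e19a2",
    1125: "e6a2",
    1319: "e8a2",
}
#: Wild-type internal-control amplicon size (bp).
CONTROL_SIZE = 808
DEFAULT_TOLERANCE = 0.03

Variant = Literal["b2a2", "b3a2", "e1a2", "e19a2", "e6a2", "e8a2", "none"]


@dataclass(frozen=True)
class BandPattern:
    sample_id: str
    band_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.band_sizes):
            raise ValueError(f"band sizes must be positive: {self.band_sizes}")


@dataclass(frozen=True)
class TranscriptCall:
    sample_id: str
    variant: Variant
    control_present: bool
    valid: bool
    binary_result: Literal["positive", "negative", "invalid"]


def _match_band(size: float, tolerance: float) -> int | None:
    """Expected size matched by an observed band, or None; raises if ambiguous."""
    expected = sorted([*EXPECTED_FUSION_SIZES, CONTROL_SIZE])
    hits = [e for e in expected if abs(size - e) <= tolerance * e]
    if len(hits) > 1:
        raise AmbiguousBandError(
            f"band {size:g} bp matches multiple expected sizes {hits} at tolerance {tolerance}"
        )
    return hits[0] if hits else None


def classify_bands(
    pattern: BandPattern,
    tolerance: float = DEFAULT_TOLERANCE,
    strict_control: bool = False,
) -> TranscriptCall:
    """Map a lane's band sizes to a transcript call and binary result.

    Band order is irrelevant.  Multiple fusion bands in one lane are reported
    as the largest variant with a warning.
    """
    if not 0 < tolerance <= 0.1:
        raise ValueError(f"tolerance must lie in (0, 0.1], got {tolerance}")
    matched = {m for b in pattern.band_sizes if (m := _match_band(b, tolerance)) is not None}
    control_present = CONTROL_SIZE in matched
    fusion_sizes = sorted(matched - {CONTROL_SIZE})
    if len(fusion_sizes) > 1:
        warnings.warn(
            f"sample {pattern.sample_id}: multiple fusion bands {fusion_sizes}; "
            "reporting the largest",
            MultipleFusionBandsWarning,
            stacklevel=2,
        )
    variant: Variant = EXPECTED_FUSION_SIZES[fusion_sizes[-1]] if fusion_sizes else "none"

    if fusion_sizes:
        valid = control_present or not strict_control
        binary = "positive" if valid else "invalid"
    elif control_present:
        valid, binary = True, "negative"
    else:
        valid, binary = False, "invalid"
    return TranscriptCall(
        sample_id=pattern.sample_id,
        variant=variant,
        control_present=control_present,
        valid=valid,
        binary_result=binary,
    )


def cohort_validity_rate(calls: Sequence[TranscriptCall]) -> float:
    """Fraction of valid runs among all calls."""
    if not calls:
        raise ValueError("cohort_validity_rate requires a non-empty list of calls")
    return sum(c.valid for c in calls) / len(calls)


# ---------------------------------------------------------------------------
# tabular I/O

def read_band_csv(path) -> list[BandPattern]:
    """Read band patterns (columns: sample_id, band_sizes as ';'-joined bp values)."""
    import pandas as pd

    frame = pd.read_csv(path, dtype={"band_sizes": str})
    required = {"sample_id", "band_sizes"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    patterns = []
    for row in frame.itertuples(index=False):
        raw = "" if pd.isna(row.band_sizes) else str(row.band_sizes)
        sizes = tuple(float(tok) for tok in raw.split(";") if tok.strip())
        patterns.append(BandPattern(sample_id=str(row.sample_id), band_sizes=sizes))
    return patterns


def classify_table(
    patterns: Sequence[BandPattern],
    tolerance: float = DEFAULT_TOLERANCE,
    strict_control: bool = False,
):
    """Classify every pattern; returns a DataFrame."""
    import pandas as pd

    calls = [classify_bands(p, tolerance, strict_control) for p in patterns]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "variant": [c.variant for c in calls],
            "control_present": [c.control_present for c in calls],
            "valid": [c.valid for c in calls],
            "binary_result": [c.binary_result for c in calls],
        }
    )
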