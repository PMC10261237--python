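"""Binary index test versus continuous reference: cutoff sweep, ROC, DeLong AUC.

The reference assay yields a continuous value (%IS); the index test yields a
single positive/negative call.  The reference is dichotomized at candidate
cutoffs with the strict convention ``condition-positive <=> value > cutoff``
(a value exactly at the cutoff counts as condition-negative).  Sensitivity is
the fraction of index-positive calls among condition-positives, specificity
the fraction of index-negative calls among condition-negatives.  When a
denominator is empty the corresponding metric is carried as ``None`` (never
coerced to 0).

The AUC is the Mann-Whitney two-sample statistic with the binary index call
as the class label and the continuous reference as the score (midrank / 0.5
handling of score ties); its variance comes from DeLong placement components.
This is the standard orientation for a DeLong computation and is distinct
from the inverted sensitivity/specificity profile exposed by
:func:`roc_points` and :func:`sweep_cutoffs` — the two constructions condition
on different variables and are both provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateClassesError, DuplicateCutoffWarning, SchemaError

__all__ = [
    "PairedSample",
    "CutoffPerformance",
    "RocCurve",
    "AucEstimate",
    "DEFAULT_CUTOFF_GRID",
    "binarize_reference",
    "performance_at_cutoff",
    "sweep_cutoffs",
    "roc_points",
    "delong_auc",
    "optimal_cutoff",
    "read_paired_samples",
    "sweep_to_frame",
    "roc_to_frame",
]

#: Default sweep grid: ten cutoffs covering 0.1 to 1.0 %IS.
DEFAULT_CUTOFF_GRID: tuple[float, ...] = tuple(round(0.1 * k, 10) for k in range(1, 11))


@dataclass(frozen=True)
class PairedSample:
    """One patient's continuous reference %IS and binary index-test call."""

    sample_id: str
    reference_value: float
    index_result: bool

    def __post_init__(self) -> None:
        v = float(self.reference_value)
        if not math.isfinite(v) or v < 0:
            raise ValueError(
                f"reference_value must be finite and >= 0, got {self.reference_value!r} "
                f"for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class CutoffPerformance:
    """Confusion counts and derived metrics at one reference cutoff.

    ``sensitivity`` / ``specificity`` are ``None`` when their denominator
    (condition-positive resp. condition-negative class) is empty.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def youden_j(self) -> float | None:
        """Youden's J = sensitivity + specificity - 1; None if either is undefined."""
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class RocCurve:
    """Inverted-profile ROC: (cutoff, sensitivity, 1 - specificity) triples.

    Contains the degenerate endpoints (0, 0) and (1, 1) corresponding to the
    all-condition-negative and all-condition-positive labelings.
    """

    points: tuple[tuple[float, float, float], ...]


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    n_positive: int = 0
    n_negative: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc must lie in [0, 1], got {self.auc}")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("confidence bounds must bracket the point estimate")


def _reference_array(pairs: Sequence[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray([p.reference_value for p in pairs], dtype=float)
    idx = np.asarray([bool(p.index_result) for p in pairs], dtype=bool)
    return ref, idx


def binarize_reference(values: Iterable[float], cutoff: float) -> np.ndarray:
    """Dichotomize reference values: positive iff value > cutoff (strict).

    A value exactly equal to the cutoff is labeled negative ("below cutoff"
    absorbs equality).
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("reference values must be finite")
    return arr > cutoff


def performance_at_cutoff(pairs: Sequence[PairedSample], cutoff: float) -> CutoffPerformance:
    """Confusion matrix and metrics for one cutoff.

    Condition = (reference > cutoff), prediction = binary index result.
    """
    if len(pairs) == 0:
        raise ValueError("performance_at_cutoff requires a non-empty sample list")
    ref, idx = _reference_array(pairs)
    cond = ref > cutoff
    tp = int(np.sum(cond & idx))
    fn = int(np.sum(cond & ~idx))
    tn = int(np.sum(~cond & ~idx))
    fp = int(np.sum(~cond & idx))
    n = tp + fp + tn + fn
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return CutoffPerformance(
        cutoff=float(cutoff),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / n,
    )


def sweep_cutoffs(
    pairs: Sequence[PairedSample],
    cutoffs: Sequence[float] | None = None,
) -> list[CutoffPerformance]:
    """Evaluate the index test at each cutoff of a grid (default 0.1 ... 1.0 %IS).

    Cutoffs are sorted ascending; duplicates are collapsed with a warning.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_CUTOFF_GRID
    grid = list(cutoffs)
    if not grid:
        raise ValueError("cutoff grid must be non-empty")
    uniq = sorted(set(float(c) for c in grid))
    if len(uniq) < len(grid):
        warnings.warn(
            f"{len(grid) - len(uniq)} duplicate cutoff(s) removed from sweep grid",
            DuplicateCutoffWarning,
            stacklevel=2,
        )
    return [performance_at_cutoff(pairs, c) for c in uniq]


def roc_points(pairs: Sequence[PairedSample]) -> RocCurve:
    """Inverted-profile ROC over all candidate cutoffs.

    Candidate cutoffs are the unique reference values plus a sentinel below
    the minimum; the maximum reference value itself yields the all-negative
    labeling.  Degenerate ends are replaced by their limiting points: the
    all-condition-positive end maps to (1, 1) and the all-condition-negative
    end to (0, 0).
    """
    if len(pairs) == 0:
        raise ValueError("roc_points requires a non-empty sample list")
    ref, _ = _reference_array(pairs)
    uniq = np.unique(ref)
    sentinel_low = float(uniq[0]) - 1.0
    candidates = [sentinel_low] + [float(u) for u in uniq]
    pts: list[tuple[float, float, float]] = []
    for c in candidates:
        perf = performance_at_cutoff(pairs, c)
        if perf.specificity is None:
            # no condition-negatives: all-positive labeling -> limiting (1, 1)
            pts.append((c, 1.0, 1.0))
        elif perf.sensitivity is None:
            # no condition-positives: all-negative labeling -> limiting (0, 0)
            pts.append((c, 0.0, 0.0))
        else:
            pts.append((c, perf.sensitivity, 1.0 - perf.specificity))
    return RocCurve(points=tuple(pts))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values with midrank tie handling.

    V10[i] = (1/n) * sum_j psi(pos_i, neg_j), V01[j] = (1/m) * sum_i psi,
    where psi = 1 if pos > neg, 0.5 on ties, 0 otherwise.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = rankdata(combined)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def delong_auc(
    pairs: Sequence[PairedSample],
    level: float = 0.95,
    ci_method: Literal["wald", "logit"] = "wald",
) -> AucEstimate:
    """Mann-Whitney AUC with DeLong variance and confidence interval.

    The binary index result is the class label; the continuous reference
    value is the score.  Ties contribute 0.5.  The Wald CI is computed on the
    AUC scale and clipped to [0, 1]; ``ci_method="logit"`` transforms to the
    logit scale instead (back-transformed bounds never leave (0, 1)).
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    ref, idx = _reference_array(pairs)
    pos = ref[idx]
    neg = ref[~idx]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateClassesError(
            f"both index-result classes must be present (got {m} positive, {n} negative)"
        )
    v10, v01 = _placements(pos, neg)
    auc = float(np.mean(v10))
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.5 + level / 2.0)
    if ci_method == "wald":
        lo = max(0.0, auc - z * se)
        hi = min(1.0, auc + z * se)
    elif ci_method == "logit":
        if se == 0.0 or auc <= 0.0 or auc >= 1.0:
            # logit transform degenerates; fall back to the clipped Wald form
            lo = max(0.0, auc - z * se)
            hi = min(1.0, auc + z * se)
        else:
            logit = math.log(auc / (1.0 - auc))
            se_logit = se / (auc * (1.0 - auc))
            lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
            hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return AucEstimate(
        auc=auc, se=se, ci_low=lo, ci_high=hi, level=level, n_positive=m, n_negative=n
    )


_CRITERIA = ("youden", "accuracy", "closest_topleft")


def optimal_cutoff(
    sweep: Sequence[CutoffPerformance],
    criterion: Literal["youden", "accuracy", "closest_topleft"] = "youden",
) -> tuple[float, CutoffPerformance]:
    """Select the best-performing cutoff from a sweep.

    Default criterion is Youden's J = sensitivity + specificity - 1, computed
    only over rows where both metrics are defined; ties break toward the
    lower cutoff.  ``accuracy`` maximizes accuracy; ``closest_topleft``
    minimizes the Euclidean distance to the (0, 1) ROC corner.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")
    if not sweep:
        raise ValueError("optimal_cutoff requires a non-empty sweep")
    rows = sorted(sweep, key=lambda r: r.cutoff)

    def score(row: CutoffPerformance) -> float | None:
        if criterion == "accuracy":
            return row.accuracy
        if row.sensitivity is None or row.specificity is None:
            return None
        if criterion == "youden":
            return row.youden_j
        return -math.hypot(1.0 - row.sensitivity, 1.0 - row.specificity)

    best: CutoffPerformance | None = None
    best_score = -math.inf
    for row in rows:
        s = score(row)
        if s is not None and s > best_score:
            best, best_score = row, s
    if best is None:
        raise ValueError(
            "no cutoff with both sensitivity and specificity defined; cannot select optimum"
        )
    return best.cutoff, best


# ---------------------------------------------------------------------------
# tabular I/O

_POSITIVE_TOKENS = {"1", "pos", "positive", "true", "yes", "+"}
_NEGATIVE_TOKENS = {"0", "neg", "negative", "false", "no", "-"}


def parse_binary_result(token: object) -> bool:
    """Parse an index-test call; accepts 0/1 and pos/neg spellings."""
    s = str(token).strip().lower()
    if s in _POSITIVE_TOKENS:
        return True
    if s in _NEGATIVE_TOKENS:
        return False
    raise SchemaError(f"cannot parse binary index result {token!r}")


def read_paired_samples(path) -> list[PairedSample]:
    """Read a paired-sample CSV with columns sample_id, qrt_percent_is, mpx_result."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"sample_id", "qrt_percent_is", "mpx_result"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: no data rows")
    return [
        PairedSample(
            sample_id=str(row.sample_id),
            reference_value=float(row.qrt_percent_is),
            index_result=parse_binary_result(row.mpx_result),
        )
        for row in frame.itertuples(index=False)
    ]


def sweep_to_frame(sweep: Sequence[CutoffPerformance]):
    """Sweep table as a DataFrame (cutoff, counts, metrics); None -> NaN."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cutoff": [r.cutoff for r in sweep],
            "tp": [r.tp for r in sweep],
            "fp": [r.fp for r in sweep],
            "tn": [r.tn for r in sweep],
            "fn": [r.fn for r in sweep],
            "sensitivity": [np.nan if r.sensitivity is None else r.sensitivity for r in sweep],
            "specificity": [np.nan if r.specificity is None else r.specificity for r in sweep],
            "accuracy": [r.accuracy for r in sweep],
        }
    )


def roc_to_frame(curve: RocCurve):
    import pandas as pd

    return pd.DataFrame(curve.points, columns=["cutoff", "sensitivity", "fpr"])
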