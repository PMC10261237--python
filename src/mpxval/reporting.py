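"""Cohort summary tables and figure export.

Percentages are rounded half-up to one decimal so that emitted tables match
conventional clinical reporting.  %IS bin membership follows the analysis
boundary convention (value > edge goes to the upper bin), so summaries and
the cutoff analysis never disagree at bin boundaries.  Note the source
tables label the adjacent bins 0.001-0.1% and 0.11-1%, leaving (0.1, 0.11)
unassigned; the summary uses contiguous half-open bins instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CohortSummary",
    "IS_BIN_EDGES",
    "IS_BIN_LABELS",
    "DURATION_CATEGORIES",
    "round_half_up",
    "assign_is_bin",
    "summarize_cohort",
    "sex_ratio",
    "plot_roc_curve",
    "plot_sweep_profile",
]

IS_BIN_EDGES: tuple[float, ...] = (0.001, 0.1, 1.0, 10.0)
IS_BIN_LABELS: tuple[str, ...] = ("<0.001", "0.001-0.1", "0.1-1", "1-10", ">10")
DURATION_CATEGORIES: tuple[str, ...] = (
    "naive",
    "1-3 months",
    "3-6 months",
    "6-12 months",
    ">1 year",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (3.25 -> 3.3 at 1 decimal), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def assign_is_bin(percent_is: float, edges: Sequence[float] = IS_BIN_EDGES) -> int:
    """Bin index for a %IS value; value > edge goes to the upper bin."""
    if percent_is < 0:
        raise ValueError(f"%IS must be >= 0, got {percent_is}")
    return int(np.searchsorted(np.asarray(edges, dtype=float), percent_is, side="left"))


@dataclass(frozen=True)
class CohortSummary:
    """Counts and half-up-rounded percentages for a cohort."""

    n_total: int
    counts_by_is_bin: dict[str, int]
    counts_by_treatment_duration: dict[str, int]
    n_male: int
    n_female: int

    def __post_init__(self) -> None:
        if sum(self.counts_by_is_bin.values()) != self.n_total:
            raise ValueError("%IS bin counts must sum to the cohort total")

    def percentages_by_is_bin(self) -> dict[str, float]:
        return {
            k: round_half_up(100.0 * v / self.n_total, 1)
            for k, v in self.counts_by_is_bin.items()
        }

    def percentages_by_treatment_duration(self) -> dict[str, float]:
        return {
            k: round_half_up(100.0 * v / self.n_total, 1)
            for k, v in self.counts_by_treatment_duration.items()
        }

    @property
    def male_female_ratio(self) -> float:
        return sex_ratio(self.n_male, self.n_female)

    def to_dict(self) -> dict:
        out = {
            "n_total": self.n_total,
            "counts_by_is_bin": dict(self.counts_by_is_bin),
            "percent_by_is_bin": self.percentages_by_is_bin(),
            "counts_by_treatment_duration": dict(self.counts_by_treatment_duration),
            "percent_by_treatment_duration": self.percentages_by_treatment_duration(),
            "n_male": self.n_male,
            "n_female": self.n_female,
        }
        if self.n_female > 0:
            out["male_female_ratio"] = self.male_female_ratio
        return out


def summarize_cohort(
    percent_is_values: Sequence[float],
    duration_categories: Sequence[str] | None = None,
    sexes: Sequence[str] | None = None,
) -> CohortSummary:
    """Tabulate a cohort into %IS bins, treatment-duration categories and sex.

    ``duration_categories`` entries must come from :data:`DURATION_CATEGORIES`;
    ``sexes`` entries are 'male'/'M' or 'female'/'F' (case-insensitive).
    """
    values = list(percent_is_values)
    if not values:
        raise ValueError("summarize_cohort requires a non-empty cohort")
    n = len(values)
    bin_counts = {label: 0 for label in IS_BIN_LABELS}
    for v in values:
        bin_counts[IS_BIN_LABELS[assign_is_bin(v)]] += 1

    duration_counts = {label: 0 for label in DURATION_CATEGORIES}
    if duration_categories is not None:
        if len(duration_categories) != n:
            raise ValueError("duration_categories length must match the cohort")
        for d in duration_categories:
            if d not in duration_counts:
                raise ValueError(
                    f"unknown duration category {d!r}; expected one of {DURATION_CATEGORIES}"
                )
            duration_counts[d] += 1

    n_male = n_female = 0
    if sexes is not None:
        if len(sexes) != n:
            raise ValueError("sexes length must match the cohort")
        for s in sexes:
            tok = str(s).strip().lower()
            if tok in {"m", "male"}:
                n_male += 1
            elif tok in {"f", "female"}:
                n_female += 1
            else:
                raise ValueError(f"cannot parse sex {s!r}")

    return CohortSummary(
        n_total=n,
        counts_by_is_bin=bin_counts,
        counts_by_treatment_duration=duration_counts,
        n_male=n_male,
        n_female=n_female,
    )


def sex_ratio(n_male: int, n_female: int) -> float:
    """Male:female ratio rounded half-up to one decimal."""
    if n_female <= 0:
        raise ValueError("sex ratio undefined with zero females")
    if n_male < 0:
        raise ValueError("counts must be non-negative")
    return round_half_up(n_male / n_female, 1)


# ---------------------------------------------------------------------------
# figures

def plot_roc_curve(curve, path, title: str = "ROC curve") -> None:
    """Save the (1 - specificity, sensitivity) curve as a simple figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = sorted(curve.points, key=lambda p: (p[2], p[1]))
    fpr = [p[2] for p in pts]
    sens = [p[1] for p in pts]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, sens, marker="o", ms=3, lw=1.2)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep_profile(sweep, path, title: str = "Performance vs cutoff") -> None:
    """Sensitivity / specificity / accuracy versus cutoff, one line each."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cutoffs = [r.cutoff for r in sweep]
    fig, ax = plt.subplots(figsize=(5.5, 4.0))
    for attr in ("sensitivity", "specificity", "accuracy"):
        ys = [getattr(r, attr) for r in sweep]
        ax.plot(cutoffs, [np.nan if y is None else y for y in ys], marker="o", ms=3, label=attr)
    ax.set_xlabel("cutoff (%IS)")
    ax.set_ylabel("metric")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
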