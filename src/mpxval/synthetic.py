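"""Synthetic cohorts of paired (continuous %IS, binary assay call) samples.

The generator mirrors the statistical structure the cutoff analysis assumes:
patients fall into %IS bins with configurable probabilities; within a bin the
latent %IS is log-uniform (it spans five orders of magnitude, and only bin
counts are known); a configurable fraction of lowest-bin patients carries
exactly zero transcript.  The binary assay fires with a logistic detection
probability on the log10(%IS) scale — it always detects high burdens, never
fires on zero transcript when the false-positive rate is zero, and
transitions near its analytical detection limit.

The default bin probabilities (9, 35, 25, 24, 126 of 219) reproduce the
observed cohort composition across the bins <0.001, 0.001-0.1, 0.1-1, 1-10
and >10 %IS.  The default detection parameters (midpoint 0.3 %IS, slope 0.25
on the log10 scale, zero false-positive rate) are a modeling choice, not a
measured property of any assay: they are set so that a simulated sweep shows
100% specificity at 0.1 %IS and a sensitivity collapse below roughly
0.6 %IS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit

from .cutoffs import PairedSample
from .errors import ConfigError

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "TABLE4_BIN_COUNTS",
    "detection_probability",
    "sample_cohort",
    "default_table4_config",
    "cohort_to_frame",
    "write_cohort_csv",
    "config_to_yaml",
    "config_from_yaml",
]

#: Observed cohort bin counts (bins <0.001, 0.001-0.1, 0.1-1, 1-10, >10 %IS).
TABLE4_BIN_COUNTS: tuple[int, ...] = (9, 35, 25, 24, 126)

_DEFAULT_EDGES = (0.001, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    ``bin_edges`` are interior %IS boundaries; together with ``lower_cap``
    and ``upper_cap`` they define ``len(bin_edges) + 1`` bins.  Non-zero
    lowest-bin draws are log-uniform on (lower_cap, bin_edges[0]]; the open
    top bin is capped at ``upper_cap``.
    """

    n_patients: int
    bin_probs: tuple[float, ...]
    bin_edges: tuple[float, ...] = _DEFAULT_EDGES
    p_zero_in_lowest_bin: float = 0.5
    detection_mid: float = 0.3
    detection_slope: float = 0.25
    false_positive_rate: float = 0.0
    seed: int = 0
    lower_cap: float = 1e-5
    upper_cap: float = 100.0
    measurement_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError(f"n_patients must be positive, got {self.n_patients}")
        probs = np.asarray(self.bin_probs, dtype=float)
        edges = np.asarray(self.bin_edges, dtype=float)
        if probs.size != edges.size + 1:
            raise ConfigError(
                f"need {edges.size + 1} bin probabilities for {edges.size} edges, got {probs.size}"
            )
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError("bin_probs must be non-negative and sum to 1 within 1e-12")
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ConfigError("bin_edges must be positive and strictly increasing")
        if not (0.0 < self.lower_cap < edges[0]):
            raise ConfigError("lower_cap must lie in (0, first bin edge)")
        if self.upper_cap <= edges[-1]:
            raise ConfigError("upper_cap must exceed the last bin edge")
        if not 0.0 <= self.p_zero_in_lowest_bin <= 1.0:
            raise ConfigError("p_zero_in_lowest_bin must lie in [0, 1]")
        if self.detection_mid <= 0:
            raise ConfigError("detection_mid must be positive")
        if self.detection_slope < 0:
            raise ConfigError("detection_slope must be >= 0 (0 = step detector)")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ConfigError("false_positive_rate must lie in [0, 1]")
        if self.measurement_cv < 0:
            raise ConfigError("measurement_cv must be >= 0")

    @property
    def all_edges(self) -> tuple[float, ...]:
        """Full bin boundary sequence including the caps."""
        return (self.lower_cap, *self.bin_edges, self.upper_cap)


@dataclass(frozen=True)
class SyntheticCohort:
    samples: tuple[PairedSample, ...]
    true_is_values: np.ndarray
    config: CohortConfig
    seed: int

    def __post_init__(self) -> None:
        if len(self.samples) != self.config.n_patients:
            raise ValueError("cohort size does not match configuration")


def detection_probability(true_is, config: CohortConfig):
    """Probability that the binary assay fires at a given latent %IS.

    Returns ``false_positive_rate`` at exactly zero transcript; otherwise
    ``fpr + (1 - fpr) * logistic((log10(x) - log10(mid)) / slope)``.  A slope
    of zero degenerates to a step detector at the midpoint (value 0.5 at the
    midpoint itself).  Monotone non-decreasing in ``true_is``.  Accepts
    scalars or arrays; negative values raise.
    """
    x = np.asarray(true_is, dtype=float)
    if np.any(x < 0):
        raise ValueError("true_is must be >= 0")
    fpr = config.false_positive_rate
    p = np.full(x.shape, fpr, dtype=float)
    nz = x > 0
    if np.any(nz):
        with np.errstate(divide="ignore"):
            t = np.log10(x[nz]) - np.log10(config.detection_mid)
        if config.detection_slope == 0.0:
            logistic = np.where(t > 0, 1.0, np.where(t < 0, 0.0, 0.5))
        else:
            logistic = expit(t / config.detection_slope)
        p[nz] = fpr + (1.0 - fpr) * logistic
    return float(p) if p.ndim == 0 else p


def sample_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; fully reproducible given ``config.seed``.

    Bin membership is multinomial in ``bin_probs``; non-zero %IS is
    log-uniform within the bin; lowest-bin patients are exactly zero with
    probability ``p_zero_in_lowest_bin``; the binary call is Bernoulli with
    :func:`detection_probability`.  The reported reference value equals the
    latent value unless ``measurement_cv`` enables log-normal noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    edges = np.asarray(config.all_edges)
    k = len(config.bin_probs)

    bins = rng.choice(k, size=n, p=np.asarray(config.bin_probs, dtype=float))
    lo = np.log10(edges[bins])
    hi = np.log10(edges[bins + 1])
    true_is = 10.0 ** (lo + rng.random(n) * (hi - lo))
    zero_mask = (bins == 0) & (rng.random(n) < config.p_zero_in_lowest_bin)
    true_is[zero_mask] = 0.0

    reported = true_is.copy()
    if config.measurement_cv > 0:
        sigma = np.sqrt(np.log1p(config.measurement_cv**2))
        noise = rng.standard_normal(n)
        nz = reported > 0
        reported[nz] *= np.exp(sigma * noise[nz] - 0.5 * sigma**2)

    positive = rng.random(n) < detection_probability(true_is, config)

    width = max(4, len(str(n)))
    samples = tuple(
        PairedSample(
            sample_id=f"S{i + 1:0{width}d}",
            reference_value=float(reported[i]),
            index_result=bool(positive[i]),
        )
        for i in range(n)
    )
    return SyntheticCohort(
        samples=samples, true_is_values=true_is, config=config, seed=config.seed
    )


def default_table4_config(n_patients: int, seed: int, **overrides) -> CohortConfig:
    """Config with the observed cohort bin frequencies and default detection model.

    ``bin_probs`` = (9, 35, 25, 24, 126) / 219.  Extra keyword arguments
    override any :class:`CohortConfig` field.
    """
    total = sum(TABLE4_BIN_COUNTS)
    probs = tuple(c / total for c in TABLE4_BIN_COUNTS)
    cfg = CohortConfig(n_patients=n_patients, bin_probs=probs, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# serialization

def cohort_to_frame(cohort: SyntheticCohort):
    """Cohort as a DataFrame: sample_id, true_percent_is, qrt_percent_is, mpx_result."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort.samples],
            "true_percent_is": cohort.true_is_values,
            "qrt_percent_is": [s.reference_value for s in cohort.samples],
            "mpx_result": [int(s.index_result) for s in cohort.samples],
        }
    )


def write_cohort_csv(cohort: SyntheticCohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.10g")


def config_to_yaml(config: CohortConfig, path) -> None:
    import yaml

    payload = asdict(config)
    payload["bin_probs"] = [float(p) for p in config.bin_probs]
    payload["bin_edges"] = [float(e) for e in config.bin_edges]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_from_yaml(path) -> CohortConfig:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["bin_probs"] = tuple(payload["bin_probs"])
    payload["bin_edges"] = tuple(payload["bin_edges"])
    return CohortConfig(**payload)
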