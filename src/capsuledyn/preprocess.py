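"""Probe filtering, replicate aggregation, and log2-ratio profiles.

Two filtering rules are applied to the summarized array data before any
downstream analysis:

1. *Absent filter* — drop a probe set whose detection call is "A" in every
   array of the series (it was never reliably detected).
2. *Low-expression filter* — drop a probe set whose per-week replicate
   median sits below the expression floor (default 100, the MAS5 scaling
   target) at every week.  Retention requires at least one week at or
   above the floor.

Surviving probes are aggregated to one median intensity per week, and
expression dynamics are expressed as log2 ratios of each later week over
the week-1 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import InputFormatError, NumericDomainError


@dataclass
class PreprocessConfig:
    """Filtering and baseline settings.

    ``expression_floor`` is on the intensity scale of the input (100 for
    MAS5 scaled to a target of 100); ``baseline_week`` is the reference
    time point for ratios; ``absent_symbol`` is the detection call treated
    as absent.
    """

    expression_floor: float = 100.0
    baseline_week: int = 1
    absent_symbol: str = "A"

    def __post_init__(self) -> None:
        if self.expression_floor <= 0:
            raise InputFormatError("expression_floor must be positive")


@dataclass
class FilterResult:
    """Outcome of one filtering rule: surviving dataset plus removals."""

    dataset: ExpressionDataset
    removed: list = field(default_factory=list)
    rule: str = ""

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_absent(
    dataset: ExpressionDataset, config: PreprocessConfig | None = None
) -> FilterResult:
    """Remove probes called absent in every sample of the dataset.

    A single non-absent call at any week in any replicate retains the
    probe; values of retained probes are untouched.
    """
    config = config or PreprocessConfig()
    all_absent = (dataset.calls == config.absent_symbol).all(axis=1)
    removed = dataset.probe_ids[all_absent].tolist()
    kept = dataset.subset_probes(dataset.probe_ids[~all_absent])
    return FilterResult(kept, removed, rule="all_absent")


def median_by_timepoint(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-probe, per-week median intensity across replicates.

    Returns a DataFrame indexed by probe id with one column per week in
    ascending order.  The standard sample median is used; an even number
    of replicates yields the midpoint of the two central order statistics.
    """
    weeks = dataset.weeks
    cols = {}
    for week in weeks:
        samp = dataset.samples.index[dataset.samples["week"] == week]
        if len(samp) == 0:
            raise InputFormatError(f"no replicate for week {week}")
        cols[week] = dataset.intensities[samp].median(axis=1)
    out = pd.DataFrame(cols, index=dataset.probe_ids)
    out.columns.name = "week"
    return out


def filter_low_expression(
    dataset: ExpressionDataset, config: PreprocessConfig | None = None
) -> FilterResult:
    """Remove probes whose weekly medians are all below the expression floor."""
    config = config or PreprocessConfig()
    medians = median_by_timepoint(dataset)
    below = (medians < config.expression_floor).all(axis=1)
    removed = dataset.probe_ids[below].tolist()
    kept = dataset.subset_probes(dataset.probe_ids[~below])
    return FilterResult(kept, removed, rule="below_floor")


def log2_ratio_profiles(
    medians: pd.DataFrame, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """log2(median_week / median_baseline) for every non-baseline week.

    ``medians`` is the output of :func:`median_by_timepoint`.  The baseline
    week is dropped from the result (its ratio is identically zero); pass
    the frame through :func:`with_baseline_zero` for plotting parity.
    """
    config = config or PreprocessConfig()
    if config.baseline_week not in medians.columns:
        raise InputFormatError(
            f"baseline week {config.baseline_week} missing from median table"
        )
    vals = medians.to_numpy(dtype=float)
    if (vals <= 0).any():
        probe = medians.index[(vals <= 0).any(axis=1)][0]
        raise NumericDomainError(
            f"non-positive median for probe {probe!r}: cannot take log2 ratio"
        )
    base = medians[config.baseline_week]
    other = [w for w in medians.columns if w != config.baseline_week]
    out = pd.DataFrame(
        {w: np.log2(medians[w] / base) for w in other}, index=medians.index
    )
    out.columns.name = "week"
    return out


def with_baseline_zero(
    profiles: pd.DataFrame, baseline_week: int = 1
) -> pd.DataFrame:
    """Prepend the identically-zero baseline column (plotting convenience)."""
    out = profiles.copy()
    out.insert(0, baseline_week, 0.0)
    return out
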