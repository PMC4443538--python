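"""Signed fold changes vs the week-1 baseline and their binning.

Ratios r_t = median_t / median_baseline are re-expressed as signed fold
changes (r for increases, -1/r for decreases, so |sFC| >= 1 always) and
binned into the four categories used for bar-chart style reporting:
up 1.5-2.0x, up >=2x, down 1.5-2.0x, down >=2x; anything below a 1.5-fold
change in either direction is "none".  Bins are half-open on |sFC|:
[1.5, 2.0) and [2.0, inf), so a probe exactly at 2-fold falls in the
>=2 bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputFormatError

BIN_LABELS = ("up_ge2", "up_1.5_2", "down_1.5_2", "down_ge2", "none")
UP_BINS = ("up_1.5_2", "up_ge2")
DOWN_BINS = ("down_1.5_2", "down_ge2")


@dataclass
class FoldChangeTable:
    """Per-probe, per-week ratios, signed fold changes and bin labels."""

    ratios: pd.DataFrame
    signed_fc: pd.DataFrame
    bins: pd.DataFrame  # same shape, values from BIN_LABELS

    @property
    def weeks(self) -> list[int]:
        return list(self.ratios.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.ratios.index


def compute_fold_changes(
    medians: pd.DataFrame, baseline_week: int = 1
) -> FoldChangeTable:
    """Ratios over baseline, signed fold changes, and bin labels.

    ``medians`` is a probe x week DataFrame of positive medians including
    the baseline week.
    """
    if baseline_week not in medians.columns:
        raise InputFormatError(f"baseline week {baseline_week} missing")
    if (medians.to_numpy(dtype=float) <= 0).any():
        raise InputFormatError("medians must be strictly positive")
    weeks = [w for w in medians.columns if w != baseline_week]
    ratios = medians[weeks].div(medians[baseline_week], axis=0)
    r = ratios.to_numpy(dtype=float)
    sfc = np.where(r >= 1.0, r, -1.0 / r)
    mag = np.abs(sfc)
    labels = np.full(r.shape, "none", dtype=object)
    up = sfc >= 1.0
    labels[up & (mag >= 2.0)] = "up_ge2"
    labels[up & (mag >= 1.5) & (mag < 2.0)] = "up_1.5_2"
    labels[~up & (mag >= 2.0)] = "down_ge2"
    labels[~up & (mag >= 1.5) & (mag < 2.0)] = "down_1.5_2"
    signed = pd.DataFrame(sfc, index=medians.index, columns=weeks)
    bins = pd.DataFrame(labels, index=medians.index, columns=weeks)
    return FoldChangeTable(ratios=ratios, signed_fc=signed, bins=bins)


@dataclass
class DirectionSummary:
    """Distinct-probe direction totals and per-week bin counts.

    A probe counts once per direction no matter how many weeks cross the
    1.5-fold threshold; probes crossing in both directions across weeks
    appear in both totals and are flagged in ``both_directions``.
    """

    bin_counts: pd.DataFrame  # bins x weeks
    up_probes: set = field(default_factory=set)
    down_probes: set = field(default_factory=set)
    up_probes_by_week: dict = field(default_factory=dict)
    down_probes_by_week: dict = field(default_factory=dict)

    @property
    def n_up(self) -> int:
        return len(self.up_probes)

    @property
    def n_down(self) -> int:
        return len(self.down_probes)

    @property
    def both_directions(self) -> set:
        return self.up_probes & self.down_probes

    def attribution_pct(self, direction: str, weeks) -> float | None:
        """Share of direction events attributable to the named weeks.

        100 x (distinct probes with the event at >= 1 named week) /
        (distinct probes with the event at any week), rounded to one
        decimal; ``None`` when no probe shows the event at all.
        """
        by_week = (
            self.up_probes_by_week if direction == "up" else self.down_probes_by_week
        )
        total = self.up_probes if direction == "up" else self.down_probes
        if not total:
            return None
        hit = set()
        for w in weeks:
            hit |= by_week.get(w, set())
        return round(100.0 * len(hit) / len(total), 1)

    def to_dict(self) -> dict:
        return {
            "bin_counts": {
                str(w): self.bin_counts[w].to_dict() for w in self.bin_counts.columns
            },
            "n_up_distinct": self.n_up,
            "n_down_distinct": self.n_down,
            "n_both_directions": len(self.both_directions),
        }


def summarize_directions(table: FoldChangeTable) -> DirectionSummary:
    """Per-week bin counts plus deduplicated direction totals."""
    weeks = table.weeks
    counts = pd.DataFrame(0, index=list(BIN_LABELS), columns=weeks)
    for w in weeks:
        vc = table.bins[w].value_counts()
        for label in BIN_LABELS:
            counts.loc[label, w] = int(vc.get(label, 0))
    up_by_week = {
        w: set(table.probe_ids[table.bins[w].isin(UP_BINS)]) for w in weeks
    }
    down_by_week = {
        w: set(table.probe_ids[table.bins[w].isin(DOWN_BINS)]) for w in weeks
    }
    up_all = set().union(*up_by_week.values()) if weeks else set()
    down_all = set().union(*down_by_week.values()) if weeks else set()
    return DirectionSummary(
        bin_counts=counts,
        up_probes=up_all,
        down_probes=down_all,
        up_probes_by_week=up_by_week,
        down_probes_by_week=down_by_week,
    )
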