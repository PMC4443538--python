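"""In-memory container for probe-level expression data with detection calls.

The pipeline consumes post-summarization array data: a positive intensity
matrix (probe sets x arrays) on a MAS5-like scale, an aligned matrix of
Present/Marginal/Absent detection calls, and per-array metadata (group,
week, replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputFormatError

VALID_CALLS = frozenset({"P", "M", "A"})
SAMPLE_FIELDS = ("group", "week", "replicate")


@dataclass
class ExpressionDataset:
    """Probe x sample intensities, aligned detection calls, sample metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by probe id, one column per sample id; strictly
        positive values on an arbitrary MAS5-like scale.
    calls
        DataFrame of the same shape holding detection calls "P"/"M"/"A".
    samples
        DataFrame indexed by sample id with columns ``group`` (str),
        ``week`` (int) and ``replicate`` (int).
    """

    intensities: pd.DataFrame
    calls: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.intensities.shape != self.calls.shape:
            raise InputFormatError(
                f"intensity matrix {self.intensities.shape} and call matrix "
                f"{self.calls.shape} have different shapes"
            )
        if not self.intensities.index.equals(self.calls.index) or not (
            self.intensities.columns.equals(self.calls.columns)
        ):
            raise InputFormatError("intensity and call matrices are not aligned")
        missing = [f for f in SAMPLE_FIELDS if f not in self.samples.columns]
        if missing:
            raise InputFormatError(f"sample table lacks columns {missing}")
        if not self.intensities.columns.equals(self.samples.index):
            raise InputFormatError("sample table does not match matrix columns")
        if (self.intensities.to_numpy() <= 0).any():
            bad = (self.intensities <= 0).any(axis=1)
            probe = bad[bad].index[0]
            raise InputFormatError(f"non-positive intensity for probe {probe!r}")
        call_values = self.calls.to_numpy()
        ok = pd.DataFrame(call_values).isin(VALID_CALLS).to_numpy()
        if not ok.all():
            rows, cols = (~ok).nonzero()
            r, c = int(rows[0]), int(cols[0])
            raise InputFormatError(
                f"unknown detection call {call_values[r, c]!r} for probe "
                f"{self.calls.index[r]!r} in sample {self.calls.columns[c]!r}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_probes(self) -> int:
        return len(self.intensities.index)

    @property
    def weeks(self) -> list[int]:
        return sorted(self.samples["week"].unique().tolist())

    @property
    def groups(self) -> list[str]:
        return sorted(self.samples["group"].unique().tolist())

    def for_group(self, group: str) -> "ExpressionDataset":
        """Restrict to the arrays of a single experimental group."""
        mask = self.samples["group"] == group
        if not mask.any():
            raise InputFormatError(f"group {group!r} absent from dataset")
        cols = self.samples.index[mask]
        return ExpressionDataset(
            self.intensities[cols], self.calls[cols], self.samples.loc[cols]
        )

    def subset_probes(self, probes) -> "ExpressionDataset":
        idx = pd.Index(probes)
        return ExpressionDataset(
            self.intensities.loc[idx], self.calls.loc[idx], self.samples
        )
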