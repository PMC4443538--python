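"""File dialects: expression TSV, profile tables, partitions, reports.

The expression dialect is a single TSV holding both matrices: row 1 is
``probe_id`` plus sample ids, rows 2-4 carry the sample metadata
(``group``, ``week``, ``replicate``), and each data cell packs intensity
and detection call as ``"<intensity>:<call>"`` (e.g. ``153.2:P``).
Intensities are written with ``repr`` so a read of a write reproduces
the dataset exactly.
"""

from __future__ import annotations

import pandas as pd

from .dataset import ExpressionDataset
from .errors import InputFormatError


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    samples = dataset.samples
    with open(path, "w") as fh:
        cols = list(dataset.intensities.columns)
        fh.write("\t".join(["probe_id", *cols]) + "\n")
        for meta in ("group", "week", "replicate"):
            fh.write(
                "\t".join([meta, *(str(samples.loc[c, meta]) for c in cols)]) + "\n"
            )
        intens = dataset.intensities.to_numpy()
        calls = dataset.calls.to_numpy()
        for r, probe in enumerate(dataset.probe_ids):
            cells = [
                f"{float(intens[r, c])!r}:{calls[r, c]}" for c in range(len(cols))
            ]
            fh.write("\t".join([str(probe), *cells]) + "\n")


def read_expression_tsv(path) -> ExpressionDataset:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "probe_id":
            raise InputFormatError(f"{path}:1: first header cell must be 'probe_id'")
        cols = header[1:]
        meta = {}
        for ln, name in ((2, "group"), (3, "week"), (4, "replicate")):
            parts = fh.readline().rstrip("\n").split("\t")
            if not parts or parts[0] != name:
                raise InputFormatError(f"{path}:{ln}: expected metadata row {name!r}")
            if len(parts) - 1 != len(cols):
                raise InputFormatError(
                    f"{path}:{ln}: {len(parts) - 1} values for {len(cols)} samples"
                )
            meta[name] = parts[1:]
        probes, ivals, cvals = [], [], []
        for ln, line in enumerate(fh, start=5):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) - 1 != len(cols):
                raise InputFormatError(
                    f"{path}:{ln}: {len(parts) - 1} cells for {len(cols)} samples"
                )
            probes.append(parts[0])
            irow, crow = [], []
            for ci, cell in enumerate(parts[1:], start=2):
                try:
                    val, call = cell.rsplit(":", 1)
                    irow.append(float(val))
                except ValueError:
                    raise InputFormatError(
                        f"{path}:{ln}: column {ci}: malformed cell {cell!r}"
                    ) from None
                crow.append(call)
            ivals.append(irow)
            cvals.append(crow)
    idx = pd.Index(probes, name="probe_id")
    intensities = pd.DataFrame(ivals, index=idx, columns=cols)
    calls = pd.DataFrame(cvals, index=idx, columns=cols, dtype=object)
    samples = pd.DataFrame(
        {
            "group": meta["group"],
            "week": [int(w) for w in meta["week"]],
            "replicate": [int(r) for r in meta["replicate"]],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionDataset(intensities, calls, samples)


def write_profile_tsv(profiles: pd.DataFrame, path) -> None:
    """Write a probe x week table (medians, ratios...) as TSV."""
    out = profiles.copy()
    out.columns = [f"week_{w}" for w in out.columns]
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_profile_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="probe_id")
    frame.columns = [int(str(c).removeprefix("week_")) for c in frame.columns]
    frame.columns.name = "week"
    return frame


def write_partition_tsv(partition, path) -> None:
    partition.labels().rename_axis("probe_id").to_frame().to_csv(path, sep="\t")


def write_cluster_summary_tsv(partition, path) -> None:
    partition.summary().to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(results, path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "term": r.term,
                "p_value": r.p_value,
                "ease_p": r.ease_p,
                "q_value": r.q_value,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "modal_cluster": r.modal_cluster,
                "modal_pct": r.modal_pct,
                "clusters": ";".join(
                    f"{c}({m})" for c, m in r.cluster_breakdown.items()
                ),
                "genes": ";".join(r.overlap),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
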