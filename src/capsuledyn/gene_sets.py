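"""Sham vs immobilized membership comparison and probe-to-gene collapse.

The probes belonging to selected clusters in each series are compared by
exact set operations: probes selected in both series reflect a response
to surgery/time shared by the groups, while the immobilization-only
difference set carries the contracture-specific signal.  Probe sets are
collapsed to gene symbols through a many-probes-to-one-gene map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, InputFormatError

log = logging.getLogger(__name__)


@dataclass
class ProbeGeneMap:
    """Probe id -> gene symbol mapping (many probes may share a gene)."""

    mapping: dict

    def __post_init__(self) -> None:
        if any(not g for g in self.mapping.values()):
            raise InputFormatError("empty gene symbol in probe-gene map")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, strict: bool = True) -> "ProbeGeneMap":
        """Build from a two-column (probe_id, gene_symbol) table.

        In the strict dialect a probe listed twice is an error; with
        ``strict=False`` the first listed gene wins.
        """
        cols = list(frame.columns[:2])
        probes = frame[cols[0]].astype(str)
        if probes.duplicated().any():
            dup = probes[probes.duplicated()].iloc[0]
            if strict:
                raise InputFormatError(
                    f"probe {dup!r} mapped to multiple genes (strict dialect)"
                )
            frame = frame.drop_duplicates(subset=cols[0], keep="first")
        return cls(dict(zip(frame[cols[0]].astype(str), frame[cols[1]].astype(str))))

    @classmethod
    def from_tsv(cls, path, strict: bool = True) -> "ProbeGeneMap":
        frame = pd.read_csv(path, sep="\t")
        if frame.shape[1] < 2:
            raise InputFormatError(f"{path}: probe-gene map needs two columns")
        return cls.from_frame(frame, strict=strict)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"probe_id": list(self.mapping), "gene_symbol": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)

    def genes_for(self, probes) -> set:
        return {self.mapping[p] for p in probes if p in self.mapping}

    def probes_for_gene(self) -> dict:
        """Inverse map: gene symbol -> set of probe ids."""
        inv: dict = {}
        for p, g in self.mapping.items():
            inv.setdefault(g, set()).add(p)
        return inv


def collapse_to_genes(probes, mapping: ProbeGeneMap) -> set:
    """Distinct gene symbols of the mapped probes.

    Unmapped probes are excluded with a warning rather than failing the
    run; an empty map is a configuration error.
    """
    if not mapping.mapping:
        raise ConfigurationError("probe-gene map is empty")
    probes = set(probes)
    unmapped = sorted(p for p in probes if p not in mapping.mapping)
    if unmapped:
        log.warning(
            "%d probes without gene annotation excluded from collapse (e.g. %s)",
            len(unmapped), unmapped[0],
        )
    return mapping.genes_for(probes)


@dataclass
class GroupComparison:
    """Probe- and gene-level overlap between the two series' selections.

    The gene-level immobilization-only set is the set difference of the
    *collapsed* gene sets (not the collapse of the probe difference): a
    gene with one shared probe and one immobilized-only probe responds in
    both series and is not immobilization-specific.
    """

    sham_probes: set
    immobilized_probes: set
    common_probes: set
    immobilized_only_probes: set
    sham_genes: set | None = None
    immobilized_genes: set | None = None
    common_genes: set | None = None
    immobilized_only_genes: set | None = None

    def counts(self) -> dict:
        out = {
            "sham_probes": len(self.sham_probes),
            "immobilized_probes": len(self.immobilized_probes),
            "common_probes": len(self.common_probes),
            "immobilized_only_probes": len(self.immobilized_only_probes),
        }
        if self.immobilized_genes is not None:
            out.update(
                sham_genes=len(self.sham_genes or set()),
                immobilized_genes=len(self.immobilized_genes),
                common_genes=len(self.common_genes or set()),
                immobilized_only_genes=len(self.immobilized_only_genes or set()),
            )
        return out


def compare_groups(
    sham_selected, imm_selected, mapping: ProbeGeneMap | None = None
) -> GroupComparison:
    """Exact intersection/difference of the two selected probe sets.

    When a probe-gene map is supplied the gene-level counterparts are
    filled in as well.
    """
    sham = set(sham_selected)
    imm = set(imm_selected)
    comp = GroupComparison(
        sham_probes=sham,
        immobilized_probes=imm,
        common_probes=sham & imm,
        immobilized_only_probes=imm - sham,
    )
    if mapping is not None:
        comp.sham_genes = collapse_to_genes(sham, mapping)
        comp.immobilized_genes = collapse_to_genes(imm, mapping)
        comp.common_genes = comp.sham_genes & comp.immobilized_genes
        comp.immobilized_only_genes = comp.immobilized_genes - comp.sham_genes
    return comp
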