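"""Orchestration of the full two-series workflow.

Each group (sham-operated, immobilized) is processed as an independent
series: absent filter -> floor filter -> weekly medians -> log2 ratios
-> fold-change summary -> inclusion filter -> Bayes-factor agglomeration
-> centers, selection, trends.  The two series meet only at the
cross-group comparison, after which the immobilization-only gene list is
tested for gene-set over-representation and cross-tabulated against the
immobilized clustering.  IHC scoring runs independently when a counts
table is supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .cluster import (
    ClusterModelConfig,
    agglomerate,
    classify_trends,
    inclusion_filter,
    select_clusters,
)
from .enrichment import GeneSetCollection, crosstab_clusters, hypergeometric_enrichment
from .errors import ConfigurationError
from .foldchange import compute_fold_changes, summarize_directions
from .gene_sets import ProbeGeneMap, compare_groups
from .ihc import kruskal_wallis_by_week, read_ihc_csv, results_frame, score_fields
from .preprocess import (
    PreprocessConfig,
    filter_absent,
    filter_low_expression,
    log2_ratio_profiles,
    median_by_timepoint,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for a full run."""

    expression_path: str = ""
    probe_gene_map_path: str | None = None
    gmt_paths: list = field(default_factory=list)
    ihc_path: str | None = None
    output_dir: str = "capsuledyn_out"
    groups: tuple = ("sham", "immobilized")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterModelConfig = field(default_factory=ClusterModelConfig)
    selection_threshold: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        clu = ClusterModelConfig(**raw.pop("cluster", {}))
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(preprocess=pre, cluster=clu, **raw)

    def check_paths(self) -> None:
        for p in [self.expression_path, self.probe_gene_map_path,
                  self.ihc_path, *self.gmt_paths]:
            if p and not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")


def process_group(dataset, config: PipelineConfig, outdir: Path, group: str) -> dict:
    """Run one series through filters, profiles, fold changes and clustering."""
    ds = dataset.for_group(group)
    n0 = ds.n_probes
    absent = filter_absent(ds, config.preprocess)
    floor = filter_low_expression(absent.dataset, config.preprocess)
    retained = floor.dataset
    medians = median_by_timepoint(retained)
    profiles = log2_ratio_profiles(medians, config.preprocess)

    fc = compute_fold_changes(medians, config.preprocess.baseline_week)
    directions = summarize_directions(fc)

    included = inclusion_filter(profiles, config.cluster)
    partition = agglomerate(included, config.cluster)
    partition = select_clusters(partition, config.selection_threshold)
    partition = classify_trends(
        partition, config.cluster.trend_tolerance, config.selection_threshold
    )

    gdir = outdir / group
    gdir.mkdir(parents=True, exist_ok=True)
    cio.write_profile_tsv(medians, gdir / "medians.tsv")
    cio.write_profile_tsv(profiles, gdir / "log2_ratios.tsv")
    fc.bins.to_csv(gdir / "foldchange_bins.tsv", sep="\t")
    with open(gdir / "direction_summary.json", "w") as fh:
        json.dump(directions.to_dict(), fh, indent=2, sort_keys=True)
    cio.write_partition_tsv(partition, gdir / "partition.tsv")
    cio.write_cluster_summary_tsv(partition, gdir / "clusters.tsv")

    counts = {
        "initial_probes": n0,
        "all_absent": absent.n_removed,
        "after_absent_filter": absent.dataset.n_probes,
        "below_floor": floor.n_removed,
        "retained": retained.n_probes,
        "profiles_clustered": int(included.shape[0]),
        "n_clusters": partition.n_clusters,
        "n_selected_clusters": sum(bool(c.selected) for c in partition.clusters),
        "selected_probes": len(partition.selected_probes()),
    }
    assert counts["initial_probes"] == (
        counts["all_absent"] + counts["below_floor"] + counts["retained"]
    ), "filter bookkeeping violated"
    for key, value in counts.items():
        log.info("%s: %s = %s", group, key, value)
    return {
        "counts": counts,
        "partition": partition,
        "directions": directions,
        "medians": medians,
        "profiles": profiles,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    config.check_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = cio.read_expression_tsv(config.expression_path)

    manifest: dict = {
        "config": _config_echo(config),
        "groups": {},
    }
    stage = {}
    for group in config.groups:
        stage[group] = process_group(dataset, config, outdir, group)
        manifest["groups"][group] = stage[group]["counts"]

    mapping = (
        ProbeGeneMap.from_tsv(config.probe_gene_map_path)
        if config.probe_gene_map_path
        else None
    )
    sham_group, imm_group = config.groups
    comparison = compare_groups(
        stage[sham_group]["partition"].selected_probes(),
        stage[imm_group]["partition"].selected_probes(),
        mapping,
    )
    manifest["comparison"] = comparison.counts()
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(comparison.counts(), fh, indent=2, sort_keys=True)

    if mapping is not None and config.gmt_paths:
        background = sorted(
            mapping.genes_for(stage[imm_group]["medians"].index)
        )
        query = sorted(comparison.immobilized_only_genes or set())
        enrichment_counts = {}
        for gmt in config.gmt_paths:
            collection = GeneSetCollection.from_gmt(gmt)
            results = hypergeometric_enrichment(query, background, collection)
            results = crosstab_clusters(
                results, stage[imm_group]["partition"], mapping
            )
            name = Path(gmt).stem
            cio.write_enrichment_tsv(results, outdir / f"enrichment_{name}.tsv")
            enrichment_counts[name] = {
                "n_terms": len(results),
                "n_significant_raw": sum(r.p_value < 0.05 for r in results),
                "top_term": results[0].term if results else None,
                "top_p": results[0].p_value if results else None,
            }
        manifest["enrichment"] = enrichment_counts

    if config.ihc_path:
        table = read_ihc_csv(config.ihc_path)
        scores = score_fields(table)
        tests = kruskal_wallis_by_week(scores)
        results_frame(tests).to_csv(outdir / "ihc_stats.tsv", sep="\t", index=False)
        manifest["ihc"] = {
            "n_weeks_tested": len(tests),
            "n_significant": sum(t.significant for t in tests),
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    echo["groups"] = list(config.groups)
    return echo


def plot_cluster_centers(partition, path, selected_only: bool = True) -> None:
    """Line plot of cluster-center trajectories (log2 ratio vs week)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cl in partition.clusters:
        if selected_only and not cl.selected:
            continue
        weeks = list(cl.center.index)
        ax.plot([0, *weeks], [0.0, *cl.center.values], marker="o",
                label=f"cluster {cl.cluster_id} (n={cl.size})")
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("week")
    ax.set_ylabel("log2 ratio vs week 1")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
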