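import numpy as np
import pandas as pd
import pytest

from capsuledyn import (
    ConfigurationError,
    GeneSetCollection,
    ProbeGeneMap,
    crosstab_clusters,
    hypergeometric_enrichment,
)
from capsuledyn.cluster import Cluster, Partition
from helpers import brute_force_upper_tail

GENES = [f"g{i:03d}" for i in range(20)]


def one_term(genes):
    return GeneSetCollection({"TERM": set(genes)}, source="test")


class TestHypergeometric:
    def test_tail_matches_enumeration_small_case(self):
        # N=12 keeps enumeration instant; the N=20 case runs in the
        # acceptance suite.
        background = GENES[:12]
        query = GENES[:4]
        collection = one_term(GENES[2:7])  # K=5, overlap k=2
        res = hypergeometric_enrichment(query, background, collection)[0]
        assert res.k == 2 and res.K == 5 and res.n == 4 and res.N == 12
        expected = brute_force_upper_tail(12, 5, 4, 2)
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_full_overlap_degenerate_case(self):
        res = hypergeometric_enrichment(GENES[:5], GENES[:5], one_term(GENES[:5]))[0]
        assert res.p_value == pytest.approx(1.0)

    def test_ease_boundary_single_gene_overlap(self):
        background = GENES
        query = GENES[:1]
        res = hypergeometric_enrichment(query, background, one_term(GENES[:1]))[0]
        assert res.k == 1
        assert res.ease_p == pytest.approx(1.0)

    def test_ease_always_at_least_plain_p(self):
        rng = np.random.default_rng(0)
        sets = {
            f"T{i}": {GENES[j] for j in rng.choice(20, size=rng.integers(2, 10),
                                                   replace=False)}
            for i in range(25)
        }
        results = hypergeometric_enrichment(
            GENES[:8], GENES, GeneSetCollection(sets)
        )
        assert all(r.ease_p >= r.p_value - 1e-15 for r in results)

    def test_label_invariance(self):
        relabel = {g: f"X_{g}" for g in GENES}
        res1 = hypergeometric_enrichment(GENES[:6], GENES, one_term(GENES[3:9]))[0]
        res2 = hypergeometric_enrichment(
            [relabel[g] for g in GENES[:6]],
            [relabel[g] for g in GENES],
            one_term([relabel[g] for g in GENES[3:9]]),
        )[0]
        assert res1.p_value == res2.p_value and res1.k == res2.k

    def test_query_outside_background_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = hypergeometric_enrichment(
                GENES[:3] + ["alien"], GENES, one_term(GENES[:5])
            )[0]
        assert res.n == 3
        assert "outside the background" in caplog.text

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigurationError):
            hypergeometric_enrichment(GENES[:2], [], one_term(GENES[:2]))


def partition_for(probe_clusters):
    clusters = {}
    for probe, cid in probe_clusters.items():
        clusters.setdefault(cid, []).append(probe)
    return Partition(
        clusters=[
            Cluster(cid, tuple(sorted(members)),
                    pd.Series(dtype=float), logml=0.0)
            for cid, members in sorted(clusters.items())
        ],
        score=0.0,
    )


class TestCrosstab:
    def test_breakdown_by_probe_cluster(self):
        mapping = ProbeGeneMap({"pr1": "g1", "pr2": "g2"})
        partition = partition_for({"pr1": 4, "pr2": 1})
        res = hypergeometric_enrichment(
            ["g1", "g2"], ["g1", "g2", "g3", "g4"], one_term(["g1", "g2"])
        )
        res = crosstab_clusters(res, partition, mapping)[0]
        assert res.cluster_breakdown == {1: 1, 4: 1}

    def test_gene_spanning_clusters_counts_in_each(self):
        mapping = ProbeGeneMap({"pa": "g1", "pb": "g1"})
        partition = partition_for({"pa": 1, "pb": 2})
        res = hypergeometric_enrichment(["g1"], ["g1", "g2"], one_term(["g1"]))
        res = crosstab_clusters(res, partition, mapping)[0]
        assert res.cluster_breakdown == {1: 1, 2: 1}

    def test_empty_overlap_empty_breakdown(self):
        mapping = ProbeGeneMap({"pr1": "g1"})
        partition = partition_for({"pr1": 1})
        res = hypergeometric_enrichment(["g9"], ["g1", "g9"], one_term(["g1"]))
        res = crosstab_clusters(res, partition, mapping)[0]
        assert res.cluster_breakdown == {} and res.modal_pct is None


class TestGmtRoundTrip:
    def test_write_read_identity(self, tmp_path):
        coll = GeneSetCollection(
            {"T1": {"a", "b"}, "T2": {"c", "d", "e"}}, source="src"
        )
        path = tmp_path / "sets.gmt"
        coll.to_gmt(path)
        back = GeneSetCollection.from_gmt(path)
        assert back.sets == coll.sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("TERM_ONLY\tdesc\n")
        from capsuledyn import InputFormatError

        with pytest.raises(InputFormatError, match="bad.gmt:1"):
            GeneSetCollection.from_gmt(path)
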