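"""Chromosome counts, density, cluster detection (with brute-force
oracle) and cross-genome cluster comparison."""

import numpy as np
import pytest

from wrkyscan.distribution import (GeneCluster, chromosome_counts,
                                   compare_clusters, density,
                                   detect_clusters, tandem_members)
from wrkyscan.genome_io import GeneModel, Genome


def _gene(gid, chrom, start, end=None, strand="+"):
    end = end if end is not None else start + 2000
    return GeneModel(gid, chrom, strand, (start, end), transcripts=[])


def brute_force_clusters(genes, max_span, min_genes):
    """Oracle: enumerate all contiguous windows, keep qualifying ones,
    drop any window contained in another qualifying window."""
    out = []
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.span[0], g.gene_id))
        n = len(gs)
        qual = []
        for i in range(n):
            for j in range(i + min_genes - 1, n):
                extent = max(g.span[1] for g in gs[i:j + 1]) - gs[i].span[0]
                if extent <= max_span:
                    qual.append((i, j))
        maximal = [
            (i, j) for (i, j) in qual
            if not any((a <= i and j <= b and (a, b) != (i, j))
                       for (a, b) in qual)
        ]
        for i, j in sorted(maximal):
            out.append((chrom, tuple(g.gene_id for g in gs[i:j + 1])))
    return out


class TestCounts:
    def test_counts_with_zero_chromosome(self):
        genes = [_gene("a", "chr1", 100), _gene("b", "chr1", 9000),
                 _gene("c", "chr1", 20000), _gene("d", "chr2", 100)]
        genome = Genome(records={"chr1": "A" * 30000, "chr2": "A" * 9000,
                                 "chr3": "A" * 5000})
        counts = chromosome_counts(genes, genome)
        assert counts == {"chr1": 3, "chr2": 1, "chr3": 0}

    def test_density(self):
        assert density({"c": 10}, {"c": 10_000_000}) == {"c": 1.0}
        assert density({"c": 0}, {"c": 1_000_000}) == {"c": 0.0}
        assert density({"c": 23}, {"c": 46_000_000}) == {"c": 0.5}

    def test_density_missing_length(self):
        with pytest.raises(ValueError):
            density({"c": 1}, {})


class TestDetectClusters:
    def test_four_gene_cluster(self):
        genes = [_gene(f"g{i}", "c", p, p) for i, p in enumerate(
            [450_000, 460_000, 470_000, 480_000, 2_000_000])]
        (cl,) = detect_clusters(genes)
        assert cl.members == ["g0", "g1", "g2", "g3"]
        assert cl.span_length == 30_000

    def test_three_genes_below_min(self):
        genes = [_gene(f"g{i}", "c", 100_000 + i * 5000, 100_000 + i * 5000)
                 for i in range(3)]
        assert detect_clusters(genes) == []

    def test_prefix_cluster_of_spread_run(self):
        # 5 genes over 550 kb whose 4-gene prefix spans 300 kb; the
        # 4-gene suffix spans 450 kb and must not qualify
        pos = [0, 100_000, 200_000, 300_000, 550_000]
        genes = [_gene(f"g{i}", "c", p, p) for i, p in enumerate(pos)]
        (cl,) = detect_clusters(genes)
        assert cl.members == ["g0", "g1", "g2", "g3"]

    def test_translation_invariance(self, rng):
        pos = sorted(int(p) for p in rng.integers(0, 2_000_000, 30))
        genes = [_gene(f"g{i:02d}", "c", p, p + 1000)
                 for i, p in enumerate(pos)]
        shifted = [_gene(f"g{i:02d}", "c", p + 12_345, p + 13_345)
                   for i, p in enumerate(pos)]
        a = [c.members for c in detect_clusters(genes)]
        b = [c.members for c in detect_clusters(shifted)]
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_bruteforce_oracle_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            pos = sorted(int(p) for p in rng.integers(0, 3_000_000, n))
            genes = [_gene(f"g{i:02d}", "c", p, p + int(rng.integers(1, 5000)))
                     for i, p in enumerate(pos)]
            max_span = int(rng.choice([50_000, 200_000, 400_000]))
            min_genes = int(rng.choice([2, 3, 4]))
            got = [(c.chrom, tuple(c.members))
                   for c in detect_clusters(genes, max_span, min_genes)]
            assert got == brute_force_clusters(genes, max_span, min_genes)

    def test_composition_and_tandem(self):
        genes = [_gene(f"g{i}", "c", 1000 * i, 1000 * i) for i in range(4)]
        labels = {"g0": "III", "g1": "III", "g2": "IIc", "g3": "III"}
        (cl,) = detect_clusters(genes, 400_000, 4, labels)
        assert cl.composition == {"III": 3, "IIc": 1}
        assert tandem_members(cl, labels) == ["g0", "g1", "g3"]


class TestCompareClusters:
    """Cross-genome comparison on printed cluster orders."""

    def _cluster(self, chrom, members):
        return GeneCluster(chrom=chrom, members=list(members),
                           span=(1, 2), span_length=1)

    def test_identical_order(self):
        names = ["w22", "w116", "w20", "w108", "w21", "w24"]
        omap = {x: x for x in names}
        (c,) = compare_clusters([self._cluster("a1", names)],
                                [self._cluster("b1", names)], omap)
        assert c.order_identical and not c.a_only and not c.b_only
        assert c.shared == names

    def test_missing_members_listed(self):
        a = ["w52", "w46", "w95", "w64", "w50"]
        b = ["w52", "w46", "w50"]
        omap = {x: x for x in a}
        (c,) = compare_clusters([self._cluster("a", a)],
                                [self._cluster("b", b)], omap)
        assert c.a_only == ["w95", "w64"] and c.b_only == []

    def test_scrambled_order_detected(self):
        a = ["w1", "w2", "w3", "w4"]
        b = ["w1", "w3", "w2", "w4"]
        omap = {x: x for x in a}
        (c,) = compare_clusters([self._cluster("a", a)],
                                [self._cluster("b", b)], omap)
        assert not c.order_identical

    def test_whole_cluster_reversal_absorbed(self):
        a = ["w1", "w2", "w3", "w4"]
        omap = {x: x for x in a}
        (c,) = compare_clusters([self._cluster("a", a)],
                                [self._cluster("b", a[::-1])], omap)
        assert c.order_identical

    def test_ambiguous_many_to_many_flagged(self):
        a = [self._cluster("a1", ["w1", "w2", "w3"])]
        b = [self._cluster("b1", ["w1", "w2"]),
             self._cluster("b2", ["w2", "w3"])]
        omap = {x: x for x in ["w1", "w2", "w3"]}
        comps = compare_clusters(a, b, omap)
        assert len(comps) == 2 and all(c.ambiguous for c in comps)

    def test_below_min_shared_not_matched(self):
        a = [self._cluster("a1", ["w1", "w9"])]
        b = [self._cluster("b1", ["w1", "w5"])]
        omap = {x: x for x in ["w1", "w5", "w9"]}
        assert compare_clusters(a, b, omap) == []
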