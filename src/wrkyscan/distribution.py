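"""Chromosomal distribution, tandem-duplication clusters, and cross-genome
cluster comparison.

A cluster is a maximal run of consecutive family genes on one chromosome
whose first-to-last span stays within ``max_span`` (default 400 kb) and
which contains at least ``min_genes`` members (default 4) - the classic
tandem-duplication signature. Cross-genome comparison matches clusters by
shared orthologue names and checks whether the shared genes appear in the
same relative order (whole-cluster reversal is absorbed, since assembly
orientation is arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GeneModel, Genome

DEFAULT_MAX_SPAN = 400_000
DEFAULT_MIN_GENES = 4


@dataclass
class GeneCluster:
    chrom: str
    members: list[str]  # gene ids, ordered by position
    span: tuple[int, int]  # genomic start of first gene, end of last gene
    span_length: int  # bp distance, end - start
    composition: dict[str, int] = field(default_factory=dict)

    def to_bed_row(self) -> str:
        name = ",".join(self.members)
        return f"{self.chrom}\t{self.span[0] - 1}\t{self.span[1]}\t{name}"


@dataclass
class ClusterComparison:
    cluster_a: GeneCluster
    cluster_b: GeneCluster
    shared: list[str]  # orthologue names, in cluster-A order
    order_identical: bool
    a_only: list[str]
    b_only: list[str]
    ambiguous: bool = False


def chromosome_counts(
    genes: list[GeneModel], genome: Genome | None = None
) -> dict[str, int]:
    """Family-gene count per chromosome; genome chromosomes with zero
    family genes are listed explicitly."""
    counts: dict[str, int] = {}
    if genome is not None:
        counts = {chrom: 0 for chrom in genome.records}
    for g in genes:
        counts[g.chrom] = counts.get(g.chrom, 0) + 1
    return counts


def density(counts: dict[str, int], lengths: dict[str, int]) -> dict[str, float]:
    """Genes per Mbp, per chromosome."""
    out = {}
    for chrom, n in counts.items():
        if chrom not in lengths:
            raise ValueError(f"no length for chromosome {chrom!r}")
        if lengths[chrom] <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        out[chrom] = n / (lengths[chrom] / 1e6)
    return out


def detect_clusters(
    genes: list[GeneModel],
    max_span: int = DEFAULT_MAX_SPAN,
    min_genes: int = DEFAULT_MIN_GENES,
    labels: dict[str, str] | None = None,
) -> list[GeneCluster]:
    """Maximal qualifying runs of consecutive family genes.

    Genes may come from several chromosomes; each chromosome is processed
    independently with genes ordered by start. A window qualifies when its
    genomic extent (start of its first member to the rightmost member
    end, as a bp distance) is <= ``max_span`` and it holds >=
    ``min_genes`` genes; only windows
    not contained in a larger qualifying window are reported, so every
    maximal run appears exactly once.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.span[0], g.gene_id))
        n = len(gs)
        j_prev = -1
        for i in range(n):
            j = i
            max_end = gs[i].span[1]
            while (j + 1 < n
                   and max(max_end, gs[j + 1].span[1]) - gs[i].span[0]
                   <= max_span):
                j += 1
                max_end = max(max_end, gs[j].span[1])
            if j - i + 1 >= min_genes and j > j_prev:
                members = gs[i : j + 1]
                comp: dict[str, int] = {}
                if labels is not None:
                    for m in members:
                        lab = labels.get(m.gene_id, "?")
                        comp[lab] = comp.get(lab, 0) + 1
                clusters.append(GeneCluster(
                    chrom=chrom,
                    members=[m.gene_id for m in members],
                    span=(members[0].span[0], max_end),
                    span_length=max_end - members[0].span[0],
                    composition=comp,
                ))
            j_prev = max(j_prev, j)
    return clusters


def tandem_members(cluster: GeneCluster, labels: dict[str, str]) -> list[str]:
    """Cluster members sharing their group label with >=1 other member -
    the genes counted as tandem duplicates."""
    from collections import Counter

    tally = Counter(labels.get(g, "?") for g in cluster.members)
    return [g for g in cluster.members if tally[labels.get(g, "?")] >= 2]


def compare_clusters(
    clusters_a: list[GeneCluster],
    clusters_b: list[GeneCluster],
    ortho_map: dict[str, str],
    min_shared: int = 2,
) -> list[ClusterComparison]:
    """Match clusters across genomes by shared orthologue names.

    Many-to-many matches are all reported and flagged ambiguous rather
    than resolved. Order identity tolerates a whole-cluster reversal.
    """
    comparisons: list[ClusterComparison] = []
    for ca in clusters_a:
        names_a = [ortho_map[g] for g in ca.members if g in ortho_map]
        for cb in clusters_b:
            names_b = [ortho_map[g] for g in cb.members if g in ortho_map]
            shared = set(names_a) & set(names_b)
            if len(shared) < min_shared:
                continue
            sa = [x for x in names_a if x in shared]
            sb = [x for x in names_b if x in shared]
            comparisons.append(ClusterComparison(
                cluster_a=ca,
                cluster_b=cb,
                shared=sa,
                order_identical=(sa == sb or sa == sb[::-1]),
                a_only=[x for x in names_a if x not in shared],
                b_only=[x for x in names_b if x not in shared],
            ))
    from collections import Counter

    seen_a = Counter(id(c.cluster_a) for c in comparisons)
    seen_b = Counter(id(c.cluster_b) for c in comparisons)
    for c in comparisons:
        if seen_a[id(c.cluster_a)] > 1 or seen_b[id(c.cluster_b)] > 1:
            c.ambiguous = True
    return comparisons


def write_clusters_bed(clusters: list[GeneCluster], path: str) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(c.to_bed_row() + "\n")
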