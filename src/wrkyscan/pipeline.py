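"""End-to-end orchestration: run every analysis stage on one dataset and
evaluate planted-truth recovery on synthetic cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import (classify, distribution, domain_scan, expression,
               gene_structure, genome_io, phospho_motifs, phylo,
               promoter_cis)


@dataclass
class PipelineParams:
    promoter_len: int = 1500
    linkage_window: int = domain_scan.DEFAULT_LINKAGE_WINDOW
    variant_table: tuple[str, ...] = domain_scan.DEFAULT_VARIANT_TABLE
    fuzzy_budget: int = 1
    cluster_max_span: int = distribution.DEFAULT_MAX_SPAN
    cluster_min_genes: int = distribution.DEFAULT_MIN_GENES
    expression_threshold: float = expression.DEFAULT_THRESHOLD
    bootstrap_B: int = 0  # 0 = plain NJ tree without supports
    seed: int = 0


@dataclass
class PipelineResults:
    domains: dict[str, list[domain_scan.WRKYDomain]] = field(
        default_factory=dict)
    assignments: dict[str, classify.GroupAssignment] = field(
        default_factory=dict)
    tallies: dict[str, int] = field(default_factory=dict)
    introns: dict[str, list[gene_structure.IntronRecord]] = field(
        default_factory=dict)
    exon_counts: dict[str, int] = field(default_factory=dict)
    phospho_table: pd.DataFrame | None = None
    phospho_summary: dict = field(default_factory=dict)
    promoter_hits: dict[str, list[promoter_cis.CisElementHit]] = field(
        default_factory=dict)
    promoter_categories: dict[str, promoter_cis.PromoterCategory] = field(
        default_factory=dict)
    promoter_summary: dict = field(default_factory=dict)
    chrom_counts: dict[str, int] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)
    clusters: list[distribution.GeneCluster] = field(default_factory=list)
    expression_summary: dict = field(default_factory=dict)
    peaks: pd.DataFrame | None = None
    tree: object = None
    supports: dict = field(default_factory=dict)
    clade_report: dict = field(default_factory=dict)


def run_pipeline(
    genome: genome_io.Genome | None,
    genes: list[genome_io.GeneModel],
    proteins: dict[str, str],
    expr: pd.DataFrame | None = None,
    alignment: phylo.Alignment | None = None,
    alignment_labels: dict[str, str] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResults:
    """Run every applicable stage; stages without inputs are skipped."""
    if params is None:
        params = PipelineParams()
    res = PipelineResults()
    rules = classify.ClassifierRules(max_mismatches=params.fuzzy_budget)

    # 1-2: domain scan + classification on the selected isoform per locus
    chosen: dict[str, str] = {}  # gene id -> protein key
    for g in genes:
        keyed = {
            t.transcript_id: proteins[t.protein_id or t.transcript_id]
            for t in g.transcripts
            if (t.protein_id or t.transcript_id) in proteins
        }
        if not keyed:
            continue
        pid = classify.select_isoform(g, keyed)
        chosen[g.gene_id] = pid
    targets = chosen or {pid: pid for pid in proteins}
    for gid in sorted(targets):
        pid = targets[gid]
        domains = domain_scan.scan_domains(
            proteins[pid], pid,
            variant_table=params.variant_table,
            linkage_window=params.linkage_window,
        )
        res.domains[gid] = domains
        if domains:
            res.assignments[gid] = classify.classify_protein(
                domains, rules, gene_id=gid)
    res.tallies = classify.tally_groups(list(res.assignments.values()))
    labels = {gid: a.label for gid, a in res.assignments.items()}

    # 3: gene structure
    if genome is not None:
        for g in genes:
            t = g.transcripts[0]
            prot = proteins.get(targets.get(g.gene_id, ""), None)
            if prot is None:
                prot = genome_io.extract_protein(t, genome).seq
            res.exon_counts[g.gene_id] = gene_structure.exon_count(t)
            recs = gene_structure.intron_phases(t, prot)
            spans = [gene_structure.residue_span(d)
                     for d in res.domains.get(g.gene_id, [])]
            gene_structure.type_domain_introns(recs, spans, prot)
            res.introns[g.gene_id] = recs

    # 4: phospho motifs
    hits_by_protein = {
        gid: phospho_motifs.scan_protein_motifs(proteins[pid], protein_id=gid)
        for gid, pid in sorted(targets.items())
    }
    res.phospho_table, res.phospho_summary = phospho_motifs.summarize_phospho(
        hits_by_protein, labels)

    # 5: promoters
    if genome is not None:
        table = promoter_cis.ElementTable()
        cats = []
        for g in genes:
            prom = genome_io.extract_promoter(g, genome, params.promoter_len)
            hits = promoter_cis.scan_elements(prom.seq, table, g.gene_id)
            res.promoter_hits[g.gene_id] = hits
            pc = promoter_cis.categorize_promoter(hits, table=table,
                                                  gene_id=g.gene_id)
            res.promoter_categories[g.gene_id] = pc
            cats.append(pc)
        res.promoter_summary = promoter_cis.cohort_category_summary(cats)

    # 6: chromosomal distribution and clusters
    if genes:
        res.chrom_counts = distribution.chromosome_counts(genes, genome)
        if genome is not None:
            res.densities = distribution.density(res.chrom_counts,
                                                 genome.lengths)
        res.clusters = distribution.detect_clusters(
            genes, params.cluster_max_span, params.cluster_min_genes, labels)

    # 7: expression
    if expr is not None:
        tissue, means = expression.baseline_tissue(expr)
        res.peaks = expression.peak_tissue(expr)
        res.expression_summary = {
            "baseline_tissue": tissue,
            "tissue_means": {t: float(means[t]) for t in expr.columns},
            "fraction_below_threshold_in_baseline": expression.fraction_below(
                expr, tissue, params.expression_threshold),
            "threshold": params.expression_threshold,
            "grid_threshold": expression.smallest_baseline_threshold(
                expr, tissue),
            "expressed_genes": expression.expressed_set(
                expr, params.expression_threshold),
        }

    # 8: phylogeny
    if alignment is not None and len(alignment) >= 3:
        if params.bootstrap_B > 0:
            res.tree, res.supports = phylo.bootstrap_support(
                alignment, B=params.bootstrap_B, seed=params.seed)
        else:
            res.tree = phylo.nj_tree(phylo.p_distance(alignment),
                                     alignment.ids)
        if alignment_labels:
            res.clade_report = phylo.clade_composition(res.tree,
                                                       alignment_labels)
    return res


def evaluate_recovery(truth: dict, res: PipelineResults) -> dict:
    """Planted-truth recovery rates (fractions in [0, 1]) for the core
    surfaces: classification, intron typing, cluster membership, promoter
    flags/categories, and peak tissue."""
    tg = truth["genes"]
    out: dict = {}

    # classification
    ok = tot = 0
    for gid, g in tg.items():
        a = res.assignments.get(gid)
        tot += 1
        if a is not None and a.label == g["label"]:
            if g["label"] != "IV" or g["secondary_label"] in (
                    None, a.secondary_label):
                ok += 1
    out["classification"] = ok / tot if tot else 1.0

    # intron typing: every planted intron recovered at matching offset,
    # phase and type, with no extra typed introns
    ok = tot = 0
    for gid, g in tg.items():
        recs = res.introns.get(gid, [])
        got = {(r.coding_offset, r.phase, r.type) for r in recs if r.in_cds}
        want = {(i["offset"], i["phase"], i["type"]) for i in g["introns"]}
        tot += 1
        ok += got == want
    out["intron_typing"] = ok / tot if tot else 1.0

    # clusters: exact member tuples
    want_clusters = {tuple(v) for v in truth["clusters"].values()}
    got_clusters = {tuple(c.members) for c in res.clusters}
    out["clusters"] = (1.0 if want_clusters == got_clusters
                       else len(want_clusters & got_clusters)
                       / max(1, len(want_clusters | got_clusters)))

    # promoter flags and categories
    ok = tot = 0
    cat_ok = 0
    for gid, g in tg.items():
        pc = res.promoter_categories.get(gid)
        tot += 1
        if pc is None:
            continue
        f = g["promoter"]["flags"]
        if (pc.sa_responsive, pc.aba_responsive, pc.drought_responsive,
                pc.wrky_regulated) == (f["sa"], f["aba"], f["drought"],
                                       f["wrky"]):
            ok += 1
        cat_ok += pc.category == g["promoter"]["category"]
    out["promoter_flags"] = ok / tot if tot else 1.0
    out["promoter_categories"] = cat_ok / tot if tot else 1.0

    # peak tissues
    if res.peaks is not None:
        peaks = dict(zip(res.peaks.gene_id, res.peaks.tissue))
        ok = sum(peaks.get(gid) == g["peak_tissue"] for gid, g in tg.items())
        out["peak_tissue"] = ok / len(tg)
        out["baseline_tissue_ok"] = (
            res.expression_summary.get("baseline_tissue")
            == truth.get("baseline_tissue"))
    return out
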