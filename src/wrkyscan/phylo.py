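"""Neighbor-joining trees on aligned WRKY domains, bootstrap supports,
and subgroup clade-composition tests.

Distances are proportion-of-mismatches (p-distance) with pairwise gap
deletion by default. NJ agglomeration uses the standard Q-criterion with a
deterministic tie-break (the pair whose smallest member labels sort first);
negative branch-length estimates are clamped to zero and counted. Bootstrap
support for an internal edge is the percentage of column-resampled
replicates whose tree contains the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .genome_io import _iter_fasta

GAP_CHARS = frozenset("-.?")


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        ids, rows = [], []
        for header, seq in _iter_fasta(path):
            ids.append(header.split(None, 1)[0])
            rows.append(seq.upper())
        return cls(ids=ids, rows=rows)

    def resample_columns(self, cols: np.ndarray) -> "Alignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(ids=list(self.ids), rows=rows)


def p_distance(aln: Alignment, gap_mode: str = "pairwise") -> np.ndarray:
    """Pairwise mismatch proportions.

    ``gap_mode="pairwise"`` compares, per pair, only the sites where both
    sequences are ungapped; ``"complete"`` first drops every column that
    contains a gap in any sequence. A pair with zero comparable sites is a
    hard error naming the pair.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need >=2 sequences")
    M = np.array([list(r) for r in aln.rows])
    gap = np.isin(M, list(GAP_CHARS))
    if gap_mode == "complete":
        keep = ~gap.any(axis=0)
        M, gap = M[:, keep], gap[:, keep]
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]!r} and "
                    f"{aln.ids[j]!r}"
                )
            mism = int((M[i, ok] != M[j, ok]).sum())
            D[i, j] = D[j, i] = mism / comparable
    return D


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(
    D: np.ndarray,
    ids: list[str],
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Standard neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion break toward the pair whose (sorted) smallest
    member labels compare lowest, which makes the topology a pure function
    of the matrix. Negative branch-length estimates are clamped to 0; the
    count is attached as ``tree.n_clamped_branches``.
    """
    D = np.asarray(D, dtype=float).copy()
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need >=3 taxa for an unrooted NJ tree")

    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    nwk = [str(i) for i in ids]
    keys = [str(i) for i in ids]
    m = n
    while m > 3:
        r = D.sum(axis=1)
        best = None  # (q, pairkey, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pk = tuple(sorted((keys[i], keys[j])))
                if (best is None or q < best[0] - 1e-12
                        or (abs(q - best[0]) <= 1e-12 and pk < best[1])):
                    best = (q, pk, i, j)
        _, _, i, j = best
        li = _clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = _clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        merged = f"({nwk[i]}:{_fmt(li)},{nwk[j]}:{_fmt(lj)})"
        key = min(keys[i], keys[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D = D2
        nwk = [nwk[k] for k in keep] + [merged]
        keys = [keys[k] for k in keep] + [key]
        m -= 1
    # final three-way join; closed-form branch lengths
    l0 = _clamp(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    l1 = _clamp(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    l2 = _clamp(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    newick = (f"({nwk[0]}:{_fmt(l0)},{nwk[1]}:{_fmt(l1)},"
              f"{nwk[2]}:{_fmt(l2)});")
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    tree.n_clamped_branches = clamped
    return tree


def internal_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each split is reported as the side containing the lexicographically
    smallest leaf label, so sets are comparable across trees regardless of
    rooting or leaf order.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(labels)
    n = len(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if anchor not in side:
            side = labels - side
        if 2 <= min(len(side), n - len(side)):
            splits.add(frozenset(side))
    return splits


def bootstrap_support(
    aln: Alignment,
    B: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree of the alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate from a seeded
    generator; support is the percentage of replicates whose tree contains
    the original bipartition. Replicates whose distance matrix is
    undefined (a pair with no comparable sites) contribute to the
    denominator but to no split. The returned dict maps *either* side of
    each internal split to its support percentage; supports are also
    written to the internal node labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tree = nj_tree(p_distance(aln, gap_mode), aln.ids)
    labels = set(aln.ids)
    orig = internal_splits(tree)
    counts = {s: 0 for s in orig}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, aln.n_sites, aln.n_sites)
        rep = aln.resample_columns(cols)
        try:
            rd = p_distance(rep, gap_mode)
        except ValueError:
            continue
        rsplits = internal_splits(nj_tree(rd, rep.ids))
        for s in orig:
            if s in rsplits:
                counts[s] += 1
    supports: dict[frozenset[str], float] = {}
    for s, c in counts.items():
        pct = 100.0 * c / B
        supports[s] = pct
        supports[frozenset(labels - s)] = pct
    anchor = min(labels)
    n = len(labels)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        canon = side if anchor in side else labels - side
        if 2 <= min(len(canon), n - len(canon)):
            node.label = f"{supports[frozenset(canon)]:.4g}"
    return tree, supports


DEFAULT_CLADE_GROUPS: dict[str, frozenset[str]] = {
    "Ia": frozenset({"Ia"}),
    "IIa+b": frozenset({"IIa", "IIb"}),
    "IIc": frozenset({"IIc"}),
    "IId+e": frozenset({"IId", "IIe"}),
    "III+Ib": frozenset({"III", "Ib"}),
}


def clade_composition(
    tree: dendropy.Tree,
    labels: dict[str, str],
    groups: dict[str, frozenset[str]] | None = None,
) -> dict[str, dict]:
    """Per-group monophyly report on an unrooted tree.

    For each named group (a set of labels), reports whether some edge
    bipartition isolates exactly the leaves carrying those labels, and if
    not, the minimum number of maximal label-pure subtrees needed to cover
    them. Every leaf must be labeled.
    """
    if groups is None:
        groups = DEFAULT_CLADE_GROUPS
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [x for x in leaf_labels if x not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing[:5]}")
    all_leaves = set(leaf_labels)
    splits = internal_splits(tree)
    anchor = min(all_leaves)
    report: dict[str, dict] = {}
    for name, labelset in groups.items():
        target = {x for x in leaf_labels if labels[x] in labelset}
        entry = {"n_leaves": len(target)}
        if len(target) <= 1 or target == all_leaves:
            entry["monophyletic"] = True
            entry["cover"] = 1 if target else 0
        else:
            canon = target if anchor in target else all_leaves - target
            mono = frozenset(canon) in splits or len(target) == len(all_leaves) - 1
            # a single leaf's complement is a trivial split not in `splits`
            if len(target) == 1 or len(all_leaves - target) == 1:
                mono = True
            entry["monophyletic"] = mono
            entry["cover"] = 1 if mono else _cover_number(tree, target,
                                                          all_leaves)
        report[name] = entry
    return report


def _cover_number(tree: dendropy.Tree, target: set[str],
                  all_leaves: set[str]) -> int:
    """Minimum number of maximal target-pure subtrees covering the target,
    computed on a clone rerooted at a leaf outside the target."""
    outside = sorted(all_leaves - target)[0]
    t2 = tree.clone(depth=1)
    og = t2.find_node_with_taxon_label(outside)
    t2.reroot_at_edge(og.edge, update_bipartitions=False)
    count = 0

    def pure(node) -> bool:
        # postorder purity: subtree leaves all inside target
        return all(
            leaf.taxon.label in target for leaf in node.leaf_iter()
        )

    def walk(node, parent_pure: bool) -> None:
        nonlocal count
        p = pure(node)
        if p and not parent_pure:
            count += 1
        if not p:
            for ch in node.child_nodes():
                walk(ch, False)

    walk(t2.seed_node, False)
    return count
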