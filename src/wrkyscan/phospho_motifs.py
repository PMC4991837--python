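"""Linear-motif scan for MAPK phosphorylation sites and docking motifs.

The default grammar is the literature-standard set: the minimal
proline-directed site (S/T)P, the preferred context P-X-(S/T)-P, the MAPK
docking D-motif (K/R)1-3 - X1-6 - Phi - X - Phi with Phi in {L, I, V}, and
the F-site F-X-F-P. Patterns are data, not code: a grammar can be loaded
from a config mapping so alternative published consensi can be dropped in.

Matching policy: within one motif class hits are non-overlapping and
leftmost-greedy (at each leftmost matching position the longest admissible
match is taken, then the scan resumes past it); across classes overlaps are
allowed. The matcher enumerates segment lengths explicitly, which makes the
longest-at-start rule exact rather than an artifact of regex backtracking
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: One motif = a sequence of segments (allowed residues, min repeat, max repeat);
#: ``None`` means any residue.
Segment = tuple[frozenset[str] | None, int, int]


def _seg(chars: str | None, lo: int = 1, hi: int = 1) -> Segment:
    return (frozenset(chars) if chars else None, lo, hi)


@dataclass
class MotifGrammar:
    patterns: dict[str, list[Segment]] = field(default_factory=lambda: {
        "mapk_minimal": [_seg("ST"), _seg("P")],
        "mapk_preferred": [_seg("P"), _seg(None), _seg("ST"), _seg("P")],
        "d_motif": [_seg("KR", 1, 3), _seg(None, 1, 6), _seg("LIV"),
                    _seg(None), _seg("LIV")],
        "f_site": [_seg("F"), _seg(None), _seg("F"), _seg("P")],
    })

    @classmethod
    def from_dict(cls, spec: dict) -> "MotifGrammar":
        """Build from config: {name: [{chars: 'ST'|'*', min: 1, max: 1}, ...]}."""
        patterns = {}
        for name, segs in spec.items():
            patterns[name] = [
                _seg(None if s.get("chars", "*") == "*" else s["chars"],
                     int(s.get("min", 1)), int(s.get("max", 1)))
                for s in segs
            ]
        return cls(patterns=patterns)

    def to_dict(self) -> dict:
        return {
            name: [
                {"chars": "".join(sorted(cs)) if cs else "*",
                 "min": lo, "max": hi}
                for cs, lo, hi in segs
            ]
            for name, segs in self.patterns.items()
        }


@dataclass
class ProteinMotifHit:
    protein_id: str
    motif_class: str
    start: int  # 0-based
    sequence: str


def _longest_match(protein: str, i: int, segments: list[Segment]) -> int | None:
    """Longest end index (exclusive) of a match starting at i, else None."""
    if not segments:
        return i
    chars, lo, hi = segments[0]
    n = len(protein)
    best: int | None = None
    run = 0  # longest admissible consumption at i for this segment
    while run < hi and i + run < n and (chars is None or protein[i + run] in chars):
        run += 1
    for L in range(run, lo - 1, -1):
        end = _longest_match(protein, i + L, segments[1:])
        if end is not None and (best is None or end > best):
            best = end
    return best


def scan_protein_motifs(
    protein: str,
    grammar: MotifGrammar | None = None,
    protein_id: str = "",
) -> list[ProteinMotifHit]:
    """All grammar matches; non-overlapping within a class, overlapping
    across classes."""
    if grammar is None:
        grammar = MotifGrammar()
    hits: list[ProteinMotifHit] = []
    for name, segments in grammar.patterns.items():
        i = 0
        n = len(protein)
        while i < n:
            end = _longest_match(protein, i, segments)
            if end is not None and end > i:
                hits.append(ProteinMotifHit(protein_id, name, i,
                                            protein[i:end]))
                i = end
            else:
                i += 1
    hits.sort(key=lambda h: (h.motif_class, h.start))
    return hits


def summarize_phospho(
    hits_by_protein: dict[str, list[ProteinMotifHit]],
    assignments: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-protein counts plus cohort rollups.

    ``assignments`` maps protein id -> group label; when given, zero-site
    proteins are additionally tallied per subgroup.
    """
    rows = []
    for pid in sorted(hits_by_protein):
        hits = hits_by_protein[pid]
        counts = {
            cls: sum(1 for h in hits if h.motif_class == cls)
            for cls in ("mapk_minimal", "mapk_preferred", "d_motif", "f_site")
        }
        rows.append({
            "protein_id": pid,
            "site_count": counts["mapk_minimal"],
            "preferred_count": counts["mapk_preferred"],
            "d_motif_count": counts["d_motif"],
            "f_site_count": counts["f_site"],
            "has_docking": counts["d_motif"] + counts["f_site"] > 0,
        })
    table = pd.DataFrame(rows, columns=[
        "protein_id", "site_count", "preferred_count", "d_motif_count",
        "f_site_count", "has_docking",
    ])
    n = len(table)
    summary: dict = {"n_proteins": n}
    if n:
        with_sites = table[table.site_count > 0]
        summary["fraction_with_site"] = len(with_sites) / n
        imax = table.sort_values(
            ["site_count", "protein_id"], ascending=[False, True]
        ).iloc[0]
        summary["max_site_count"] = int(imax.site_count)
        summary["max_site_protein"] = imax.protein_id
        summary["fraction_sites_with_dmotif"] = (
            float((with_sites.d_motif_count > 0).mean()) if len(with_sites) else 0.0
        )
        summary["n_without_docking"] = int((~table.has_docking).sum())
        summary["n_without_docking_or_sites"] = int(
            ((~table.has_docking) & (table.site_count == 0)).sum()
        )
        if assignments is not None:
            zero = table[table.site_count == 0]
            per_group: dict[str, int] = {}
            for pid in zero.protein_id:
                g = assignments.get(pid, "?")
                per_group[g] = per_group.get(g, 0) + 1
            summary["zero_site_by_group"] = per_group
    return table, summary
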