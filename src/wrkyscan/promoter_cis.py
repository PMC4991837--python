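"""Promoter cis-element scanning and stress-responsiveness categories.

Six element classes are scanned by IUPAC consensus on both strands: the
ABA-responsive element (ABRE) and its coupling elements CE1/CE3, the
dehydration/drought-responsive element (DRE), the salicylic-acid response
element (SARE), and the W-box bound by WRKY proteins themselves. The key
combination rule is ABRE coupling: a lone ABRE does not confer ABA
responsiveness - it must co-occur with a CE, a second ABRE, or a DRE.

Consensus strings and the category rule table ship as data (config
overridable), since different sources print slightly different motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values

from .genome_io import reverse_complement

#: Default consensus table; IUPAC codes allowed.
DEFAULT_ELEMENTS: dict[str, str] = {
    "ABRE": "ACGTGKC",    # ACGTG(G/T)C
    "CE1": "TGCCACCGG",
    "CE3": "ACGCGTGTC",
    "DRE": "RCCGAC",      # (A/G)CCGAC
    "SARE": "TTCGACC",
    "WBOX": "TTGACY",     # TTGAC(C/T)
}

#: Category rule table, evaluated top-down; first match wins, else 6.
DEFAULT_CATEGORY_RULES: list[dict] = [
    {"category": 5, "all_elements": True},
    {"category": 4, "flags": {"sa": True, "aba": True, "drought": True}},
    {"category": 2, "flags": {"sa": True, "aba": True}},
    {"category": 3, "flags": {"sa": True, "drought": True, "aba": False}},
    {"category": 1, "flags": {"sa": True}},
]


def iupac_to_regex(consensus: str) -> str:
    parts = []
    for c in consensus.upper():
        expansion = ambiguous_dna_values.get(c)
        if expansion is None:
            raise ValueError(f"not an IUPAC nucleotide code: {c!r}")
        parts.append(c if len(expansion) == 1 else f"[{expansion}]")
    return "".join(parts)


@dataclass
class ElementTable:
    elements: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENTS))
    both_strands: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cons in self.elements.items():
            if len(cons) < 5:
                raise ValueError(f"{name}: consensus shorter than 5 nt")
            iupac_to_regex(cons)  # validates codes
        for name in self.elements:
            self.both_strands.setdefault(name, True)

    @classmethod
    def from_dict(cls, spec: dict) -> "ElementTable":
        elements, strands = {}, {}
        for name, v in spec.items():
            if isinstance(v, str):
                elements[name] = v
            else:
                elements[name] = v["consensus"]
                strands[name] = bool(v.get("both_strands", True))
        return cls(elements=elements, both_strands=strands)


@dataclass
class CisElementHit:
    gene_id: str
    element: str
    strand: str  # "+" | "-"
    start: int  # 0-based within the promoter window
    offset: int  # negative, relative to the window's 3' end
    sequence: str


@dataclass
class PromoterCategory:
    gene_id: str
    counts: dict[str, int]
    category: int
    sa_responsive: bool
    aba_responsive: bool
    drought_responsive: bool
    wrky_regulated: bool
    evidence: list[str] = field(default_factory=list)


def scan_elements(
    promoter: str,
    table: ElementTable | None = None,
    gene_id: str = "",
) -> list[CisElementHit]:
    """All matches of every consensus on both strands.

    Offsets are negative and measured from the 3' end of the window (the
    position just upstream of the anchor is -consensus-length). Overlapping
    occurrences of one element are all reported.
    """
    if not promoter:
        raise ValueError("empty promoter sequence")
    if table is None:
        table = ElementTable()
    promoter = promoter.upper()
    n = len(promoter)
    hits: list[CisElementHit] = []
    for name, cons in table.elements.items():
        fwd = re.compile(f"(?=({iupac_to_regex(cons)}))")
        for m in fwd.finditer(promoter):
            hits.append(CisElementHit(gene_id, name, "+", m.start(),
                                      m.start() - n, m.group(1)))
        if table.both_strands[name]:
            rev = re.compile(f"(?=({iupac_to_regex(reverse_complement(cons))}))")
            for m in rev.finditer(promoter):
                hits.append(CisElementHit(gene_id, name, "-", m.start(),
                                          m.start() - n, m.group(1)))
    hits.sort(key=lambda h: (h.element, h.start, h.strand))
    return hits


def element_counts(hits: list[CisElementHit],
                   table: ElementTable | None = None) -> dict[str, int]:
    if table is None:
        table = ElementTable()
    counts = {name: 0 for name in table.elements}
    for h in hits:
        counts[h.element] = counts.get(h.element, 0) + 1
    return counts


def responsiveness_flags(counts: dict[str, int]) -> dict[str, bool]:
    """The combination logic over element presence/multiplicity."""
    abre = counts.get("ABRE", 0)
    ce = counts.get("CE1", 0) + counts.get("CE3", 0)
    dre = counts.get("DRE", 0)
    return {
        "sa": counts.get("SARE", 0) >= 1,
        "aba": abre >= 1 and (ce >= 1 or abre >= 2 or dre >= 1),
        "drought": dre >= 1,
        "wrky": counts.get("WBOX", 0) >= 1,
    }


def categorize_promoter(
    hits: list[CisElementHit],
    rules: list[dict] | None = None,
    table: ElementTable | None = None,
    gene_id: str = "",
) -> PromoterCategory:
    """Derive responsiveness flags and the 1-6 category for one gene."""
    if rules is None:
        rules = DEFAULT_CATEGORY_RULES
    if table is None:
        table = ElementTable()
    counts = element_counts(hits, table)
    flags = responsiveness_flags(counts)
    all_elements = (
        counts.get("ABRE", 0) >= 1
        and (counts.get("CE1", 0) + counts.get("CE3", 0)) >= 1
        and counts.get("DRE", 0) >= 1
        and counts.get("SARE", 0) >= 1
        and counts.get("WBOX", 0) >= 1
    )
    category = 6
    evidence = [f"counts={counts}", f"flags={flags}"]
    for rule in rules:
        if rule.get("all_elements") and not all_elements:
            continue
        if any(flags[k] != v for k, v in rule.get("flags", {}).items()):
            continue
        category = int(rule["category"])
        evidence.append(f"matched rule {rule}")
        break
    else:
        evidence.append("no rule matched; category 6")
    return PromoterCategory(
        gene_id=gene_id or (hits[0].gene_id if hits else ""),
        counts=counts,
        category=category,
        sa_responsive=flags["sa"],
        aba_responsive=flags["aba"],
        drought_responsive=flags["drought"],
        wrky_regulated=flags["wrky"],
        evidence=evidence,
    )


def cohort_category_summary(categories: list[PromoterCategory]) -> dict:
    by_cat = {c: 0 for c in range(1, 7)}
    by_flag = {"sa": 0, "aba": 0, "drought": 0, "wrky": 0}
    for pc in categories:
        by_cat[pc.category] += 1
        by_flag["sa"] += pc.sa_responsive
        by_flag["aba"] += pc.aba_responsive
        by_flag["drought"] += pc.drought_responsive
        by_flag["wrky"] += pc.wrky_regulated
    assert sum(by_cat.values()) == len(categories)
    return {"n_genes": len(categories), "by_category": by_cat,
            "by_flag": by_flag}
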