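"""Detection of WRKY heptamers and zinc fingers, and domain assembly.

A WRKY domain is a ~60-aa DNA-binding module: a seven-residue core motif
(canonically WRKYGQK) followed, within a short linkage window, by a
metal-binding zinc finger of either the C2H2 type (C-X4-5-C-X22-23-H-X1-H)
or the C2HC type (C-X5-7-C-X23-H-X1-C). The finger type and the residues
trailing its second cysteine carry the family's group/subgroup signal, so
both are captured verbatim on each hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Core-motif consensus: W(R/K)(K/R)Y, reported with the following 3 residues.
CANONICAL_RE = re.compile(r"(?=(W[RK][KR]Y.{3}))")

#: Variant 4-mers accepted only when confirmed by a downstream zinc finger.
DEFAULT_VARIANT_TABLE: tuple[str, ...] = ("WSKY", "WVKY", "WRMC")

#: Admissible (type, spacer1, spacer2) geometries, shortest spacers first.
_FINGER_GEOMETRIES: tuple[tuple[str, int, int], ...] = (
    ("C2H2", 4, 22),
    ("C2H2", 4, 23),
    ("C2H2", 5, 22),
    ("C2H2", 5, 23),
    ("C2HC", 5, 23),
    ("C2HC", 6, 23),
    ("C2HC", 7, 23),
)

DEFAULT_LINKAGE_WINDOW = 30  # residues between heptamer end and first cysteine
DEFAULT_TAIL_OFFSET = 4  # residues after the second cysteine to the X-V-E window


@dataclass
class HeptamerHit:
    protein_id: str
    start: int  # 0-based
    sequence: str  # 7 aa
    tier: str  # "canonical" | "variant"

    @property
    def end(self) -> int:
        return self.start + 7


@dataclass
class ZincFinger:
    protein_id: str
    start: int  # 0-based position of the first cysteine
    type: str  # "C2H2" | "C2HC"
    spacer1: int  # residues between the two cysteines
    signature: str  # first C through the final H/C, inclusive
    tail_triplet: str  # 3-aa X-V-E-style window (IId/IIe/Ia comparisons)

    @property
    def end(self) -> int:
        return self.start + len(self.signature)

    @property
    def trailing(self) -> str:
        """The 7 residues immediately after the second cysteine."""
        return self.signature[self.spacer1 + 2 : self.spacer1 + 9]


@dataclass
class WRKYDomain:
    protein_id: str
    heptamer: HeptamerHit | None
    finger: ZincFinger | None
    complete: bool
    terminal_role: str = "sole"  # "N" | "C" | "sole"

    @property
    def start(self) -> int:
        if self.heptamer is not None:
            return self.heptamer.start
        assert self.finger is not None
        return self.finger.start

    @property
    def end(self) -> int:
        if self.finger is not None:
            return self.finger.end
        assert self.heptamer is not None
        return self.heptamer.end


def scan_heptamers(
    protein: str,
    protein_id: str = "",
    variant_table: tuple[str, ...] = DEFAULT_VARIANT_TABLE,
) -> list[HeptamerHit]:
    """All heptamer core-motif matches, canonical consensus plus variants.

    Canonical = W(R/K)(K/R)Y; variants are exact 4-mer matches from the
    configurable table. Hits are reported as 7-mers (matches closer than
    3 residues to the C terminus are dropped) sorted by position.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    hits = [
        HeptamerHit(protein_id, m.start(), m.group(1), "canonical")
        for m in CANONICAL_RE.finditer(protein)
    ]
    seen = {h.start for h in hits}
    for fourmer in variant_table:
        for m in re.finditer(f"(?={re.escape(fourmer)})", protein):
            i = m.start()
            if i in seen or i + 7 > len(protein):
                continue
            hits.append(HeptamerHit(protein_id, i, protein[i : i + 7], "variant"))
            seen.add(i)
    hits.sort(key=lambda h: h.start)
    return hits


def _match_finger_at(
    protein: str, i: int, tail_offset: int, protein_id: str
) -> ZincFinger | None:
    n = len(protein)
    if protein[i] != "C":
        return None
    for ftype, s1, s2 in _FINGER_GEOMETRIES:
        c2 = i + 1 + s1
        h1 = c2 + 1 + s2
        last = h1 + 2
        if last >= n:
            continue
        final = "H" if ftype == "C2H2" else "C"
        if protein[c2] == "C" and protein[h1] == "H" and protein[last] == final:
            return ZincFinger(
                protein_id=protein_id,
                start=i,
                type=ftype,
                spacer1=s1,
                signature=protein[i : last + 1],
                tail_triplet=protein[c2 + 1 + tail_offset : c2 + 4 + tail_offset],
            )
    return None


def scan_zinc_fingers(
    protein: str,
    protein_id: str = "",
    tail_offset: int = DEFAULT_TAIL_OFFSET,
) -> list[ZincFinger]:
    """Non-overlapping zinc-finger matches, left to right.

    At each candidate cysteine the admissible geometries are tried with the
    shortest spacers first (C2H2 before C2HC); the scan then resumes past
    the accepted match, which makes the result deterministic.
    """
    hits: list[ZincFinger] = []
    i = 0
    n = len(protein)
    while i < n:
        zf = _match_finger_at(protein, i, tail_offset, protein_id)
        if zf is not None:
            hits.append(zf)
            i = zf.end
        else:
            i += 1
    return hits


def assemble_domains(
    heptamers: list[HeptamerHit],
    fingers: list[ZincFinger],
    linkage_window: int = DEFAULT_LINKAGE_WINDOW,
) -> list[WRKYDomain]:
    """Pair heptamers with downstream fingers into WRKY domains.

    Each heptamer takes the nearest unused finger whose first cysteine lies
    within ``linkage_window`` residues downstream of the heptamer end
    (complete domain). Pairings are resolved left to right. Unpaired
    canonical heptamers and unpaired fingers become incomplete domains;
    unpaired *variant* heptamers are dropped entirely (the tier gate: a
    variant core motif is only believed when a confirming finger follows).
    Terminal roles N/C are assigned when exactly two complete domains exist.
    """
    pids = {h.protein_id for h in heptamers} | {f.protein_id for f in fingers}
    if len(pids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(pids)}")
    pid = pids.pop() if pids else ""

    used: set[int] = set()
    domains: list[WRKYDomain] = []
    for h in sorted(heptamers, key=lambda h: h.start):
        best = None
        for idx, f in enumerate(fingers):
            if idx in used:
                continue
            gap = f.start - h.end
            if 0 <= gap <= linkage_window:
                if best is None or gap < best[0]:
                    best = (gap, idx)
        if best is not None:
            used.add(best[1])
            domains.append(WRKYDomain(pid, h, fingers[best[1]], complete=True))
        elif h.tier == "canonical":
            domains.append(WRKYDomain(pid, h, None, complete=False))
        # variant heptamer without a confirming finger: dropped
    for idx, f in enumerate(fingers):
        if idx not in used:
            domains.append(WRKYDomain(pid, None, f, complete=False))
    domains.sort(key=lambda d: d.start)

    complete = [d for d in domains if d.complete]
    if len(complete) == 2:
        complete[0].terminal_role = "N"
        complete[1].terminal_role = "C"
    return domains


def scan_domains(
    protein: str,
    protein_id: str = "",
    variant_table: tuple[str, ...] = DEFAULT_VARIANT_TABLE,
    linkage_window: int = DEFAULT_LINKAGE_WINDOW,
    tail_offset: int = DEFAULT_TAIL_OFFSET,
) -> list[WRKYDomain]:
    """Convenience: heptamer scan + finger scan + assembly for one protein."""
    heptamers = scan_heptamers(protein, protein_id, variant_table) if protein else []
    fingers = scan_zinc_fingers(protein, protein_id, tail_offset)
    return assemble_domains(heptamers, fingers, linkage_window)


def read_hmmer_domtbl(path: str) -> list[tuple[str, int, int]]:
    """Adapter for external HMMER ``--domtblout`` hits.

    Returns (target id, envelope start, envelope end) triples, 1-based
    inclusive, as an alternative candidate-region source. No scoring is
    interpreted here.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < 21:
                continue
            out.append((f[0], int(f[19]), int(f[20])))
    return out
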