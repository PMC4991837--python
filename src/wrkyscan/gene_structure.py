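"""Exon counts, intron phases, and PR/VQR intron typing inside WRKY domains.

Intron phase is defined relative to codon boundaries in the coding (5'->3'
translation) orientation: phase 0 sits between two codons, phase 1 after the
first nucleotide of a codon, phase 2 after the second. Within the
domain-coding region two intron types recur in this family: the PR intron,
which interrupts the codon of an arginine (phase 1 or 2), and the VQR
intron, a phase-0 intron immediately 5' of a valine codon (canonically in a
V-Q-R context).
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain_scan import WRKYDomain
from .genome_io import TranscriptModel


@dataclass
class IntronRecord:
    transcript_id: str
    index: int  # 5'->3' in coding orientation, 0-based
    donor: int  # first intron base, genomic 1-based, transcript orientation
    acceptor: int  # last intron base
    coding_offset: int  # coding nt upstream of the intron
    phase: int  # coding_offset mod 3
    in_cds: bool  # interrupts the CDS (UTR introns are never typed)
    within_domain: bool = False
    type: str = "none"  # "PR" | "VQR" | "none"
    interrupted_residue: str | None = None  # aa, phases 1/2
    following_context: str | None = None  # 3 aa, phase 0


def exon_count(t: TranscriptModel) -> int:
    return len(t.exons)


def _exon_index_of(t: TranscriptModel, iv: tuple[int, int]) -> int:
    for k, (s, e) in enumerate(t.exons):
        if s <= iv[0] and iv[1] <= e:
            return k
    raise ValueError(f"{t.transcript_id}: CDS {iv} not inside any exon")


def intron_phases(
    t: TranscriptModel, protein: str | None = None
) -> list[IntronRecord]:
    """One record per intron, in coding orientation.

    ``coding_offset`` counts CDS nucleotides upstream of the intron;
    phase = offset mod 3. Introns entirely in UTR are reported with
    ``in_cds=False``. When ``protein`` is supplied the interrupted residue
    (phases 1/2) or the 3-aa following context (phase 0) is attached.
    """
    total = t.cds_length()
    cds_exon = [_exon_index_of(t, iv) for iv in t.cds]
    records: list[IntronRecord] = []
    for k in range(len(t.exons) - 1):
        up, down = t.exons[k], t.exons[k + 1]
        if t.strand == "+":
            donor, acceptor = up[1] + 1, down[0] - 1
        else:
            donor, acceptor = up[0] - 1, down[1] + 1
        offset = sum(
            e - s + 1
            for (s, e), xi in zip(t.cds, cds_exon)
            if xi <= k
        )
        phase = offset % 3
        in_cds = 0 < offset < total
        rec = IntronRecord(
            transcript_id=t.transcript_id,
            index=k,
            donor=donor,
            acceptor=acceptor,
            coding_offset=offset,
            phase=phase,
            in_cds=in_cds,
        )
        if protein is not None and in_cds:
            aa_i = offset // 3
            if phase in (1, 2) and aa_i < len(protein):
                rec.interrupted_residue = protein[aa_i]
            elif phase == 0:
                rec.following_context = protein[aa_i : aa_i + 3]
        records.append(rec)
    return records


def residue_span(d: WRKYDomain) -> tuple[int, int]:
    """Domain residue span (0-based, end-exclusive) over the protein."""
    return d.start, d.end


def map_domain_to_cds(
    d: WRKYDomain, t: TranscriptModel
) -> list[tuple[int, int]]:
    """Genomic intervals (1-based inclusive) covering the domain's codons.

    Intervals may split across exons; they are returned in translation
    order and are strand-aware.
    """
    rs, re_ = residue_span(d)
    return residues_to_genomic(t, rs, re_)


def residues_to_genomic(
    t: TranscriptModel, res_start: int, res_end: int
) -> list[tuple[int, int]]:
    """Map protein residues [res_start, res_end) to genomic codon intervals."""
    a, b = 3 * res_start, 3 * res_end
    total = t.cds_length()
    if b > total:
        raise ValueError(
            f"{t.transcript_id}: residue span {res_start}-{res_end} beyond "
            f"protein length ({total // 3} codons incl. stop)"
        )
    out: list[tuple[int, int]] = []
    cum = 0
    for s, e in t.cds:
        L = e - s + 1
        lo, hi = max(a, cum), min(b, cum + L)  # overlap in CDS coords
        if lo < hi:
            if t.strand == "+":
                out.append((s + (lo - cum), s + (hi - cum) - 1))
            else:
                out.append((e - (hi - cum) + 1, e - (lo - cum)))
        cum += L
    return out


def type_domain_introns(
    records: list[IntronRecord],
    domain_spans: list[tuple[int, int]],
    protein: str,
    require_vqr_context: bool = True,
) -> list[IntronRecord]:
    """Fill in PR/VQR types for introns inside domain-coding regions.

    ``domain_spans`` are residue spans (0-based, end-exclusive) of the
    protein's WRKY domains. Within a domain: a phase-1/2 intron splitting
    an arginine codon is PR; a phase-0 intron immediately 5' of a valine
    codon is VQR (by default the V must start a V-Q-R context; relax with
    ``require_vqr_context=False``). UTR introns are never typed.
    """
    for rec in records:
        if not rec.in_cds:
            continue
        o = rec.coding_offset
        rec.within_domain = any(
            3 * rs <= o <= 3 * re_ for rs, re_ in domain_spans
        )
        if not rec.within_domain:
            continue
        aa_i = o // 3
        if rec.phase in (1, 2):
            if aa_i < len(protein) and protein[aa_i] == "R":
                rec.type = "PR"
        else:
            ctx = protein[aa_i : aa_i + 3]
            if ctx[:1] == "V" and (not require_vqr_context or ctx == "VQR"):
                rec.type = "VQR"
    return records


def intron_type_tallies(records: list[IntronRecord]) -> dict[str, int]:
    out = {"PR": 0, "VQR": 0, "none": 0}
    for r in records:
        if r.in_cds and r.within_domain:
            out[r.type] += 1
    return out


def domains_without_typed_intron(
    domain_spans: list[tuple[int, int]], records: list[IntronRecord]
) -> int:
    """Number of domains harbouring neither a PR nor a VQR intron.

    Whether such counts should be read per domain or per gene is genuinely
    ambiguous in the field's usage, so this per-domain count is paired with
    a per-gene rollup downstream.
    """
    n = 0
    for rs, re_ in domain_spans:
        typed = any(
            r.in_cds
            and r.type in ("PR", "VQR")
            and 3 * rs <= r.coding_offset <= 3 * re_
            for r in records
        )
        if not typed:
            n += 1
    return n
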