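"""Genome and annotation I/O with coordinate-safe sequence extraction.

All public coordinates are 1-based inclusive (the GFF3 convention); interval
arithmetic inside this module converts to 0-based half-open at the boundary
and back, so exon/CDS/promoter slicing never accumulates off-by-one drift.
Exon and CDS interval lists are stored in *translation order*: ascending on
the + strand, descending on the - strand.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

from Bio.Seq import Seq

import gffutils

log = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")


class GenomeIOError(ValueError):
    """Raised on malformed FASTA/GFF3 input."""


@dataclass
class Genome:
    """Chromosome sequences keyed by id, uppercase A/C/G/T/N only."""

    records: dict[str, str]
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.records.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Return bases [start, end], 1-based inclusive, forward strand."""
        if chrom not in self.records:
            raise GenomeIOError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > len(self.records[chrom]) or start > end:
            raise GenomeIOError(
                f"interval {start}-{end} outside {chrom} "
                f"(length {len(self.records[chrom])})"
            )
        return self.records[chrom][start - 1 : end]


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein_id: str | None = None
    partial: bool = False

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.transcript_id}: bad strand {self.strand!r}")
        ivs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise GenomeIOError(f"{self.transcript_id}: overlapping exons")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise GenomeIOError(
                    f"{self.transcript_id}: CDS {cs}-{ce} not contained in an exon"
                )
        if self.cds_length() % 3 and not self.partial:
            raise GenomeIOError(
                f"{self.transcript_id}: CDS length {self.cds_length()} not a "
                "multiple of 3 and transcript not flagged partial"
            )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptModel]

    def validate(self) -> None:
        if not self.transcripts:
            raise GenomeIOError(f"{self.gene_id}: gene without transcripts")
        lo = min(min(s for s, _ in t.exons) for t in self.transcripts)
        hi = max(max(e for _, e in t.exons) for t in self.transcripts)
        if self.span[0] > lo or self.span[1] < hi:
            raise GenomeIOError(f"{self.gene_id}: span does not cover transcripts")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _iter_fasta(path: str):
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:]
                chunks = []
            elif line:
                if header is None:
                    raise GenomeIOError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str) -> Genome:
    """Load a nucleotide FASTA into a :class:`Genome`.

    Lowercase is normalized to uppercase; ambiguity codes other than N are
    rejected. Duplicate record ids and empty files are hard errors.
    """
    records: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    for header, seq in _iter_fasta(path):
        parts = header.split(None, 1)
        rid = parts[0]
        if rid in records:
            raise GenomeIOError(f"{path}: duplicate FASTA id {rid!r}")
        seq = seq.upper()
        bad = set(seq) - _VALID_NT
        if bad:
            raise GenomeIOError(
                f"{path}: record {rid!r} contains non-ACGTN characters "
                f"{sorted(bad)}; only N is accepted as an ambiguity code"
            )
        records[rid] = seq
        descriptions[rid] = parts[1] if len(parts) > 1 else ""
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records found")
    return Genome(records=records, descriptions=descriptions)


def write_fasta(records: Genome | dict[str, str], path: str, width: int = 60) -> None:
    if isinstance(records, Genome):
        mapping = records.records
        desc = records.descriptions
    else:
        mapping = records
        desc = {}
    with open(path, "w") as fh:
        for rid, seq in mapping.items():
            d = desc.get(rid, "")
            fh.write(f">{rid} {d}\n" if d else f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path: str) -> dict[str, str]:
    """Protein FASTA as an id -> sequence map (uppercased, stops kept)."""
    out: dict[str, str] = {}
    for header, seq in _iter_fasta(path):
        rid = header.split(None, 1)[0]
        if rid in out:
            raise GenomeIOError(f"{path}: duplicate FASTA id {rid!r}")
        out[rid] = seq.upper()
    if not out:
        raise GenomeIOError(f"{path}: no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str, genome: Genome | None = None) -> list[GeneModel]:
    """Assemble gene/mRNA/exon/CDS hierarchies from a GFF3 file.

    Coordinates are validated against ``genome`` chromosome lengths when a
    genome is supplied. Orphan features (Parent unresolvable) are skipped
    with a logged warning; out-of-bounds CDS is a hard error.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(g, featuretype="mRNA", order_by="start"):
            parents = mrna.attributes.get("Parent", [])
            if parents and parents[0] not in gene_ids:
                log.warning("mRNA %s has unresolvable Parent %s; skipped",
                            mrna.id, parents[0])
                continue
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            if not exons and cds:
                exons = list(cds)  # minimal GFF3 without explicit exon rows
            if genome is not None and g.seqid in genome:
                clen = genome.lengths[g.seqid]
                for s, e in cds:
                    if s < 1 or e > clen:
                        raise GenomeIOError(
                            f"{mrna.id}: CDS {s}-{e} outside chromosome "
                            f"{g.seqid} (length {clen})"
                        )
            if mrna.strand == "-":
                exons = exons[::-1]
                cds = cds[::-1]
            pid = mrna.attributes.get("protein_id", [None])[0]
            partial = mrna.attributes.get("partial", ["false"])[0] == "true"
            t = TranscriptModel(
                transcript_id=mrna.id,
                gene_id=g.id,
                chrom=g.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                protein_id=pid,
                partial=partial,
            )
            t.validate()
            transcripts.append(t)
        if not transcripts:
            log.warning("gene %s has no valid mRNA children; skipped", g.id)
            continue
        gm = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand,
            span=(g.start, g.end),
            transcripts=transcripts,
        )
        gm.validate()
        genes.append(gm)
    # orphan mRNAs whose Parent gene is absent entirely
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if parents and parents[0] not in gene_ids:
            log.warning("mRNA %s has Parent %s with no gene record; skipped",
                        mrna.id, parents[0])
    return genes


def read_gff3_string(text: str, genome: Genome | None = None) -> list[GeneModel]:
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(text)
        tmp = fh.name
    try:
        return read_gff3(tmp, genome)
    finally:
        os.unlink(tmp)


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon/CDS rows; interval lists re-sorted ascending."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\twrkyscan\tgene\t{g.span[0]}\t{g.span[1]}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                lo = min(s for s, _ in t.exons)
                hi = max(e for _, e in t.exons)
                attrs = f"ID={t.transcript_id};Parent={g.gene_id}"
                if t.protein_id:
                    attrs += f";protein_id={t.protein_id}"
                if t.partial:
                    attrs += ";partial=true"
                fh.write(
                    f"{g.chrom}\twrkyscan\tmRNA\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                    f"{attrs}\n"
                )
                phase = 0
                for s, e in sorted(t.exons):
                    fh.write(
                        f"{g.chrom}\twrkyscan\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for s, e in t.cds:  # translation order, so phase is correct
                    fh.write(
                        f"{g.chrom}\twrkyscan\tCDS\t{s}\t{e}\t.\t{t.strand}\t"
                        f"{phase}\tParent={t.transcript_id}\n"
                    )
                    phase = (3 - ((e - s + 1 - phase) % 3)) % 3


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

@dataclass
class Translation:
    seq: str
    internal_stop: bool = False
    partial: bool = False


def extract_cds_nt(t: TranscriptModel, genome: Genome) -> str:
    """CDS nucleotides concatenated in translation order (coding strand)."""
    parts = []
    for s, e in t.cds:
        chunk = genome.slice(t.chrom, s, e)
        parts.append(reverse_complement(chunk) if t.strand == "-" else chunk)
    return "".join(parts)


def extract_protein(t: TranscriptModel, genome: Genome) -> Translation:
    """Translate a transcript's CDS with the standard nuclear code.

    The trailing stop is removed; an internal stop is kept in the sequence
    and flagged rather than silently dropped. N codons translate to X.
    """
    nt = extract_cds_nt(t, genome)
    if len(nt) < 3:
        raise GenomeIOError(f"{t.transcript_id}: CDS shorter than one codon")
    if len(nt) % 3:
        if not t.partial:
            raise GenomeIOError(
                f"{t.transcript_id}: CDS length {len(nt)} not divisible by 3"
            )
        nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return Translation(seq=aa, internal_stop="*" in aa, partial=t.partial)


@dataclass
class Promoter:
    gene_id: str
    seq: str
    truncated: bool = False


def extract_promoter(
    g: GeneModel,
    genome: Genome,
    upstream_bp: int = 1500,
    anchor: str = "cds",
) -> Promoter:
    """Upstream bases 5' of the gene start, on the coding strand.

    ``anchor`` selects the reference point: the first CDS base of the first
    transcript (``"cds"``, default) or the gene span boundary (``"span"``).
    Windows running off the chromosome edge are truncated and flagged.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    if anchor == "cds":
        t = g.transcripts[0]
        a = min(s for s, _ in t.cds) if g.strand == "+" else max(e for _, e in t.cds)
    elif anchor == "span":
        a = g.span[0] if g.strand == "+" else g.span[1]
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    clen = genome.lengths[g.chrom]
    if g.strand == "+":
        lo, hi = a - upstream_bp, a - 1
        truncated = lo < 1
        lo = max(lo, 1)
        seq = genome.slice(g.chrom, lo, hi) if lo <= hi else ""
    else:
        lo, hi = a + 1, a + upstream_bp
        truncated = hi > clen
        hi = min(hi, clen)
        seq = reverse_complement(genome.slice(g.chrom, lo, hi)) if lo <= hi else ""
    return Promoter(gene_id=g.gene_id, seq=seq, truncated=truncated)
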