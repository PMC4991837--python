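"""Synthetic cohorts with planted, machine-readable ground truth.

Every stage of the pipeline is testable offline against data this module
generates: proteins carrying heptamer + zinc-finger domains of known
subgroup, gene models with introns of planned phase and PR/VQR type inside
the domain-coding region, promoters with planted cis-elements per
responsiveness category, chromosomes with planted tandem clusters, and an
RPKM matrix with designated peak tissues.

Recoverability is engineered, not hoped for: protein flanks exclude the
motif-forming residues (W, C), finger spacers additionally exclude H,
promoter backgrounds are scrubbed of chance cis-element matches on both
strands, and the peak-tissue effect is applied as ``effect x max(other
tissues)`` so any effect >1 is recovered deterministically. Reverse
translation uses a fixed most-frequent-codon table. Regeneration from
(seed, params) is byte-identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import promoter_cis
from .genome_io import GeneModel, Genome, TranscriptModel, reverse_complement
from .phylo import Alignment

# fixed reverse-translation table (one codon per residue)
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTG",
}
STOP = "TAA"

FLANK_AA = "ADEFGHIKLMNPQRSTVY"  # 20 aa minus W and C
FILLER_AA = "ADEFGIKLMNPQRSTVY"  # additionally minus H (finger spacers)
PHOSPHO_SAFE_AA = "ADEGNQYMHW"  # no S/T/P (sites), K/R (D-motif), F (F-site)

GROUP_LABELS = ("Ia", "Ib", "IIa", "IIb", "IIc", "IId", "IIe", "III", "IV")

#: family composition of a rice-like WRKY survey (97 genes)
DEFAULT_GROUP_COUNTS = {
    "Ia": 11, "Ib": 2, "IIa": 4, "IIb": 7, "IIc": 22,
    "IId": 7, "IIe": 11, "III": 28, "IV": 5,
}

#: heptamer variants planted per subgroup (the rest get canonical WRKYGQK)
DEFAULT_VARIANT_PLAN = {
    "IIc": ["WRKYGKK", "WRKYGKK", "WRKYGKK", "WRKYGKK", "WRKYGKK",
            "WKKYGQK", "WRMCGQK"],
    "III": ["WRKYGEK"] * 6,
    "Ib": ["WRKYGLK"],  # paired with WVKYGQK on the second domain
}


def _rand(rng: np.random.Generator, alphabet: str, n: int) -> str:
    idx = rng.integers(0, len(alphabet), n)
    lut = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return lut[idx].tobytes().decode()


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def _finger_seq(rng: np.random.Generator, ftype: str, spacer1: int,
                spacer2: int, trailing: str) -> str:
    pad = spacer2 - len(trailing)
    last = "H" if ftype == "C2H2" else "C"
    return ("C" + _rand(rng, FILLER_AA, spacer1) + "C" + trailing
            + _rand(rng, FILLER_AA, pad) + "H" + _rand(rng, FILLER_AA, 1)
            + last)


def _finger_plan(label: str, rng: np.random.Generator, terminal: str = "sole",
                 mismatches: int = 0) -> tuple[str, int, int, str]:
    """(type, spacer1, spacer2, trailing) for a subgroup-consistent finger."""
    if label == "IIa":
        trailing = "PVKKK" + ("L" if rng.integers(2) else "V") + "Q"
        spec = ("C2H2", 5, 23, trailing)
    elif label == "IIb":
        spec = ("C2H2", 5, 23, "PVRKQVQ")
    elif label == "IIc":
        spec = ("C2H2", 4, 22, _rand(rng, FILLER_AA, 4) + "KVE")
    elif label == "IId":
        spec = ("C2H2", 5, 23, "PARKHVE")
    elif label == "IIe":
        trailing = ("PARK" + ("Q" if rng.integers(2) else "M") + "V"
                    + ("E" if rng.integers(2) else "D"))
        spec = ("C2H2", 5, 23, trailing)
    elif label == "III":
        spec = ("C2HC", int(rng.integers(5, 8)), 23,
                _rand(rng, FILLER_AA, 4) + "RVE")
    elif label == "Ia":
        tail = "HVE" if terminal == "C" else _rand(rng, FILLER_AA, 3)
        spec = ("C2H2", 4, 22, _rand(rng, FILLER_AA, 4) + tail)
    elif label == "Ib":
        spec = ("C2HC", int(rng.integers(5, 8)), 23,
                _rand(rng, FILLER_AA, 4) + "HVE")
    else:
        raise ValueError(f"no finger template for label {label!r}")
    if mismatches:
        ftype, s1, s2, trailing = spec
        # avoid the sole position discriminating IId from IIe (index 4,
        # H vs Q/M): a substitution there is genuinely ambiguous at
        # Hamming distance 1
        avoid = {4} if label in ("IId", "IIe") else set()
        candidates = [p for p in range(len(trailing)) if p not in avoid]
        pos = rng.choice(candidates,
                         size=min(mismatches, len(candidates)),
                         replace=False)
        t = list(trailing)
        for p in pos:
            # G sits outside every signature's allowed set at every position
            t[p] = "G" if t[p] != "G" else "A"
        spec = (ftype, s1, s2, "".join(t))
    return spec


def _tier(heptamer: str) -> str:
    return "canonical" if re.match(r"W[RK][KR]Y", heptamer) else "variant"


@dataclass
class ProteinTruth:
    label: str
    secondary_label: str | None
    heptamers: list[dict]
    fingers: list[dict]  # incl. the generating segments (linker, signature)
    domain_spans: list[list[int]]  # residue spans, 0-based end-exclusive
    variant_heptamer: bool


def gen_protein(
    label: str,
    rng: np.random.Generator | int,
    heptamers: list[str] | None = None,
    iv_mode: str | None = None,
    mismatches: int = 0,
) -> tuple[str, ProteinTruth]:
    """One protein of the requested group with planted domain truth.

    Group I labels get two domains, group IV a deliberately broken one
    (``iv_mode``: ``"no_finger"`` keeps the heptamer and drops the finger,
    ``"finger_only"`` the reverse, leaving an intact finger that supports a
    secondary label). ``mismatches`` plants that many neutral substitutions
    in the trailing signature (for fuzzy-matching checks). Linkers always
    start with a V-Q-R tripeptide, so every complete domain offers both a
    PR target (the heptamer arginine) and a VQR target.
    """
    if label not in GROUP_LABELS:
        raise ValueError(f"unknown label {label!r}")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)

    pieces: list[str] = []
    pos = 0
    hep_truth: list[dict] = []
    fin_truth: list[dict] = []
    spans: list[list[int]] = []
    secondary: str | None = None

    def emit(seq: str) -> int:
        nonlocal pos
        pieces.append(seq)
        start = pos
        pos += len(seq)
        return start

    def emit_domain(hseq: str, fspec: tuple, terminal: str) -> None:
        linker = "VQR" + _rand(rng, FILLER_AA, int(rng.integers(3, 15)))
        ftype, s1, s2, trailing = fspec
        hstart = emit(hseq)
        emit(linker)
        fseq = _finger_seq(rng, ftype, s1, s2, trailing)
        fstart = emit(fseq)
        hep_truth.append({"start": hstart, "sequence": hseq,
                          "tier": _tier(hseq)})
        fin_truth.append({
            "start": fstart, "type": ftype, "spacer1": s1,
            "trailing": trailing, "terminal": terminal,
            "tail_triplet": trailing[4:7],
            "heptamer": hseq, "linker": linker, "signature": fseq,
        })
        spans.append([hstart, fstart + len(fseq)])

    emit(_rand(rng, FLANK_AA, int(rng.integers(15, 60))))
    if label in ("Ia", "Ib"):
        heps = heptamers or ["WRKYGQK", "WRKYGQK"]
        emit_domain(heps[0], _finger_plan(label, rng, "N", mismatches), "N")
        emit(_rand(rng, FLANK_AA, int(rng.integers(40, 90))))
        emit_domain(heps[-1] if len(heps) > 1 else heps[0],
                    _finger_plan(label, rng, "C", mismatches), "C")
    elif label == "IV":
        iv_mode = iv_mode or ("no_finger" if rng.integers(2) else "finger_only")
        if iv_mode == "no_finger":
            hseq = (heptamers or ["WRKYGQK"])[0]
            hstart = emit(hseq)
            hep_truth.append({"start": hstart, "sequence": hseq,
                              "tier": _tier(hseq)})
            spans.append([hstart, hstart + len(hseq)])
        elif iv_mode == "finger_only":
            base = ["IIb", "IIc", "III"][int(rng.integers(3))]
            ftype, s1, s2, trailing = _finger_plan(base, rng)
            fseq = _finger_seq(rng, ftype, s1, s2, trailing)
            fstart = emit(fseq)
            fin_truth.append({
                "start": fstart, "type": ftype, "spacer1": s1,
                "trailing": trailing, "terminal": "sole",
                "tail_triplet": trailing[4:7], "heptamer": "",
                "linker": "", "signature": fseq,
            })
            spans.append([fstart, fstart + len(fseq)])
            secondary = base
        else:
            raise ValueError(f"unknown iv_mode {iv_mode!r}")
    else:
        hseq = (heptamers or ["WRKYGQK"])[0]
        emit_domain(hseq, _finger_plan(label, rng, "sole", mismatches), "sole")
    emit(_rand(rng, FLANK_AA, int(rng.integers(15, 60))))

    seq = "".join(pieces)
    variant = any(h["tier"] == "variant" for h in hep_truth)
    return seq, ProteinTruth(
        label=label, secondary_label=secondary, heptamers=hep_truth,
        fingers=fin_truth, domain_spans=spans, variant_heptamer=variant,
    )


def gen_phospho_protein(rng: np.random.Generator, n_sites: int = 0,
                        n_dmotifs: int = 0, length: int = 120) -> str:
    """Protein over a motif-free background with the requested number of
    minimal MAPK sites and D-motifs planted (for scanner truth tests)."""
    parts = [_rand(rng, PHOSPHO_SAFE_AA, int(rng.integers(5, 15)))]
    for _ in range(n_sites):
        parts.append(("S" if rng.integers(2) else "T") + "P")
        parts.append(_rand(rng, PHOSPHO_SAFE_AA, int(rng.integers(4, 12))))
    for _ in range(n_dmotifs):
        parts.append("KK" + _rand(rng, "ADEGNQ", 3) + "LAL")
        parts.append(_rand(rng, PHOSPHO_SAFE_AA, int(rng.integers(4, 12))))
    s = "".join(parts)
    if len(s) < length:
        s += _rand(rng, PHOSPHO_SAFE_AA, length - len(s))
    return s


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------

@dataclass
class IntronPlanItem:
    kind: str  # "PR" | "VQR" | "plain"
    residue: int | None = None
    phase: int | None = None
    offset: int | None = None  # coding-nt offset; derived for PR/VQR


@dataclass
class SyntheticLocus:
    fragment: str  # chromosome-sense (+) sequence of the gene body
    exons_plus: list[tuple[int, int]]  # 1-based, ascending, local coords
    strand: str
    introns: list[dict]  # planted truth: offset, phase, type, residue


def gen_locus(
    protein: str,
    plans: list[IntronPlanItem],
    rng: np.random.Generator | int,
    strand: str = "+",
    intron_len: tuple[int, int] = (60, 200),
) -> SyntheticLocus:
    """Reverse-translate a protein and insert introns at planned offsets.

    PR plans split the codon of an arginine residue (phase 1 or 2, default
    2); VQR plans insert a phase-0 intron immediately before a valine
    codon. A plan naming a residue that is not R (PR) or V (VQR) is an
    error. Intron sequences are random (no GT-AG constraint is imposed).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    cds = "".join(CODON[aa] for aa in protein) + STOP
    items: list[tuple[int, dict]] = []
    for p in plans:
        if p.kind == "PR":
            phase = p.phase if p.phase is not None else 2
            if phase not in (1, 2):
                raise ValueError("PR introns must be phase 1 or 2")
            if protein[p.residue] != "R":
                raise ValueError(
                    f"PR plan at residue {p.residue} "
                    f"({protein[p.residue]}): not an arginine"
                )
            offset = 3 * p.residue + phase
            items.append((offset, {"offset": offset, "phase": phase,
                                   "type": "PR", "residue": p.residue}))
        elif p.kind == "VQR":
            if protein[p.residue] != "V":
                raise ValueError(
                    f"VQR plan at residue {p.residue} "
                    f"({protein[p.residue]}): not a valine"
                )
            offset = 3 * p.residue
            items.append((offset, {"offset": offset, "phase": 0,
                                   "type": "VQR", "residue": p.residue}))
        elif p.kind == "plain":
            offset = p.offset
            if offset is None:
                offset = int(rng.integers(1, len(cds)))
            items.append((offset, {"offset": offset, "phase": offset % 3,
                                   "type": "none",
                                   "residue": offset // 3}))
        else:
            raise ValueError(f"unknown intron plan kind {p.kind!r}")
    items.sort(key=lambda x: x[0])
    offsets = [o for o, _ in items]
    if len(set(offsets)) != len(offsets):
        raise ValueError("duplicate intron offsets in plan")
    if offsets and not (0 < offsets[0] and offsets[-1] < len(cds)):
        raise ValueError("intron offsets must fall strictly inside the CDS")

    gene_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cursor = 1  # local 1-based
    prev = 0
    for off, meta in items + [(len(cds), None)]:
        chunk = cds[prev:off]
        gene_parts.append(chunk)
        exons.append((cursor, cursor + len(chunk) - 1))
        cursor += len(chunk)
        if meta is not None:
            ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
            gene_parts.append(_rand(rng, "ACGT", ilen))
            cursor += ilen
        prev = off
    gene_seq = "".join(gene_parts)
    if strand == "-":
        L = len(gene_seq)
        fragment = reverse_complement(gene_seq)
        exons_plus = sorted((L - e + 1, L - s + 1) for s, e in exons)
    else:
        fragment = gene_seq
        exons_plus = exons
    return SyntheticLocus(
        fragment=fragment,
        exons_plus=exons_plus,
        strand=strand,
        introns=[meta for _, meta in items],
    )


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _category_plan(category: int, rng: np.random.Generator,
                   wbox_only: bool = False) -> dict[str, int]:
    if category == 1:
        plan = {"SARE": 1 + int(rng.integers(2))}
        if rng.random() < 0.3:
            plan["ABRE"] = 1  # uncoupled: must NOT flip the ABA flag
    elif category == 2:
        if rng.integers(2):
            plan = {"SARE": 1, "ABRE": 2}
        else:
            plan = {"SARE": 1, "ABRE": 1,
                    ("CE1" if rng.integers(2) else "CE3"): 1}
    elif category == 3:
        plan = {"SARE": 1, "DRE": 1}
    elif category == 4:
        plan = {"SARE": 1, "DRE": 1, "ABRE": 1}
    elif category == 5:
        plan = {"SARE": 1, "DRE": 1, "ABRE": 1, "CE1": 1, "WBOX": 1}
    elif category == 6:
        plan = {"WBOX": 1} if wbox_only else {}
    else:
        raise ValueError(f"no such category {category}")
    return plan


def _expected_flags(plan: dict[str, int]) -> dict[str, bool]:
    abre = plan.get("ABRE", 0)
    return {
        "sa": plan.get("SARE", 0) >= 1,
        "aba": abre >= 1 and (plan.get("CE1", 0) + plan.get("CE3", 0) >= 1
                              or abre >= 2 or plan.get("DRE", 0) >= 1),
        "drought": plan.get("DRE", 0) >= 1,
        "wrky": plan.get("WBOX", 0) >= 1,
    }


def _scrub(seq: list[str], rng: np.random.Generator,
           table: promoter_cis.ElementTable) -> list[str]:
    """Re-randomize any window matching a cis-element on either strand."""
    regexes = []
    for cons in table.elements.values():
        regexes.append(re.compile(promoter_cis.iupac_to_regex(cons)))
        regexes.append(re.compile(
            promoter_cis.iupac_to_regex(reverse_complement(cons))))
    for _ in range(200):
        s = "".join(seq)
        dirty = False
        for rx in regexes:
            m = rx.search(s)
            if m:
                dirty = True
                for k in range(m.start(), m.end()):
                    seq[k] = "ACGT"[rng.integers(4)]
        if not dirty:
            return seq
    raise RuntimeError("could not scrub promoter background")


def _concretize(consensus: str, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    out = []
    for c in consensus:
        exp = ambiguous_dna_values[c]
        out.append(exp if len(exp) == 1 else exp[rng.integers(len(exp))])
    return "".join(out)


def gen_promoter(
    plan: dict[str, int],
    rng: np.random.Generator,
    length: int = 1500,
    table: promoter_cis.ElementTable | None = None,
) -> str:
    """Promoter of the given length containing exactly the planted element
    counts (verified by re-scanning; re-drawn on chance collisions)."""
    if table is None:
        table = promoter_cis.ElementTable()
    for _attempt in range(30):
        seq = _scrub(["ACGT"[i] for i in rng.integers(0, 4, length)],
                     rng, table)
        taken: list[tuple[int, int]] = []
        ok = True
        for name in sorted(plan):
            cons = table.elements[name]
            for _ in range(plan[name]):
                for _try in range(100):
                    start = int(rng.integers(0, length - len(cons)))
                    iv = (start, start + len(cons))
                    if all(iv[1] <= s or iv[0] >= e for s, e in taken):
                        break
                else:
                    ok = False
                    break
                taken.append(iv)
                for k, base in enumerate(_concretize(cons, rng)):
                    seq[iv[0] + k] = base
            if not ok:
                break
        if not ok:
            continue
        s = "".join(seq)
        counts = promoter_cis.element_counts(
            promoter_cis.scan_elements(s, table), table)
        if counts == {name: plan.get(name, 0) for name in table.elements}:
            return s
    raise RuntimeError(f"could not realize promoter plan {plan}")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class ClusterPlan:
    chrom_index: int
    n_genes: int
    span: int  # target bp extent; must respect the detection threshold


@dataclass
class CohortConfig:
    group_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    n_chromosomes: int = 12
    promoter_len: int = 1500
    intergenic: tuple[int, int] = (410_000, 600_000)
    cluster_plans: list[ClusterPlan] = field(default_factory=lambda: [
        ClusterPlan(0, 6, 310_000),
        ClusterPlan(4, 4, 225_000),
        ClusterPlan(10, 7, 200_000),
    ])
    promoter_category_weights: dict[int, int] = field(
        default_factory=lambda: {1: 45, 2: 6, 3: 12, 4: 4, 5: 1, 6: 29})
    wbox_only_cat6_weight: int = 5  # of the category-6 share
    tissues: tuple[str, ...] = ("root", "shoot", "flag_leaf", "panicle")
    tissue_scales: dict[str, float] = field(default_factory=lambda: {
        "root": 3.0, "shoot": 1.5, "flag_leaf": 1.2, "panicle": 0.7})
    peak_fractions: dict[str, float] = field(default_factory=lambda: {
        "root": 0.56, "shoot": 0.23, "flag_leaf": 0.20, "panicle": 0.01})
    peak_effect: float = 3.0
    expr_sigma: float = 1.0
    expr_median: float = 8.0
    domain_intron_prob: float = 0.84
    signature_mismatches: int = 0
    max_chromosome_length: int = 50_000_000

    def n_genes(self) -> int:
        return sum(self.group_counts.values())


def scale_counts(counts: dict, n: int) -> dict:
    """Proportional rescale to total n (largest-remainder rounding)."""
    total = sum(counts.values())
    raw = {k: v * n / total for k, v in counts.items()}
    out = {k: int(v) for k, v in raw.items()}
    rem = n - sum(out.values())
    order = sorted(counts, key=lambda k: (out[k] - raw[k], str(k)))
    for k in order[:rem]:
        out[k] += 1
    return out


def scaled_config(n_genes: int, **overrides) -> CohortConfig:
    cfg = CohortConfig(**overrides)
    cfg.group_counts = scale_counts(cfg.group_counts, n_genes)
    return cfg


@dataclass
class SyntheticCohort:
    genome: Genome
    genes: list[GeneModel]
    proteins: dict[str, str]
    expression: pd.DataFrame
    ortho_map: dict[str, str]
    domain_alignment: Alignment
    domain_labels: dict[str, str]  # alignment row id -> group label
    truth: dict
    config: CohortConfig
    seed: int

    def write(self, outdir: str) -> None:
        import os

        from . import genome_io
        from .genome_io import write_fasta, write_gff3

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_gff3(self.genes, os.path.join(outdir, "genes.gff3"))
        write_fasta(self.proteins, os.path.join(outdir, "proteins.fa"))
        self.expression.to_csv(os.path.join(outdir, "expression.tsv"),
                               sep="\t")
        with open(os.path.join(outdir, "ortho_map.tsv"), "w") as fh:
            for gid in sorted(self.ortho_map):
                fh.write(f"{gid}\t{self.ortho_map[gid]}\n")
        write_fasta(
            dict(zip(self.domain_alignment.ids, self.domain_alignment.rows)),
            os.path.join(outdir, "domain_alignment.fa"),
        )
        with open(os.path.join(outdir, "domain_labels.tsv"), "w") as fh:
            for rid in self.domain_alignment.ids:
                fh.write(f"{rid}\t{self.domain_labels[rid]}\n")
        proms = {}
        for g in self.genes:
            proms[g.gene_id] = genome_io.extract_promoter(
                g, self.genome, self.config.promoter_len).seq
        write_fasta(proms, os.path.join(outdir, "promoters.fa"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _default_intron_plans(label: str, truth: ProteinTruth, protein: str,
                          rng: np.random.Generator,
                          domain_intron_prob: float) -> list[IntronPlanItem]:
    plans: list[IntronPlanItem] = []
    spans = truth.domain_spans

    def pr_residue(k: int) -> int:
        # first arginine of the heptamer; variant heptamers without one
        # fall back to the arginine of the linker's V-Q-R tripeptide
        hstart = truth.heptamers[k]["start"]
        hep = truth.heptamers[k]["sequence"]
        if "R" in hep:
            return hstart + hep.index("R")
        return hstart + len(hep) + 2

    if label in ("Ia", "Ib"):
        # PR intron in the C-terminal domain; Ib also in the N-terminal one
        for fi, f in enumerate(truth.fingers):
            if f["terminal"] == "C" or label == "Ib":
                plans.append(IntronPlanItem("PR", residue=pr_residue(fi),
                                            phase=2))
        n_extra = int(rng.integers(3, 6))
    elif label in ("IIa", "IIb"):
        if rng.random() < domain_intron_prob and truth.fingers:
            linker_v = truth.heptamers[0]["start"] + 7  # linker starts V-Q-R
            plans.append(IntronPlanItem("VQR", residue=linker_v))
        n_extra = int(rng.integers(0, 3))
    elif label in ("IIc", "IId", "IIe", "III"):
        if rng.random() < domain_intron_prob and truth.heptamers:
            plans.append(IntronPlanItem("PR", residue=pr_residue(0), phase=2))
        n_extra = int(rng.integers(0, 3))
    else:  # IV
        n_extra = int(rng.integers(0, 3))
    # plain introns strictly outside domain spans (planted type stays none)
    cds_nt = 3 * len(protein) + 3
    forbidden = [(3 * a, 3 * b) for a, b in spans]
    used = {3 * p.residue + (p.phase or 0) for p in plans if p.residue is not None}
    for _ in range(n_extra):
        for _try in range(50):
            off = int(rng.integers(1, cds_nt))
            if off in used or any(a <= off <= b for a, b in forbidden):
                continue
            plans.append(IntronPlanItem("plain", offset=off))
            used.add(off)
            break
    return plans


def gen_cohort(config: CohortConfig | None = None,
               seed: int = 0) -> SyntheticCohort:
    """Full dataset: genome + gene models + proteins + promoters +
    expression + orthologue map, with all truths emitted."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(seed)
    table = promoter_cis.ElementTable()
    n = config.n_genes()

    # --- gene roster ------------------------------------------------------
    labels: list[str] = []
    for lab in GROUP_LABELS:
        labels += [lab] * config.group_counts.get(lab, 0)
    gene_ids = [f"G{i + 1:03d}" for i in range(n)]
    base_total = sum(DEFAULT_GROUP_COUNTS.values())
    variant_plan = {
        lab: v[: max(1, round(len(v) * n / base_total))] if n != base_total
        else list(v)
        for lab, v in DEFAULT_VARIANT_PLAN.items()
    }

    # --- promoter categories ---------------------------------------------
    cat_counts = scale_counts(config.promoter_category_weights, n)
    wbox_only = min(config.wbox_only_cat6_weight, cat_counts.get(6, 0))
    cat_list: list[tuple[int, bool]] = []
    for cat in sorted(cat_counts):
        for k in range(cat_counts[cat]):
            cat_list.append((cat, cat == 6 and k < wbox_only))
    perm = rng.permutation(n)
    cat_by_gene = {gene_ids[i]: cat_list[perm[i]] for i in range(n)}

    # --- peak tissues -----------------------------------------------------
    peak_counts = scale_counts(
        {t: round(1000 * config.peak_fractions[t]) for t in config.tissues},
        n)
    peak_list: list[str] = []
    for t in config.tissues:
        peak_list += [t] * peak_counts[t]
    perm2 = rng.permutation(n)
    peak_by_gene = {gene_ids[i]: peak_list[perm2[i]] for i in range(n)}

    # --- cluster membership (prefer group III, the tandem-expanding group)
    pool = sorted(range(n), key=lambda i: (labels[i] != "III", i))
    cluster_members: dict[str, list[int]] = {}
    used_idx: set[int] = set()
    p = 0
    for ci, plan in enumerate(config.cluster_plans):
        if plan.span > config.max_chromosome_length:
            raise ValueError("cluster plan exceeds chromosome length limit")
        if plan.chrom_index >= config.n_chromosomes:
            raise ValueError("cluster plan names a missing chromosome")
        take = pool[p : p + plan.n_genes]
        if len(take) < plan.n_genes:
            raise ValueError("not enough genes for the cluster plans")
        used_idx.update(take)
        p += plan.n_genes
        cluster_members[f"cluster{ci + 1}"] = take

    # --- proteins and loci ------------------------------------------------
    truth_genes: dict[str, dict] = {}
    proteins: dict[str, str] = {}
    loci: dict[str, SyntheticLocus] = {}
    aln_items: list[tuple[str, str, str, str, str]] = []
    for i, gid in enumerate(gene_ids):
        lab = labels[i]
        heps = None
        if variant_plan.get(lab):
            if lab == "Ib":
                heps = [variant_plan[lab].pop(0), "WVKYGQK"]
            else:
                heps = [variant_plan[lab].pop(0)]
        pseq, ptruth = gen_protein(lab, rng, heptamers=heps,
                                   mismatches=config.signature_mismatches)
        proteins[gid] = pseq
        strand = "+" if rng.integers(2) else "-"
        plans = _default_intron_plans(lab, ptruth, pseq, rng,
                                      config.domain_intron_prob)
        locus = gen_locus(pseq, plans, rng, strand=strand)
        loci[gid] = locus
        cat, wonly = cat_by_gene[gid]
        plan_counts = _category_plan(cat, rng, wonly)
        truth_genes[gid] = {
            "label": lab,
            "secondary_label": ptruth.secondary_label,
            "variant_heptamer": ptruth.variant_heptamer,
            "heptamers": ptruth.heptamers,
            "fingers": [
                {k: f[k] for k in ("start", "type", "spacer1", "trailing",
                                   "terminal", "tail_triplet")}
                for f in ptruth.fingers
            ],
            "domain_spans": ptruth.domain_spans,
            "introns": locus.introns,
            "strand": strand,
            "exon_count": len(locus.exons_plus),
            "promoter": {
                "category": cat,
                "counts": plan_counts,
                "flags": _expected_flags(plan_counts),
            },
            "peak_tissue": peak_by_gene[gid],
            "cluster": None,
        }
        for f in ptruth.fingers:
            if not f["heptamer"]:
                continue
            suffix = {"N": ".N", "C": ".C"}.get(f["terminal"], "")
            aln_items.append((gid + suffix, lab, f["heptamer"], f["linker"],
                              f["signature"]))

    # --- domain alignment (heptamer | padded linker | padded signature) ---
    max_link = max((len(x[3]) for x in aln_items), default=0)
    max_sig = max((len(x[4]) for x in aln_items), default=0)
    aln_ids = [x[0] for x in aln_items]
    aln_rows = [
        x[2] + x[3].ljust(max_link, "-") + x[4].ljust(max_sig, "-")
        for x in aln_items
    ]
    domain_alignment = Alignment(ids=aln_ids, rows=aln_rows)
    domain_labels = {x[0]: x[1] for x in aln_items}

    # --- chromosomes ------------------------------------------------------
    chrom_ids = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    cluster_of_idx: dict[int, str] = {}
    for name, mem in cluster_members.items():
        for i in mem:
            cluster_of_idx[i] = name
    assignment: dict[str, list[int]] = {c: [] for c in chrom_ids}
    for ci, plan in enumerate(config.cluster_plans):
        assignment[chrom_ids[plan.chrom_index]] += (
            cluster_members[f"cluster{ci + 1}"])
    rest = [i for i in range(n) if i not in used_idx]
    for k, i in enumerate(rest):
        assignment[chrom_ids[k % config.n_chromosomes]].append(i)

    records: dict[str, str] = {}
    genes: list[GeneModel] = []
    for chrom in chrom_ids:
        idxs = assignment[chrom]
        cluster_first = [i for i in idxs if i in cluster_of_idx]
        others = [i for i in idxs if i not in cluster_of_idx]
        parts: list[str] = []
        cursor = 0
        prev_cluster: str | None = None
        for i in cluster_first + others:
            gid = gene_ids[i]
            locus = loci[gid]
            cname = cluster_of_idx.get(i)
            if cname is not None and cname == prev_cluster:
                plan = config.cluster_plans[
                    int(cname.removeprefix("cluster")) - 1]
                budget = plan.span // max(1, plan.n_genes)
                gap = int(rng.integers(2000, max(3000, budget - 8000)))
            else:
                gap = int(rng.integers(*config.intergenic))
            prev_cluster = cname
            prom = gen_promoter(
                dict(truth_genes[gid]["promoter"]["counts"]), rng,
                config.promoter_len, table)
            spacer = _rand(rng, "ACGT", gap)
            if locus.strand == "+":
                parts += [spacer, prom, locus.fragment]
                gstart = cursor + gap + config.promoter_len + 1
                cursor += gap + config.promoter_len + len(locus.fragment)
            else:
                parts += [spacer, locus.fragment, reverse_complement(prom)]
                gstart = cursor + gap + 1
                cursor += gap + len(locus.fragment) + config.promoter_len
            gend = gstart + len(locus.fragment) - 1
            exons = [(gstart + s - 1, gstart + e - 1)
                     for s, e in locus.exons_plus]
            if locus.strand == "-":
                exons = exons[::-1]  # translation order
            t = TranscriptModel(
                transcript_id=gid + ".t1", gene_id=gid, chrom=chrom,
                strand=locus.strand, exons=exons, cds=list(exons),
                protein_id=gid,
            )
            genes.append(GeneModel(gene_id=gid, chrom=chrom,
                                   strand=locus.strand, span=(gstart, gend),
                                   transcripts=[t]))
            truth_genes[gid]["chrom"] = chrom
            truth_genes[gid]["span"] = [gstart, gend]
            truth_genes[gid]["cluster"] = cname
        parts.append(_rand(rng, "ACGT", int(rng.integers(10_000, 30_000))))
        records[chrom] = "".join(parts)
        if len(records[chrom]) > config.max_chromosome_length:
            raise ValueError(f"{chrom} exceeds the chromosome length limit")
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    genome = Genome(records=records)

    # --- expression -------------------------------------------------------
    tissues = list(config.tissues)
    base = rng.lognormal(np.log(config.expr_median), config.expr_sigma,
                         size=(n, len(tissues)))
    for j, t in enumerate(tissues):
        base[:, j] *= config.tissue_scales[t]
    for i, gid in enumerate(gene_ids):
        pt = tissues.index(peak_by_gene[gid])
        others = [j for j in range(len(tissues)) if j != pt]
        base[i, pt] = config.peak_effect * base[i, others].max()
    expression = pd.DataFrame(np.round(base, 3), index=gene_ids,
                              columns=tissues)
    expression.index.name = "gene_id"

    ortho_map = {gid: f"W{i + 1:03d}" for i, gid in enumerate(gene_ids)}

    truth = {
        "seed": seed,
        "params": _config_dict(config),
        "genes": truth_genes,
        "clusters": {name: [gene_ids[i] for i in mem]
                     for name, mem in cluster_members.items()},
        "group_counts": dict(config.group_counts),
        "baseline_tissue": "panicle",
    }
    return SyntheticCohort(
        genome=genome, genes=genes, proteins=proteins,
        expression=expression, ortho_map=ortho_map,
        domain_alignment=domain_alignment, domain_labels=domain_labels,
        truth=truth, config=config, seed=seed,
    )


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["cluster_plans"] = [asdict(p) for p in config.cluster_plans]
    return d
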