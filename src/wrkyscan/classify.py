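"""Group/subgroup classification of WRKY proteins from assembled domains.

The family's closed label set is {Ia, Ib, IIa, IIb, IIc, IId, IIe, III, IV}:
two complete domains make group I (Ia with C2H2 fingers, Ib with C2HC);
one complete domain with a C2HC finger is group III; one complete domain
with a C2H2 finger falls into a group II subgroup determined by the spacer
between the two cysteines and the residues trailing the second cysteine
(IIa: CX5C-PVKKK(L/V)Q, IIb: CX5C-PVRKQVQ, IIc: CX4C, IId: CX5C-PARKHVE,
IIe: CX5C-PARK(Q/M)V(E/D)); no complete domain is group IV, optionally
carrying a secondary label read off any intact finger.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .domain_scan import WRKYDomain, ZincFinger
from .genome_io import GeneModel

LABELS = ("Ia", "Ib", "IIa", "IIb", "IIc", "IId", "IIe", "III", "IV")


def _sig(pattern: str) -> tuple[frozenset[str], ...]:
    """Parse 'PARK(Q/M)V(E/D)' into per-position allowed-residue sets."""
    out: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "(":
            j = pattern.index(")", i)
            out.append(frozenset(pattern[i + 1 : j].replace("/", "")))
            i = j + 1
        else:
            out.append(frozenset(pattern[i]))
            i += 1
    return tuple(out)


@dataclass
class SignatureRule:
    label: str
    spacer1: int
    trailing: tuple[frozenset[str], ...]


@dataclass
class ClassifierRules:
    """Subgroup signature table plus the fuzzy-match budget.

    Fuzzy matching is Hamming distance over positions, position-class
    aware: a residue inside a position's allowed set (e.g. L or V at the
    (L/V) position) is never counted as a mismatch.
    """

    signatures: list[SignatureRule] = field(default_factory=lambda: [
        SignatureRule("IIa", 5, _sig("PVKKK(L/V)Q")),
        SignatureRule("IIb", 5, _sig("PVRKQVQ")),
        SignatureRule("IId", 5, _sig("PARKHVE")),
        SignatureRule("IIe", 5, _sig("PARK(Q/M)V(E/D)")),
    ])
    iic_spacer1: int = 4
    max_mismatches: int = 1

    @classmethod
    def from_table(cls, rows: list[dict], max_mismatches: int = 1,
                   iic_spacer1: int = 4) -> "ClassifierRules":
        sigs = [SignatureRule(r["label"], int(r["spacer1"]), _sig(r["trailing"]))
                for r in rows]
        return cls(signatures=sigs, iic_spacer1=iic_spacer1,
                   max_mismatches=max_mismatches)


@dataclass
class GroupAssignment:
    gene_id: str
    label: str
    secondary_label: str | None = None
    evidence: list[str] = field(default_factory=list)


def _mismatches(trailing: str, rule: SignatureRule) -> int | None:
    if len(trailing) < len(rule.trailing):
        return None
    return sum(
        1 for aa, allowed in zip(trailing, rule.trailing) if aa not in allowed
    )


def _classify_finger(f: ZincFinger, rules: ClassifierRules,
                     evidence: list[str]) -> str:
    if f.type == "C2HC":
        evidence.append("C2HC finger -> III")
        return "III"
    trailing = f.trailing
    for rule in rules.signatures:  # exact pass
        if f.spacer1 == rule.spacer1 and _mismatches(trailing, rule) == 0:
            evidence.append(f"exact signature match {rule.label} ({trailing})")
            return rule.label
    best: tuple[int, str] | None = None
    for rule in rules.signatures:  # fuzzy pass, table order breaks ties
        if f.spacer1 != rule.spacer1:
            continue
        mm = _mismatches(trailing, rule)
        if mm is not None and mm <= rules.max_mismatches:
            if best is None or mm < best[0]:
                best = (mm, rule.label)
    if best is not None:
        evidence.append(
            f"fuzzy signature match {best[1]} ({trailing}, {best[0]} mismatch)"
        )
        return best[1]
    if f.spacer1 == rules.iic_spacer1:
        evidence.append(f"CX{rules.iic_spacer1}C spacer -> IIc")
        return "IIc"
    evidence.append(
        f"warning: CX{f.spacer1}C C2H2 finger with unrecognized trailing "
        f"{trailing!r}; defaulted to IIe"
    )
    return "IIe"


def classify_protein(
    domains: list[WRKYDomain],
    rules: ClassifierRules | None = None,
    gene_id: str = "",
) -> GroupAssignment:
    """Apply the group/subgroup rules to one protein's assembled domains."""
    if rules is None:
        rules = ClassifierRules()
    if not domains:
        raise ValueError(f"{gene_id or 'protein'}: not a WRKY protein "
                         "(no domains)")
    evidence: list[str] = []
    complete = [d for d in domains if d.complete]
    if len(complete) >= 2:
        types = [d.finger.type for d in complete]
        if all(t == "C2H2" for t in types):
            evidence.append(f"{len(complete)} complete C2H2 domains -> Ia")
            label = "Ia"
        elif all(t == "C2HC" for t in types):
            evidence.append(f"{len(complete)} complete C2HC domains -> Ib")
            label = "Ib"
        else:
            cterm = types[-1]
            label = "Ia" if cterm == "C2H2" else "Ib"
            evidence.append(
                f"mixed finger types {types}; labeled {label} by the "
                "C-terminal domain"
            )
        return GroupAssignment(gene_id, label, evidence=evidence)
    if len(complete) == 1:
        label = _classify_finger(complete[0].finger, rules, evidence)
        return GroupAssignment(gene_id, label, evidence=evidence)
    # no complete domain: group IV, secondary label from any intact finger
    evidence.append("no complete WRKY domain -> IV")
    secondary = None
    for d in domains:
        if d.finger is not None:
            secondary = _classify_finger(d.finger, rules, evidence)
            evidence.append(f"secondary label {secondary} from intact finger")
            break
    if secondary is None:
        evidence.append("no intact zinc finger; unclassifiable beyond IV")
    return GroupAssignment(gene_id, "IV", secondary_label=secondary,
                           evidence=evidence)


def select_isoform(g: GeneModel, proteins: dict[str, str]) -> str:
    """Pick one isoform per locus: longest protein, ties to the
    lexicographically smallest transcript id. Returns the chosen
    transcript's protein id (falling back to the transcript id)."""
    candidates = [t for t in g.transcripts if t.transcript_id in proteins]
    if not candidates:
        raise ValueError(f"{g.gene_id}: no translatable transcript")
    best = min(
        candidates,
        key=lambda t: (-len(proteins[t.transcript_id]), t.transcript_id),
    )
    return best.protein_id or best.transcript_id


def tally_groups(assignments: list[GroupAssignment]) -> dict[str, int]:
    return dict(Counter(a.label for a in assignments))


def tail_triplet_report(
    assignments: list[GroupAssignment],
    fingers_by_gene: dict[str, list[ZincFinger]],
) -> pd.DataFrame:
    """One row per classified finger with its X-V-E-style tail triplet.

    Fingers too short to yield a full triplet are flagged with an empty
    triplet rather than dropped.
    """
    rows = []
    for a in assignments:
        for f in fingers_by_gene.get(a.gene_id, []):
            triplet = f.tail_triplet
            flagged = len(triplet) < 3
            rows.append({
                "gene_id": a.gene_id,
                "label": a.label,
                "tail_triplet": "" if flagged else triplet,
                "flagged": flagged,
            })
    return pd.DataFrame(rows, columns=["gene_id", "label", "tail_triplet",
                                       "flagged"])
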