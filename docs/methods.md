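# Methods

This note documents the models and procedures wrkyscan implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make every result a pure
function of its inputs.

## Domain model and classification

A WRKY domain is detected compositionally: a heptamer core motif and a
zinc finger, assembled by proximity.

- **Heptamer scan.** Canonical hits match the consensus `W(R/K)(K/R)Y`
  and are reported as 7-mers. A configurable variant table (default
  `WSKY`, `WVKY`, `WRMC`) admits 4-mers outside the consensus, but a
  variant hit is only believed when a zinc finger follows within the
  linkage window (*tier gate*). Rationale: published surveys accept such
  loci as family members when the finger is intact, and the gate keeps
  the false-positive rate of a 4-letter motif at zero on background
  sequence.
- **Zinc-finger scan.** The admissible geometries are C2H2
  `C-X4-5-C-X22-23-H-X1-H` and C2HC `C-X5-7-C-X23-H-X1-C`. At each
  cysteine the geometries are tried shortest-spacer-first, C2H2 before
  C2HC; the scan is non-overlapping left to right. This makes the hit
  list deterministic and means a planted finger is recovered with its
  planted geometry whenever its internal spacers avoid C and H.
- **Assembly.** Each heptamer pairs with the nearest unused finger whose
  first cysteine lies 0–30 residues (`linkage_window`, configurable)
  downstream of the heptamer end. The window is a design choice — the
  literature never states one — chosen to span observed linker lengths
  while keeping cross-domain mispairing impossible in two-domain
  proteins, whose domains sit much farther apart.
- **Classification.** Two complete domains ⇒ group I (Ia if the fingers
  are C2H2, Ib if C2HC; mixed fingers are labeled by the C-terminal
  domain, which the field treats as functionally definitive). One
  complete domain with C2HC ⇒ III. One complete domain with C2H2 ⇒ a
  group II subgroup by the spacer and the 7 residues trailing the second
  cysteine: exact signature match first, then fuzzy match (Hamming ≤ 1
  by default, position-class aware so L/V, Q/M, E/D alternations never
  count as mismatches), then CX4C ⇒ IIc regardless of trailing. A
  single-C2H2 CX5C protein matching nothing within budget is labeled IIe
  with a warning in the evidence trail rather than given a new label —
  the label set stays closed. No complete domain ⇒ IV, with a secondary
  label read off any intact finger by the same table.
- **Tail triplet.** The X-V-E-style window used for IId/IIe/Ia
  comparisons (HVE / KVE / RVE …) is extracted at a configurable offset
  (default 4) after the second cysteine, which reproduces the intended
  triplet for every signature subgroup.

A genuinely ambiguous case: IId (`PARKHVE`) and IIe (`PARK(Q/M)V(E/D)`)
differ at exactly one informative position, so a substitution there is
equidistant from both rules at fuzzy budget 1; the tie breaks by table
order (IId). The classification-recovery guarantee therefore applies to
mismatches at non-discriminating positions, which is how the generator
plants them.

## Gene structure

Intron phase is `coding_offset mod 3`, with the offset counted in
translation orientation; coordinates are 1-based inclusive externally
(GFF3) and 0-based half-open internally. Typing inside domain-coding
regions: a phase-1/2 intron splitting an arginine codon is **PR**; a
phase-0 intron immediately 5' of a valine codon is **VQR**, by default
requiring the V-Q-R context (relaxable, since the type name is the only
published definition). PR detection accepts any in-domain arginine and
reports the offset so downstream analysis can restrict to the conserved
position. UTR introns are reported but never typed. Because "domains
harbouring neither intron type" can be counted per domain or per gene,
both granularities are exposed.

## Motif and promoter scans

The phospho-motif grammar ships as data: minimal site `(S/T)P`, preferred
context `P-X-(S/T)-P`, D-motif `(K/R)1-3 X1-6 Φ X Φ` (Φ ∈ L/I/V), F-site
`F-X-F-P`. Within a class, matching is *leftmost, then longest at that
start*, non-overlapping; the matcher enumerates segment lengths
explicitly rather than trusting regex backtracking order, which is not
longest-at-start for the D-motif. Overlaps across classes are allowed.
Published surveys defer the exact patterns to their citations, so the
grammar is config-overridable.

Promoter elements are IUPAC consensi scanned on both strands (defaults:
ABRE `ACGTG(G/T)C`, CE1 `TGCCACCGG`, CE3 `ACGCGTGTC`, DRE `(A/G)CCGAC`,
SARE `TTCGACC`, W-box `TTGAC(C/T)`); the table is data so other published
motifs can be dropped in. Responsiveness flags implement the coupling
rule: ABA requires ABRE together with a CE, a second ABRE, or a DRE; SA,
drought and WRKY-regulation are single-element flags. The six-category
rule table (data, evaluated top-down: 5 = all element classes, 4 =
SA+coupled-ABRE+DRE, 2 = SA+coupled-ABRE, 3 = SA+DRE without coupled
ABRE, 1 = SA, else 6) is a reconstruction from worked category examples,
since the originating supplementary definitions are not public.

The promoter window is 1,500 bp upstream of the CDS start by default
(configurable; an anchor at the gene-span boundary is also available).
No published window length exists for this family's surveys; 1–2 kb is
the field's usual choice.

## Clusters and cross-genome comparison

A tandem-duplication cluster is a maximal run of consecutive family genes
whose genomic extent (first member start to rightmost member end) is ≤
400 kb with ≥ 4 members — both thresholds explicit parameters, matching
the published rule. Extent uses the running maximum of member ends so
the definition stays monotone when genes overlap; for non-overlapping
genes this equals the naive first-start-to-last-end span. Detection is
verified against exhaustive window enumeration. Cluster members sharing a
group label with another member are the "tandem duplicate" set. Clusters
from two genomes match when they share ≥ 2 orthologue names; order
identity tolerates whole-cluster reversal (assembly orientation is
arbitrary); many-to-many matches are reported and flagged, not resolved.

## Expression summaries

The baseline tissue is the arg-min of per-tissue means (ties → column
order, logged). `fraction_below` uses strict `<`; the expressed set uses
inclusive `≥` in at least one tissue, sorted ascending by the
highest-mean tissue with ties broken by gene id. The 50-RPKM default
threshold is also *recomputed*: the module reports the smallest grid
value in {10, 20, 50, 100} for which more than 95% of genes fall below it
in the baseline tissue.

## Phylogeny

Distances are p-distances with pairwise gap deletion by default (complete
deletion available). NJ uses the standard Q-criterion; ties break toward
the pair whose sorted minimum leaf labels compare lowest, making the
topology a pure function of the matrix; negative branch-length estimates
are clamped to zero and counted on the tree object. Bootstrap resamples
columns with replacement from a seeded generator; support is the
percentage of replicates containing the original bipartition, attached as
internal node labels. The N- and C-terminal domains of two-domain
proteins enter the domain alignment as separate `.N`/`.C` rows. Clade
composition reports, for each group or union (Ia, IIa+b, IIc, IId+e,
III+Ib), whether an edge isolates exactly that label set, and otherwise
the minimum number of maximal pure subtrees covering it.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of a rice-scale family
survey: 97 genes with group composition Ia 11, Ib 2, IIa 4, IIb 7,
IIc 22, IId 7, IIe 11, III 28, IV 5; heptamer variants planted per
subgroup (WRKYGKK/WKKYGQK/WRMCGQK in IIc, WRKYGEK in III, WRKYGLK +
WVKYGQK in Ib); 12 chromosomes with three planted clusters of 6, 4 and 7
genes within 310/225/200 kb drawn preferentially from group III; PR
introns (phase 2) in C-terminal group-I domains and in IIc/IId/IIe/III,
VQR introns in IIa/IIb, at 0.84 per-gene probability for single-domain
groups; promoter categories weighted 45/6/12/4/1/29 so that 68 genes are
SA-responsive, 11 ABA-responsive and 6 W-box-bearing at the 97-gene
scale; expression log-normal (σ = 1, median 8 RPKM) with tissue scales
root 3.0 / shoot 1.5 / flag leaf 1.2 / panicle 0.7 and peak-tissue
fractions 0.56/0.23/0.20/0.01. The panicle scale makes the published
baseline choice reproducible as a computation: >95% of genes fall below
50 RPKM in panicle while 20 RPKM does *not* satisfy the criterion.

Recoverability is engineered: protein flanks exclude W and C, finger
spacers additionally exclude H, promoter backgrounds are scrubbed of
chance element matches on both strands and re-verified after planting,
and the peak-tissue value is set to `effect × max(other tissues)` so any
effect > 1 is recovered deterministically. Reverse translation uses a
fixed most-frequent-codon table; regeneration from (seed, params) is
byte-identical.

What passing on this data does **not** show: the generator does not mimic
rice codon usage, repeat content, intron length distributions, GT–AG
splice sites, alignment uncertainty (domain rows are constructed aligned,
not re-aligned), or realistic amino-acid composition — chance MAPK sites
are therefore much rarer than in real proteins (the cohort site-bearing
fraction is ~43% against ~90% in real surveys), and domain trees on
synthetic cohorts are noisier than on curated alignments because random
linkers dominate the signal. Results on real genomes will differ in
exactly those respects.

## Problem sizes

The default test suite and the acceptance script run: a 200-gene recovery
cohort, 1,000 random layouts (n ≤ 50) for the cluster oracle, proteins ≤
200 aa for the motif oracle, 100 additive matrices each at 4–6 taxa for
NJ, 10,000 random offsets for the phase identity, the full 2^6 flag truth
table, and a 16-taxon bootstrap at B = 200 — sizes chosen so the whole
suite completes in well under a minute while every check remains
exhaustive or oracle-backed at its scale.
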