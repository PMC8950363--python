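# Methods

This note documents the models, rules and numerical choices behind
`igloci`, the assumptions they rest on, and what the synthetic-locus tests
do and do not demonstrate about real data.

## Scope and inputs

The package implements the *computational* layer of IG locus curation.
Structural gene models — which intervals are L-PART1, V-INTRON, V-REGION,
RS, and so on — are inputs (FASTA + GFF3/TSV), because locus delimitation
by flanking-gene homology and exon-structure discovery are curation work
performed upstream with alignment tooling. Given those models, everything
downstream is computed here: subgroup partition, nomenclature, allele
matching, functionality, numbering, RS consensus/canonicality, and
promoter architecture.

Coordinates are 1-based inclusive throughout, matching GenBank/GFF3
convention. Loci are always handled in their own 5'→3' orientation; a
locus on the chromosome's reverse strand is reverse complemented once at
extraction, and genes transcribed against the locus direction are marked
`inverted` and have their label sequences reverse complemented on demand,
never at parse time. Locus spans in kb round half up, which reproduces
the published spans of all three loci from their chromosome coordinates.
N-runs of any length ≥ 1 count as assembly gaps.

## Sequence identity and subgroup clustering

Subgroup membership uses nucleotide identity from a global pairwise
alignment of V-REGION cores: match +1, mismatch 0, affine internal gaps
(open 10, extend 0.5), terminal gaps free. Identity is matches divided by
alignment columns excluding terminal-gap columns, so internal indels count
against identity but length overhangs do not. This "maximize matches"
scale makes unrelated sequences align end-to-end with low identity rather
than retreating to short high-identity fragments, which is the behavior a
clustering threshold needs. The alignment engine is
`Bio.Align.PairwiseAligner`; an independent test verifies identity values
on instances whose optimal alignment is known by construction.

The > 75% rule is strict (exactly 75.0% does not join), and the relation
is closed by single linkage: two genes are in one subgroup if a chain of
pairs each above threshold connects them. Single linkage makes
"assigned to the same subgroup" an equivalence without arbitrary
exclusions; the per-pair identities are retained as auditable evidence.
Clustering is order-independent (components are sorted by smallest member
name). Pseudogenes matching no subgroup can be assigned to clans against
user-supplied exemplar sequences; clan exemplars are configuration, not
shipped truth.

## Nomenclature

V genes are numbered by locus position 3'→5' (most 3' gene gets the
smallest hyphen number), D and J genes 5'→3', C genes by isotype with an
ordinal when an isotype recurs. Duplicated genes share one position
number and the second occurrence takes a terminal `D`; the pipeline
detects duplication as adjacent same-subgroup genes with identical cores.
Unlocalized genes take provisional `S` numbers in directory insertion
order. Subgroup numbers default to the rank of each subgroup's most 3'
localized member; they can be pinned externally when an established
numbering (e.g. by cross-species homology) must be preserved.

Allele matching is exact: 100% core identity to a stored allele returns
that allele's name with provenance "literature"; otherwise the next free
`*NN` is assigned with provenance "reference". Matching is per mapped
gene, mirroring how reference directories are keyed.

## Functionality calling

Pseudogene-level defects (in-frame stop, frameshift, missing initiation
codon, truncated core) dominate ORF-level defects (splice-site defect,
non-canonical RS, promoter defect, replaced pivotal residue); an allele
with neither is functional. Checks that do not apply to a gene type pass
`None` and are ignored — D/J/C genes have no initiation-codon or splice
requirement, and D-REGIONs are not translated at all (their reading frame
is set by rearrangement). For V genes a core length not divisible by 3
is treated as a frameshift; this is exact under the generator's
codon-complete V-REGION convention and conservative on real data, where a
germline CDR3 may end mid-codon. An unresolvable frame raises an error
rather than silently calling P.

Functionality and RS canonicality are mutually dependent (the consensus is
taken over functional genes), so classification runs twice: coding-level
defects first define a provisional functional set; the consensus and
occurrence counts computed from that set then settle the RS clause. This
mirrors how a curator bootstraps locus consensus from the clearly intact
genes.

Genes whose alleles disagree get the mixture labels FO and FP; OP and FOP
extend the same symmetry to combinations that published tables never
needed.

## IMGT unique numbering

The full profile-based numbering algorithm is not reimplemented; numbering
here is template-based. A template fixes the framework gap pattern
(kappa-type: 26 FR1 residues, FR3 gaps at 73/81/82; lambda-type: 25 FR1
residues with a gap at 10; heavy-type default: FR1 gap at 10, FR3 gap at
73 — all user-editable configuration). Region boundaries are then
delimited by anchors: the C23 slot is structural (fixed by the template),
W41 is the first tryptophan at a feasible CDR1 offset, and C104 is the
last cysteine compatible with the CDR2/FR3/CDR3 window constraints
(windows 12/10/13 at positions 27–38, 56–65, 105–117). CDRs shorter than
their window are gapped middle-out — residues pack from both window ends,
ceil(n/2) at the front — and framework insertions (15A, 20A, 50A/50B) are
per-allele configuration with lettered labels that sort between their
anchors. When an anchor is absent (e.g. a replaced W41), an explicit CDR
length triplet — typically that of a successfully numbered subgroup
sibling — delimits instead, so the replaced residue still lands on its
grid position and fails the conserved-residue check rather than crashing
numbering.

The pivotal-residue check requires C at 23 and 104, W at 41 and membership
of the classical hydrophobic class {A,V,L,I,M,F,W,C,Y} at 89; a missing or
gapped position is reported "missing" and fails. CDR-length tables count
first alleles only and exclude out-of-frame pseudogenes, so a subgroup
whose genes are all out-of-frame P is simply absent from the table.

## Recombination signals

Spacer classes follow the 12/23 rule per locus and gene type (heavy V 23,
heavy D 12 on both flanks, heavy J 23; kappa V 12 / J 23; lambda V 23 /
J 12), configurable. Extraction uses explicit RS labels when present and
otherwise takes the heptamer as abutting the core region with the
configured spacer between heptamer and nonamer, with strand handled
through the gene's orientation. Consensus is per-column plurality over
functional-gene signals; ties resolve to the lexicographically smallest
base and are reported, because a locus can legitimately carry two
consensus variants — when it does, the tolerance clause of the
canonicality rule tests against all variants and takes the minimum
mismatch count. Position frequency matrices are exported as tidy tables
(position × base → count) consumable by any logo renderer; image
rendering is out of scope.

## Promoter architecture

Offsets count nucleotides upstream of the A of the initiation codon, to
the element's 5' base, so increasing offset walks 3'→5'. Element
definitions are IUPAC patterns (degenerate positions never count as
mismatches) or rules: the TATA box is a maximal A/T-only run of length
≥ 5 (no single consensus exists; the run length is reported), and the
pyrimidine-rich region is any maximal interval of length ≥ 10 with C/T
fraction ≥ 0.8 over its 10-nt windows, trimmed to start and end on a
pyrimidine (both cutoffs configurable). The heavy-chain heptanucleotide
has no published consensus, so its definition ships empty and is skipped
until one is supplied. The kappa CCCT element accepts the TCCT variant
when scanning kappa subgroup 5.

`annotate_promoter` assigns the locus's canonical element chain greedily
3'→5' (heavy: TATA, octamer, heptanucleotide, pyrimidine-rich; light:
TATA, CCCT, decamer, CCCT, pentadecamer), choosing within each search
window the match closest to the window center with ties going 3'-ward,
and requiring offsets to increase strictly. Missing elements are data,
not errors. The E-box (CAnnTG) is deliberately not part of the greedy
chain: it is short enough to occur every ~64 nt by chance and its
documented positions lie *inside* the pentadecamer or between TATA and
ATG, so it is scanned separately (`scan_element`) and the pentadecamer's
inner E-box is checked by pattern containment. A motif-table self-check
asserts that the octamer is the reverse complement of the decamer's last
eight bases.

## The synthetic-locus generator

The generator emulates the structures the pipeline must recognize: V units
are promoter (500 bp) + L-PART1 (46 nt starting ATG) + V-INTRON (GT…AG) +
L-PART2 (11 nt) + V-REGION + heptamer/spacer/nonamer; D units carry RS on
both flanks with heptamers facing the D-REGION; J units carry
nonamer–spacer–heptamer upstream; C units are single stop-free ORFs.
L-PART1+L-PART2 lengths are chosen so the V-REGION starts on a codon
boundary. Subgroup scaffolds are random V-domain proteins over an
alphabet that excludes C and W except at the four pivotal anchors, with
subgroup CDR lengths drawn from the germline ranges (CDR1 5–12, CDR2
3–10, CDR3 2–13); members diverge from their scaffold by per-base
substitutions (default 2%) that are rejection-sampled never to create a
stop, touch an anchor codon, or introduce C/W — so within-subgroup
identity stays ~0.96 while cross-subgroup identity of independent
scaffolds sits far below the 0.75 threshold.

Planted defects guarantee their planned calls under the classification
rules: P via a TAA in mid-FR3, a 1-nt deletion (length mod 3 ≠ 0), or
ATG→ATA; ORF via a donor GT→GG, a W41→R codon, or a heptamer with three
substitutions drawn unique within the locus — uniqueness matters, because
a broken heptamer shared by several coding-intact genes would be *rescued*
by the more-than-one-functional-gene clause, which is the rule working as
stated, not a generator failure.

Promoter windows are built over a structured background (every third base
G) in which no spurious A/T run ≥ 5, pyrimidine tract, CCCT, octamer,
decamer or pentadecamer can occur, with planted elements at
subgroup-specific offsets (jitter ±3 nt by default) flanked by G to stop
run extension; a rejection loop re-draws the window until the default
scanner recovers exactly the planted offsets. Exact promoter-offset
recovery in the round trip is therefore a structural property of the
generated data. Intergenic spacing defaults put ~200 V genes in roughly
160 kb — a 1/10-scale heavy locus, which keeps the full round trip under
a minute; gene counts, functionality mix (roughly half F, a third P, the
rest ORF in the demo plan), inversions, duplications, unlocalized genes
and N-run gaps follow the organization of the real loci.

What passing round trips show: the pipeline's rules invert the generator's
constructions exactly — classification, naming, numbering, RS and promoter
logic are mutually consistent and deterministic. What they do not show:
robustness to real-data phenomena the generator omits — sequencing error,
indels inside cores, splice variants, truncated assemblies mid-gene,
subgroups that straddle the 75% threshold, promoters that diverge from
their subgroup architecture, or genuine biological ambiguity in anchor
residues. The published-exemplar tests (consensus strings, canonicality
exceptions, conserved-residue exceptions, table arithmetic) tie the rules
to real printed values, but the genome-wide counts themselves cannot be
regenerated without the underlying assembly.

## Fixtures and the consistency audit

The published per-subgroup gene/allele tables, CDR-length distributions,
locus coordinates and RS consensus strings ship as TSV fixtures.
`consistency_check` re-verifies every printed total against its printed
addends and flags disagreements without correcting them; on the shipped
fixtures exactly one check fails — the kappa locus allele total (printed
214; the printed per-type counts sum to 213). Both numbers are stored;
the discrepancy is surfaced as data.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (`random.Random`);
generation is byte-identical for a fixed spec + seed. Default test sizes:
unit tests use 6–24-gene loci; the acceptance round trip uses ~200 genes
(about 240 kb), chosen as the point where the full pipeline still
completes in well under a minute on one CPU while exercising eight
subgroups, all defect types, inversions, duplication, gaps and
unlocalized genes.
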