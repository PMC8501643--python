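# Methods

## Data model

The store keeps three linked entities. A **genome** is one uploaded
nucleotide sequence (strict `{A,C,G,T,N}` alphabet). A **feature** is a
located region on one genome — a CDS, a tRNA, or a repeat region — with
0-based half-open internal coordinates and a strand. An **annotation** holds
everything curators write (label, flag, public/private notes, assignment)
plus an auto-assigned accession, and is keyed by its sequence: the protein
translation for CDS features, the nucleotide sequence otherwise. Exactly one
annotation exists per distinct (sequence, molecule kind), so identical
proteins in different genomes share a single annotation and are curated
once. Every edit appends an immutable event (timestamp, user, field, old and
new value); replaying the event list from the creation state reconstructs
the current record, which the test suite verifies with an independent fold.

Accessions are `MAS_` plus a 7-digit zero-padded counter. The format is a
package convention chosen so lexicographic and chronological order coincide;
the counter is global to a store and never reissued, even after deletions.
No-op edits (new value equals old) append no event, keeping histories
minimal. Users are plain strings; there is no authentication layer.

Origin-wrapping features (possible on circular genomes after
re-orientation) are stored with `wraps_origin=True` and `start > stop`, and
are exported as two-segment locations (GFF3: two lines sharing an ID;
GenBank: a `join(...)` of two intervals).

## Gene calling

Phage and bacterial uploads call genes automatically. External callers are
supported through adapters (a parser for the Glimmer `.predict` dialect and
for tRNAscan-SE tabular output, fed either by a recorded output file or a
configured executable); adapters are pure functions of (sequence, config).
The builtin caller is a deliberately simple maximal-ORF finder: on both
strands it reports every open reading frame with a start codon in
{ATG, GTG, TTG}, an in-frame stop in {TAA, TAG, TGA} (included in the
feature coordinates), and at least 30 encoded residues by default. Nested
same-frame ORFs resolve to the longest (earliest start); overlapping ORFs in
different frames are all kept, since curation happens downstream. This is
not a statistical gene finder and makes no claim to Glimmer's accuracy on
real genomes; it exists so the full pipeline runs with no external binaries.

Translation uses NCBI table 11 by default; alternative start codons
translate to methionine, the trailing stop is stripped, and an internal stop
aborts the upload. Uploads are transactional: any failure leaves the store
untouched.

## Terminase re-orientation

Phage assemblies from circularly permuted packaging can begin anywhere, so
uploads can be re-oriented to start at the terminase gene. Every called CDS
is searched against a terminase protein database; a CDS is a candidate when
its best hit has e-value <= 1e-10 **and** query coverage >= 0.5 (the notion
of "enough evidence" is not standardized; both cutoffs are configurable).
Subunit identity is read from subject headers ("terminase large subunit" /
"terminase small subunit", case-insensitive). If large and small subunit
candidates lie on the same strand, the upstream one — 5'-most in their
transcription direction — anchors the new origin, matching the operon
arrangement of packaging genes; on opposite strands the lowest-e-value
candidate wins and a warning is logged, since that situation is biologically
ambiguous. When the chosen terminase lies on the minus strand the genome is
reverse-complemented before rotation, so annotation always reads forward
from the terminase start. This reverse-complement step is an interpretive
choice: re-orientation is only defined up to strand, and a forward-reading
canonical form makes re-oriented genomes directly comparable.

Rotation is a pure coordinate transform: genome length, feature count,
per-feature lengths and the multiset of CDS translations are invariant, and
re-orienting an already re-oriented genome is the identity. Features split
by the rotation become origin-wrapping.

## Homology evidence

Three tools are modelled: `blastp` (vs Swiss-Prot, nr, the internal
database, the terminase database, or custom protein sets), `rpsblast` (vs
CDD) and `hhsearch` (vs PDB). Result files parse from NCBI tabular format
(`outfmt 6 std slen stitle`, comments tolerated for outfmt 7 — the two extra
columns guarantee subject length and description, which the decision
predicates need) and from HH-suite `.hhr` reports (probability 0–100 kept as
the significance measure, never converted to a pseudo e-value). Reruns of
the same (annotation, tool, database) supersede the stored result.

The builtin search is a Smith–Waterman local alignment (BLOSUM62, gap open
11 / extend 1, biotite's C kernel) with Karlin–Altschul statistics: bit
score S' = (λS − ln K)/ln 2 with the published gapped-BLOSUM62 constants
λ = 0.267, K = 0.041, and E = m·n·2^(−S') over the query length m and total
database length n. These statistics are approximate (no length or
composition correction) and intended for the internal and terminase
databases, not as a BLAST substitute. The test suite pins the aligner to an
independent brute-force dynamic-programming oracle on hundreds of random
pairs; the gap convention (the first gap column costs the open penalty) is
therefore fixed by test, not by library documentation.

The **internal database** gives naming consistency: one entry per distinct
CDS protein in the store, with the annotation's accession, current flag and
label encoded in the FASTA header (`accession|flag|label`, also consumable
by an external `makeblastdb`). Any edit or upload marks it stale; searching
it rebuilds it first, so results always reflect current curation.

## Evidence summarization

Raw hits reduce to the qualitative predicates a curator weighs: presence,
significance, within-database consistency, cross-database consistency,
length similarity, and query/subject coverage classes. Defaults (all
configurable, all echoed into recommendation rationales):

| quantity | significant | moderate |
| --- | --- | --- |
| blastp / rpsblast e-value | <= 1e-5 | <= 1e-2 |
| hhsearch probability | >= 80 | >= 50 |

Coverage >= 0.8 is "all/most", >= 0.35 "some", else negligible (the classes
partition [0, 1]); lengths are "similar" when min/max >= 0.8. Label
agreement uses Jaccard similarity >= 0.5 of normalized token sets (lowercase,
punctuation stripped, generic filler words like "putative", "protein",
"domain" removed) over a strict majority of pairs — the top 5 hits within a
database, the top hit of each database across databases. None of these
numbers is standardized anywhere; they are explicit, auditable
interpretations of inherently qualitative guidance.

The e-value colour scale for rendering hits runs black (`#000000`) at
e-value 10 to light yellow (`#FFFFE0`) at e-value 0, linear in log10 space
and clamped below at 1e-180 to keep the logarithm finite. The genome-map
data product (JSON, optional static SVG, blocks coloured by flag) is
emitted only for genomes with fewer than 1000 features, mirroring the usual
practical limit for a browsable genome view.

## The decision guide

`recommend()` encodes the conventional result-interrogation guide as twelve
ordered procedures (P1–P12, first match fires; see the module docstring of
`manna.decision` for the full list): no evidence → "hypothetical protein";
nr-only evidence is adopted only under review; domain-only evidence names
the protein by its domain ("`<DOMAIN>` domain-containing protein" for
domains of unknown function); trustworthy Swiss-Prot agreement is adopted
verbatim; coverage/length anomalies flag possible wrong start codons or
truncations for review; moderate-only evidence gets a "putative " prefix;
a significant internal-database hit reuses its label *and flag* so naming
stays consistent; hhsearch-only evidence is generalized to the head
functional noun ("cell death-related nuclease" → "nuclease") because HMM
search is sensitive enough to over-annotate; and significant but mutually
inconsistent databases defer to the most curated one (internal > Swiss-Prot
> CDD > PDB > nr) under a review flag.

The source guidance is a table of situations, not an algorithm — several
rows can apply at once and some cells are deliberately blank. Imposing a
total order and keying the "only nr"-style rows on *significance* rather
than mere presence are this package's design choices, made so that every
syntactically valid summary fires exactly one procedure (verified by fuzz
test). Two deliberate extensions for totality: moderate-but-inconsistent
evidence resolves to "hypothetical protein" under review (P9), and any
significant evidence that matches no more specific situation falls through
to the review procedure (P12). Rationales enumerate every predicate
evaluated and the thresholds in force.

Recommendations are suggestions: nothing is written until
`apply_recommendation` is called with an explicit accept, which routes
through the normal edit path (history recorded, internal database marked
stale) and raises a conflict if the annotation changed since the summary was
built. Where no rule dictates a flag, accepting clears UNANNOTATED to NONE.
"putative " is prepended at most once.

## Exports

GenBank (via Biopython; LOCUS division PHG/BCT/UNA by upload mode), GFF3,
genome FASTA, CDS-translation FASTA, and an annotation table (TSV always,
Office Open XML optionally) with the fixed column set accession, label,
flag, public_notes, private_notes, assigned_to, sequence, genome, start,
stop, strand. Exports convert to 1-based inclusive coordinates. Private
notes appear **only** in the annotation table — never in GenBank, GFF3 or
FASTA — and the table re-imports by exact, case-insensitive sequence match,
so exporting and re-importing a genome's table is a no-op. The per-genome
bundle is a gzip tarball of all five members with zeroed timestamps, making
archives byte-reproducible for a fixed store clock. The bundle includes the
GenBank file alongside the four core members because the same export action
produces it; keeping them together was judged more useful than a minimal
archive.

## Synthetic data

The fixture generator produces genomes whose gene content is exactly
recoverable by the builtin ORF caller, which requires controlling all six
reading frames: genes interleave an 8-residue cassette (LKYKFKYY, fixed
codons) that plants stop codons in both shifted forward frames and in every
reverse-frame offset, so no spurious ORF of >= 30 codons can thread through
a gene body; intergenic spacers are TTAA repeats (stops at every offset on
both strands) that double as the in-frame stop guard pinning each called ORF
start to the planted start codon; and circular-permutation cut points fall
only in spacers, never inside a gene or between the two terminase subunits.
Gene length defaults to ~110 residues (terminase large ~170, small ~80,
loosely phage-like); non-cassette codons are drawn uniformly from the
synonymous choices of table 11 — no codon-usage realism is attempted or
needed. The terminase database contains <= 10%-mutated copies of the planted
terminase proteins plus random decoys; all sequences are synthetic strings,
not copies of real database content.

What passing these tests shows — and does not. The fixtures exercise the
machinery (coordinate arithmetic, deduplication, evidence plumbing, the rule
engine, format round-trips) under exactly known truth. They do not show that
the builtin ORF caller finds real genes accurately (real genomes have
overlapping genes, non-canonical starts, and no cassette structure), that
the builtin search statistics match BLAST on real databases, or that the
decision thresholds are well calibrated for real evidence; on real data the
external tool adapters and a curator's judgement carry those burdens.

## Numerical and degenerate-input choices

Strict nucleotide alphabet {A,C,G,T,N}; IUPAC ambiguity codes are rejected
(documented limitation — they would poison translation silently). CDS
containing N fail translation explicitly. E-value ties in hit ordering break
by descending bit score; candidate ties in terminase detection break by
lowest e-value. The colour-scale floor of 1e-180 keeps log10 finite in
double precision. Problem sizes in the test suite (6–8 genes of ~110
residues per genome, 20 re-orientation fixtures, 200 aligner-oracle pairs)
were chosen as the smallest sizes that still exercise every code path,
keeping the whole suite fast enough to run on every change.
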