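"""Synthetic genomes, terminase databases and mock search results.

Everything the pipeline consumes can be generated here with known ground
truth, so the whole system is testable offline: no real genomes, no copied
database content, no external search binaries.

Design of the synthetic genomes
-------------------------------
Planted genes must be recovered *exactly* by the maximal-ORF caller, which
requires controlling every reading frame:

* every ~10 random residues, genes embed an 8-residue cassette (``LKYKFKYY``)
  encoded with fixed codons (``TTA AAA TAT AAA TTT AAA TAT TAC``) that places
  a stop codon in both shifted forward frames and a reverse-strand stop at
  every frame offset -- so no spurious ORF of >= 30 codons can thread through
  a gene body in any non-reading frame;
* intergenic spacers are ``TTAA`` repeats, which contain stops at every
  offset on both strands and automatically provide the in-frame stop guard
  immediately upstream of each gene, pinning the called ORF start to the
  planted start codon;
* circular-permutation cut points fall inside spacers only, so rotation never
  splits a gene and every gene keeps its guard.

The cassette makes the synthetic proteins share a periodic motif; the
resulting chance alignments score orders of magnitude above the terminase
detection threshold (1e-10), so detection specificity is unaffected.  Codons
for the non-cassette residues are drawn uniformly from the synonymous
choices of translation table 11.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .errors import ValidationError
from .ingest import revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CASSETTE_AA = "LKYKFKYY"
CASSETTE_CODONS = ("TTA", "AAA", "TAT", "AAA", "TTT", "AAA", "TAT", "TAC")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for codons in _SYNONYMS.values():
    codons.sort()

STOP_CHOICES = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class PlantedGene:
    protein: str
    start: int  # 0-based, includes the stop codon in [start, stop)
    stop: int
    strand: str
    role: str  # terminase_large | terminase_small | generic


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic genome."""

    sequence: str
    genes: list[PlantedGene]
    seed: int
    dtr_length: Optional[int] = None
    permutation_offset: int = 0
    reverse_complemented: bool = False
    canonical_sequence: str = ""

    def proteins(self) -> list[str]:
        return [g.protein for g in self.genes]

    def gene_with_role(self, role: str) -> PlantedGene:
        matches = [g for g in self.genes if g.role == role]
        if len(matches) != 1:
            raise ValidationError(f"expected exactly one {role} gene")
        return matches[0]


def _random_protein(rng: random.Random, target_len: int) -> str:
    """Cassette-interleaved protein of roughly ``target_len`` residues."""
    blocks = max(1, round((target_len - 14) / 18))
    residues = ["M"] + [rng.choice(AA20) for _ in range(3)]
    for _ in range(blocks):
        residues.extend(CASSETTE_AA)
        residues.extend(rng.choice(AA20) for _ in range(10))
    # final cassette keeps the gene tail stop-dense in every frame
    residues = residues[: -10 + 2] if blocks else residues
    return "".join(residues)


def _encode_gene(rng: random.Random, protein: str) -> str:
    """DNA for a protein: ATG start, cassette codons forced, stop appended."""
    codons = ["ATG"]
    i = 1
    while i < len(protein):
        if protein[i : i + len(CASSETTE_AA)] == CASSETTE_AA:
            codons.extend(CASSETTE_CODONS)
            i += len(CASSETTE_AA)
        else:
            codons.append(rng.choice(_SYNONYMS[protein[i]]))
            i += 1
    codons.append(rng.choice(STOP_CHOICES))
    return "".join(codons)


def _spacer(rng: random.Random, min_nt: int = 20) -> str:
    return "TTAA" * max(5, (min_nt + 3) // 4 + rng.randint(0, 5))


def make_synthetic_phage(
    seed: int,
    n_genes: int = 8,
    mean_gene_len: int = 110,
    with_terminase: str = "large",
    dtr_length: Optional[int] = None,
    permute: bool = False,
    rc: bool = False,
) -> tuple[str, SyntheticTruth]:
    """Generate a synthetic phage genome with known gene content.

    ``with_terminase``: ``none``, ``large`` (one large-subunit gene at the
    canonical origin) or ``both`` (small subunit immediately upstream of the
    large, operon-like, both forward).  ``permute`` rotates the sequence by a
    random intergenic offset and ``rc`` reverse-complements the result,
    emulating an arbitrarily opened circularly permuted assembly; the truth
    records both so the canonical form can be compared against.

    Returns ``(fasta_text, truth)``; regeneration from the same arguments is
    byte-identical.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if with_terminase not in ("none", "large", "both"):
        raise ValidationError(f"unknown terminase mode: {with_terminase!r}")
    n_terminase = {"none": 0, "large": 1, "both": 2}[with_terminase]
    if n_genes < n_terminase:
        raise ValidationError("n_genes too small for the requested terminase genes")

    rng = random.Random(seed)

    plan: list[tuple[str, str, int]] = []  # (role, strand, target_len)
    if with_terminase == "both":
        plan.append(("terminase_small", "+", 80))
        plan.append(("terminase_large", "+", 170))
    elif with_terminase == "large":
        plan.append(("terminase_large", "+", 170))
    for _ in range(n_genes - n_terminase):
        plan.append(("generic", rng.choice("+-"), mean_gene_len))

    parts: list[str] = []
    genes: list[PlantedGene] = []
    spacer_spans: list[tuple[int, int]] = []
    pos = 0
    if with_terminase == "none" or dtr_length:
        lead = _spacer(rng, min_nt=max(24, (dtr_length or 0) + 8))
        parts.append(lead)
        spacer_spans.append((0, len(lead)))
        pos = len(lead)
    for role, strand, target_len in plan:
        protein = _random_protein(rng, target_len)
        dna = _encode_gene(rng, protein)
        segment = revcomp(dna) if strand == "-" else dna
        parts.append(segment)
        genes.append(PlantedGene(protein, pos, pos + len(segment), strand, role))
        pos += len(segment)
        spacer = _spacer(rng)
        parts.append(spacer)
        # the spacer inside the terminase operon is never a permutation cut
        # point: the small subunit must stay immediately upstream of the large
        if role != "terminase_small":
            spacer_spans.append((pos, pos + len(spacer)))
        pos += len(spacer)

    sequence = "".join(parts)
    if dtr_length:
        if not 0 < dtr_length < len(sequence) / 2:
            raise ValidationError("dtr_length does not fit in the genome")
        sequence = sequence + sequence[:dtr_length]

    truth = SyntheticTruth(
        sequence=sequence,
        genes=genes,
        seed=seed,
        dtr_length=dtr_length,
        canonical_sequence=sequence,
    )

    if permute:
        if dtr_length:
            raise ValidationError("permutation and terminal repeats are exclusive")
        n = len(sequence)
        # cut inside a spacer, away from the guard triplets at its edges
        candidates = [
            (a, b) for a, b in spacer_spans if b - a >= 12 and a > 0
        ]
        a, b = candidates[rng.randrange(len(candidates))]
        offset = rng.randrange(a + 4, b - 4)
        sequence = sequence[offset:] + sequence[:offset]
        truth.permutation_offset = offset
        truth.genes = [
            PlantedGene(
                g.protein, (g.start - offset) % n, (g.start - offset) % n + (g.stop - g.start),
                g.strand, g.role,
            )
            for g in genes
        ]
    if rc:
        n = len(sequence)
        sequence = revcomp(sequence)
        truth.reverse_complemented = True
        truth.genes = [
            PlantedGene(
                g.protein, n - g.stop, n - g.start,
                "-" if g.strand == "+" else "+", g.role,
            )
            for g in truth.genes
        ]
    truth.sequence = sequence
    truth.genes.sort(key=lambda g: g.start)

    fasta = f">synthetic_phage_seed{seed}\n" + "\n".join(
        sequence[i : i + 70] for i in range(0, len(sequence), 70)
    ) + "\n"
    return fasta, truth


def _mutate(rng: random.Random, protein: str, fraction: float = 0.08) -> str:
    """Substitute up to ``fraction`` of positions (never the initial M)."""
    chars = list(protein)
    k = max(1, int(len(chars) * fraction))
    for i in rng.sample(range(1, len(chars)), k):
        chars[i] = rng.choice([a for a in AA20 if a != chars[i]])
    return "".join(chars)


def make_terminase_db(
    truth_or_proteins, seed: int, n_decoys: int = 5
) -> str:
    """Protein FASTA emulating a terminase reference database.

    Contains slightly mutated (<= 10% of positions) copies of the planted
    terminase proteins, with subunit-identifying headers, plus ``n_decoys``
    unrelated random proteins.  All sequences are synthetic.
    """
    rng = random.Random(seed)
    entries: list[tuple[str, str]] = []
    if isinstance(truth_or_proteins, SyntheticTruth):
        sources = [
            (g.role, g.protein)
            for g in truth_or_proteins.genes
            if g.role.startswith("terminase")
        ]
    else:
        sources = list(truth_or_proteins)
    for idx, (role, protein) in enumerate(sources, start=1):
        subunit = "large subunit" if role.endswith("large") else "small subunit"
        entries.append(
            (
                f"TERM_{idx:03d} synthetic phage terminase {subunit}",
                _mutate(rng, protein),
            )
        )
    for idx in range(1, n_decoys + 1):
        decoy = "M" + "".join(rng.choice(AA20) for _ in range(rng.randint(120, 200)))
        entries.append((f"DECOY_{idx:03d} synthetic decoy protein", decoy))
    lines = []
    for header, protein in entries:
        lines.append(f">{header}")
        lines.extend(protein[i : i + 70] for i in range(0, len(protein), 70))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Mock search results
# ---------------------------------------------------------------------------

def _blast_rows(
    qid: str,
    hits: Sequence[tuple[str, str, float, int, tuple[int, int, int, int]]],
) -> str:
    """hits: (subject_id, stitle, evalue, slen, (qs, qe, ss, se))."""
    rows = []
    for sid, stitle, evalue, slen, (qs, qe, ss, se) in hits:
        bits = max(30.0, -10.0 * (0 if evalue <= 0 else math.log10(evalue)))
        rows.append(
            "\t".join(
                [
                    qid, sid, "98.000", str(qe - qs + 1), "2", "0",
                    str(qs), str(qe), str(ss), str(se),
                    f"{evalue:.2g}", f"{bits:.1f}", str(slen), stitle,
                ]
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


def _hhr_text(
    qid: str,
    query_length: int,
    hits: Sequence[tuple[str, str, float, float, int, tuple[int, int, int, int]]],
) -> str:
    """hits: (subject_id, description, prob, evalue, tlen, (qs, qe, ts, te))."""
    lines = [
        f"Query         {qid}",
        f"Match_columns {query_length}",
        "No_of_seqs    1 out of 1",
        "Neff          1.0",
        "Searched_HMMs 100",
        "Date          Mon Jan  1 00:00:00 2024",
        "Command       hhsearch",
        "",
        " No Hit                             Prob E-value P-value  Score    SS "
        "Cols Query HMM  Template HMM",
    ]
    for i, (sid, desc, prob, evalue, tlen, (qs, qe, ts, te)) in enumerate(hits, 1):
        name = f"{sid} {desc}"[:30]
        cols = qe - qs + 1
        lines.append(
            f"{i:>3} {name:<30} {prob:5.1f} {evalue:8.2g} {evalue / 100:8.2g}"
            f" {prob * 2:6.1f}   0.0 {cols:4d} {qs}-{qe} {ts}-{te} ({tlen})"
        )
    lines.append("")
    for i, (sid, desc, prob, evalue, tlen, _) in enumerate(hits, 1):
        lines.append(f"No {i}")
        lines.append(f">{sid} {desc}")
        lines.append(f"Probab={prob:.2f}  E-value={evalue:.2g}")
        lines.append("")
    return "\n".join(lines) + "\n"


def pattern_results(
    pattern: str, query_length: int = 200, qid: str = "q1"
) -> dict[tuple[str, str], str]:
    """Mock result files exercising one situation of the decision guide.

    Returns ``{(tool, database): file text}``; blast-style values parse with
    :func:`manna.homology.parse_blast_tabular`, hhsearch values with
    :func:`manna.homology.parse_hhr`.
    """
    L = query_length
    full = (1, L, 1, L)

    def sp(hits):
        return ("blastp", "swissprot"), _blast_rows(qid, hits)

    def nr(hits):
        return ("blastp", "nr"), _blast_rows(qid, hits)

    def internal(hits):
        return ("blastp", "internal"), _blast_rows(qid, hits)

    def cdd(hits):
        return ("rpsblast", "cdd"), _blast_rows(qid, hits)

    patterns: dict[str, dict] = {
        "P1": dict([]),
        "P2": dict(
            [
                nr(
                    [
                        ("NR_1", "integrase", 1e-30, L, full),
                        ("NR_2", "tail fiber protein", 2e-28, L, full),
                        ("NR_3", "DNA polymerase", 5e-25, L, full),
                        ("NR_4", "holin", 1e-20, L, full),
                        ("NR_5", "portal protein", 3e-18, L, full),
                    ]
                )
            ]
        ),
        "P3": dict(
            [
                nr(
                    [
                        (f"NR_{i}", "major capsid protein", ev, L, full)
                        for i, ev in enumerate(
                            (1e-40, 3e-38, 2e-35, 1e-30, 5e-28), start=1
                        )
                    ]
                )
            ]
        ),
        "P4": dict(
            [
                cdd(
                    [
                        ("PHA00123", "TerL, phage terminase large subunit (GpA)", 1e-25, L, full),
                        ("PHA00124", "TerL_2, phage terminase large subunit", 4e-22, L, full),
                    ]
                ),
                nr([("NR_1", "terminase large subunit", 1e-30, L, full)]),
            ]
        ),
        "P4-DUF": dict(
            [
                cdd(
                    [
                        ("PF09999", "DUF9999, Domain of unknown function", 1e-18, L, full),
                        ("PF09998", "DUF9999, Domain of unknown function", 2e-15, L, full),
                    ]
                )
            ]
        ),
        "P5": dict(
            [
                cdd(
                    [
                        ("PF00078", "RVT_1, reverse transcriptase domain", 1e-15, 80,
                         (61, 140, 1, 80)),
                        ("PF00079", "RVT_1, reverse transcriptase domain", 3e-12, 80,
                         (61, 140, 1, 80)),
                    ]
                )
            ]
        ),
        "P6": dict(
            [
                cdd(
                    [
                        ("PF01111", "EndoA, endonuclease domain", 1e-20, 80, (11, 90, 1, 80)),
                        ("PF02222", "LigB, DNA ligase domain", 1e-12, 80, (21, 95, 1, 75)),
                    ]
                )
            ]
        ),
        "P6-disjoint": dict(
            [
                cdd(
                    [
                        ("PF01111", "EndoA, endonuclease domain", 1e-20, 80, (11, 90, 1, 80)),
                        ("PF02222", "LigB, DNA ligase domain", 1e-12, 80, (111, 190, 1, 80)),
                    ]
                )
            ]
        ),
        "P7": dict(
            [
                sp(
                    [
                        ("SP_P001", "terminase large subunit", 1e-45, L, full),
                        ("SP_P002", "terminase large subunit", 2e-40, L, full),
                    ]
                ),
                nr([("NR_1", "terminase large subunit", 1e-42, L, full)]),
            ]
        ),
        "P8": dict(
            [
                sp([("SP_P010", "tape measure protein", 1e-30, 2 * L, (1, L, L + 1, 2 * L))])
            ]
        ),
        "P9": dict([sp([("SP_P020", "portal protein", 1e-3, L, full)])]),
        "P10": dict(
            [
                internal([("MAS_0000042", "MAS_0000042|GREEN|major capsid protein", 1e-50, L, full)]),
                sp([("SP_P030", "major capsid protein", 1e-40, L, full)]),
                nr([("NR_1", "major capsid protein", 1e-38, L, full)]),
            ]
        ),
        "P12": dict(
            [
                sp([("SP_P040", "integrase", 1e-35, L, full)]),
                cdd([("PF03333", "HTH_XRE, helix-turn-helix domain", 1e-22, L, full)]),
            ]
        ),
    }
    patterns["P11"] = {
        ("hhsearch", "pdb"): _hhr_text(
            qid, L,
            [
                ("5XYZ_A", "cell death-related nuclease", 97.5, 1.2e-12, L, full),
            ],
        )
    }
    if pattern not in patterns:
        raise ValidationError(f"unknown evidence pattern: {pattern!r}")
    return patterns[pattern]


ALL_PATTERNS = (
    "P1", "P2", "P3", "P4", "P4-DUF", "P5", "P6", "P6-disjoint",
    "P7", "P8", "P9", "P10", "P11", "P12",
)

EXPECTED_PROCEDURE = {
    "P1": "P1", "P2": "P2", "P3": "P3", "P4": "P4", "P4-DUF": "P4",
    "P5": "P5", "P6": "P6", "P6-disjoint": "P6", "P7": "P7", "P8": "P8",
    "P9": "P9", "P10": "P10", "P11": "P11", "P12": "P12",
}


def make_mock_results(
    truth: SyntheticTruth,
    combos: Sequence[tuple[str, str]],
    patterns: dict[int, str] | None = None,
    query_ids: Sequence[str] | None = None,
) -> dict[tuple[str, str], dict[str, str]]:
    """Mock result files for every gene of a synthetic genome.

    Terminase genes receive consistent significant terminase hits; other
    genes follow ``patterns`` (gene index -> pattern name, default ``P1`` =
    no results).  Returns ``{(tool, db): {query_id: text}}`` suitable for
    :class:`manna.homology.RecordedBackend`.
    """
    patterns = patterns or {}
    if query_ids is None:
        query_ids = [f"gene_{i + 1}" for i in range(len(truth.genes))]
    files: dict[tuple[str, str], dict[str, str]] = {combo: {} for combo in combos}
    for i, gene in enumerate(truth.genes):
        qid = query_ids[i]
        L = len(gene.protein)
        if gene.role.startswith("terminase"):
            subunit = "large" if gene.role.endswith("large") else "small"
            per_combo = {
                ("blastp", "swissprot"): _blast_rows(
                    qid,
                    [("SP_T001", f"terminase {subunit} subunit", 1e-40, L, (1, L, 1, L))],
                ),
                ("blastp", "nr"): _blast_rows(
                    qid,
                    [("NR_T001", f"terminase {subunit} subunit", 1e-38, L, (1, L, 1, L))],
                ),
            }
        else:
            name = patterns.get(i, "P1")
            per_combo = pattern_results(name, query_length=L, qid=qid)
        for combo in combos:
            files[combo][qid] = per_combo.get(combo, "")
    return files
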