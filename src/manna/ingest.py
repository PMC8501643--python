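"""Genome upload: FASTA reading, gene calling, terminase re-orientation.

Phage and bacterial uploads run a gene caller over the sequence (the builtin
maximal-ORF caller, or an external adapter such as Glimmer / tRNAscan-SE);
custom uploads take user-supplied coordinates.  Phage uploads can re-orient
the genome so it starts at the terminase gene: every CDS is searched against
a terminase protein database, and on sufficient evidence (default e-value <=
1e-10 and query coverage >= 0.5) the genome is rotated -- and
reverse-complemented first when the terminase lies on the minus strand -- so
the terminase start becomes coordinate 0.  When both packaging subunits are
found on one strand, the upstream (5'-most in their transcription direction)
subunit anchors the new origin.

Internal coordinates are 0-based half-open; user feature files are 1-based
inclusive (GFF3 convention) and converted on load.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .config import Thresholds, DEFAULT_THRESHOLDS
from .errors import (
    AdapterUnavailableError,
    AlphabetError,
    ConfigurationError,
    FormatError,
    TranslationError,
    UniquenessError,
    ValidationError,
)
from .homology import builtin_protein_search, load_protein_fasta
from .store import GenomeRecord, Store

log = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureDraft:
    """A located feature candidate, not yet persisted."""

    kind: str
    start: int
    stop: int
    strand: str
    source: str = "builtin_orf"
    wraps_origin: bool = False

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.stop
        return self.stop - self.start


@dataclass(frozen=True)
class TerminaseCall:
    feature: FeatureDraft
    subunit: str  # large | small | unspecified
    best_evalue: float
    query_coverage: float


@dataclass
class UploadOptions:
    """Options controlling :func:`upload_genome`.

    ``reorient_terminase`` and ``dtr_length`` apply to phage mode only;
    ``features_path`` is required in custom mode.  ``genetic_code`` is an
    NCBI translation table id (11 = bacterial/plastid, the prokaryote and
    phage default).
    """

    mode: str = "phage"
    reorient_terminase: bool = False
    dtr_length: Optional[int] = None
    assign_to: Optional[str] = None
    gene_caller: str = "builtin"
    genetic_code: int = 11
    min_aa_len: int = 30
    features_path: Optional[str] = None
    terminase_db: Optional[object] = None  # FASTA path/text or entry list
    adapters: Optional[dict] = None
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    topology: str = "linear"

    def validate(self) -> None:
        if self.mode not in ("phage", "bacterial", "custom"):
            raise ValidationError(f"unknown upload mode: {self.mode!r}")
        if self.mode != "phage" and (self.reorient_terminase or self.dtr_length):
            raise ValidationError(
                "terminase re-orientation and DTRs are phage-mode options"
            )
        if self.mode == "custom" and not self.features_path:
            raise ValidationError("custom mode requires a feature file")
        if self.dtr_length is not None and self.dtr_length <= 0:
            raise ValidationError("dtr_length must be positive")


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_single_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record nucleotide FASTA; strict {A,C,G,T,N} alphabet."""
    text = Path(path).read_text()
    header = None
    extra = False
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is None:
                header = line[1:].strip()
            else:
                extra = True
        elif header is not None:
            chunks.append(line.strip())
    if header is None or extra:
        raise FormatError("expected exactly one FASTA record")
    sequence = "".join(chunks).upper()
    if not sequence:
        raise ValidationError("FASTA record has an empty sequence")
    bad = set(sequence) - NUCLEOTIDES
    if bad:
        raise AlphabetError(
            f"sequence contains non-nucleotide characters: {sorted(bad)}"
            " (accepted alphabet: A,C,G,T,N)"
        )
    return header, sequence


# ---------------------------------------------------------------------------
# Gene calling
# ---------------------------------------------------------------------------

def _orfs_one_strand(sequence: str, min_aa_len: int) -> list[tuple[int, int]]:
    """Maximal ORFs [start, stop_codon_end) on the forward strand."""
    n = len(sequence)
    orfs = []
    for frame in range(3):
        first_start = None
        for p in range(frame, n - 2, 3):
            codon = sequence[p : p + 3]
            if codon in STOP_CODONS:
                if first_start is not None and (p - first_start) // 3 >= min_aa_len:
                    orfs.append((first_start, p + 3))
                first_start = None
            elif first_start is None and codon in START_CODONS:
                first_start = p
    return orfs


def call_genes_builtin(
    sequence: str, min_aa_len: int = 30, genetic_code: int = 11
) -> list[FeatureDraft]:
    """Builtin ORF caller: maximal open reading frames on both strands.

    Start codons ATG/GTG/TTG; an ORF runs to its in-frame stop codon
    (included in the coordinates) and must encode at least ``min_aa_len``
    residues.  Nested same-frame ORFs resolve to the longest (earliest
    start); overlapping ORFs in different frames are all reported.
    """
    n = len(sequence)
    drafts = [
        FeatureDraft("CDS", s, e, "+", "builtin_orf")
        for s, e in _orfs_one_strand(sequence, min_aa_len)
    ]
    for s, e in _orfs_one_strand(revcomp(sequence), min_aa_len):
        drafts.append(FeatureDraft("CDS", n - e, n - s, "-", "builtin_orf"))
    drafts.sort(key=lambda d: (d.start, d.stop, d.strand))
    return drafts


def _parse_glimmer_predict(text: str) -> list[FeatureDraft]:
    drafts = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise FormatError("expected 'orf start end frame [score]'", lineno)
        try:
            a, b, frame = int(fields[1]), int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise FormatError(f"unparsable coordinates: {exc}", lineno) from exc
        if frame > 0:
            drafts.append(FeatureDraft("CDS", a - 1, b, "+", "external_caller"))
        else:
            drafts.append(FeatureDraft("CDS", b - 1, a, "-", "external_caller"))
    return drafts


def _parse_trnascan(text: str) -> list[FeatureDraft]:
    drafts = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("Sequence", "Name", "----")):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            fields = line.split()
        if len(fields) < 5:
            raise FormatError("expected tRNAscan-SE tabular columns", lineno)
        try:
            begin, end = int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise FormatError(f"unparsable coordinates: {exc}", lineno) from exc
        if begin <= end:
            drafts.append(FeatureDraft("tRNA", begin - 1, end, "+", "external_caller"))
        else:
            drafts.append(FeatureDraft("tRNA", end - 1, begin, "-", "external_caller"))
    return drafts


_ADAPTER_PARSERS = {
    "glimmer": _parse_glimmer_predict,
    "trnascan": _parse_trnascan,
}


def run_external_caller(
    sequence: str, adapter_name: str, config: dict
) -> list[FeatureDraft]:
    """Run (or replay) an external gene caller through its adapter.

    Adapter definitions (``config[adapter_name]``):

    * ``format``: output dialect, one of ``glimmer`` (``.predict``) or
      ``trnascan`` (tabular).
    * ``recorded_output``: path to a previously produced output file, replayed
      as-is (pure function of the recorded run).
    * ``exec`` / ``args``: alternatively, an executable and an argument
      template containing ``{fasta}`` and ``{out}`` placeholders.
    """
    if not config or adapter_name not in config:
        raise AdapterUnavailableError(f"adapter {adapter_name!r} is not configured")
    spec = config[adapter_name]
    fmt = spec.get("format", adapter_name)
    if fmt not in _ADAPTER_PARSERS:
        raise ConfigurationError(f"unknown adapter output format {fmt!r}")
    if "recorded_output" in spec:
        text = Path(spec["recorded_output"]).read_text()
        return _ADAPTER_PARSERS[fmt](text)
    exe = spec.get("exec")
    if not exe or shutil.which(exe) is None:
        raise AdapterUnavailableError(
            f"adapter {adapter_name!r}: executable {exe!r} not found"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "genome.fasta"
        out = Path(tmp) / "output.txt"
        fasta.write_text(f">genome\n{sequence}\n")
        args = [
            a.format(fasta=str(fasta), out=str(out))
            for a in spec.get("args", "{fasta}").split()
        ]
        proc = subprocess.run([exe, *args], capture_output=True, text=True)
        if proc.returncode != 0:
            raise AdapterUnavailableError(
                f"adapter {adapter_name!r} failed: {proc.stderr.strip()[:500]}"
            )
        text = out.read_text() if out.exists() else proc.stdout
    return _ADAPTER_PARSERS[fmt](text)


def load_user_features(
    source: str | Path, genome_length: int | None = None
) -> list[FeatureDraft]:
    """Load user gene calls from GFF3 or a seqid/kind/start/stop/strand table.

    Coordinates in both dialects are 1-based inclusive and are converted to
    internal 0-based half-open.  Feature kinds other than CDS / tRNA /
    repeat_region are skipped with a warning.
    """
    text = str(source)
    if "\n" not in text and "\t" not in text:
        text = Path(source).read_text()
    drafts: list[FeatureDraft] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 8:  # GFF3 body line
            kind, start_s, stop_s, strand = fields[2], fields[3], fields[4], fields[6]
        elif len(fields) == 5:  # seqid kind start stop strand
            kind, start_s, stop_s, strand = fields[1], fields[2], fields[3], fields[4]
        else:
            raise FormatError(
                "expected GFF3 (9 columns) or seqid/kind/start/stop/strand table",
                lineno,
            )
        if kind not in ("CDS", "tRNA", "repeat_region"):
            log.warning("line %d: skipping unsupported feature kind %r", lineno, kind)
            continue
        try:
            start1, stop1 = int(start_s), int(stop_s)
        except ValueError as exc:
            raise FormatError(f"unparsable coordinates: {exc}", lineno) from exc
        if strand == ".":
            strand = "+"
        if strand not in ("+", "-"):
            raise FormatError(f"bad strand {strand!r}", lineno)
        if start1 < 1 or stop1 < start1:
            raise FormatError(f"bad coordinate pair {start1}..{stop1}", lineno)
        start, stop = start1 - 1, stop1
        if genome_length is not None and stop > genome_length:
            raise FormatError(
                f"feature {start1}..{stop1} extends past genome end ({genome_length})",
                lineno,
            )
        if kind == "CDS" and (stop - start) % 3 != 0:
            raise FormatError(
                f"CDS length {stop - start} is not a multiple of 3", lineno
            )
        drafts.append(FeatureDraft(kind, start, stop, strand, "user_supplied"))
    return drafts


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def feature_nt_sequence(genome_seq: str, draft) -> str:
    """Nucleotide sequence of a feature in its reading direction."""
    if draft.wraps_origin:
        dna = genome_seq[draft.start :] + genome_seq[: draft.stop]
    else:
        dna = genome_seq[draft.start : draft.stop]
    return revcomp(dna) if draft.strand == "-" else dna


def translate_cds(
    genome_seq: str,
    start: int,
    stop: int,
    strand: str,
    genetic_code: int = 11,
    wraps_origin: bool = False,
) -> str:
    """Translate a CDS to protein; trailing stop removed, internal stop fatal.

    Alternative start codons of the genetic code translate to methionine, as
    in standard CDS semantics.
    """
    dna = feature_nt_sequence(
        genome_seq, FeatureDraft("CDS", start, stop, strand, wraps_origin=wraps_origin)
    )
    if len(dna) % 3 != 0:
        raise TranslationError(f"CDS length {len(dna)} is not a multiple of 3")
    if "N" in dna:
        raise TranslationError("CDS contains ambiguous bases (N)")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    protein = str(Seq(dna).translate(table=genetic_code))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise TranslationError(
            f"internal stop codon at residue {protein.index('*') + 1}"
        )
    if not protein:
        raise TranslationError("CDS encodes an empty protein")
    if dna[:3] in table.start_codons:
        protein = "M" + protein[1:]
    return protein


# ---------------------------------------------------------------------------
# Terminal repeats & terminase re-orientation
# ---------------------------------------------------------------------------

def add_terminal_repeats(genome_length: int, dtr_length: int) -> list[FeatureDraft]:
    """Direct terminal repeat features at both genome ends."""
    if not 0 < dtr_length < genome_length / 2:
        raise ValidationError(
            f"dtr_length must lie in (0, genome_length/2); got {dtr_length}"
            f" for genome of length {genome_length}"
        )
    return [
        FeatureDraft("repeat_region", 0, dtr_length, "+", "dtr"),
        FeatureDraft(
            "repeat_region", genome_length - dtr_length, genome_length, "+", "dtr"
        ),
    ]


def _subunit_from_header(subject_id: str, description: str) -> str:
    text = f"{subject_id} {description}".lower()
    if "large subunit" in text:
        return "large"
    if "small subunit" in text:
        return "small"
    return "unspecified"


def detect_terminase(
    cds_drafts: Sequence[FeatureDraft],
    proteins: Sequence[str],
    terminase_db,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    search=builtin_protein_search,
) -> Optional[TerminaseCall]:
    """Find the terminase CDS (if any) by searching the terminase database.

    A CDS is a candidate when its best database hit passes the e-value and
    query-coverage thresholds.  With large and small subunit candidates on
    the same strand the upstream one (5'-most in transcription direction) is
    returned; with subunits on opposite strands the lowest-e-value candidate
    wins and a warning is logged.
    """
    if len(cds_drafts) != len(proteins):
        raise ValidationError("one protein required per CDS draft")
    if isinstance(terminase_db, (str, Path)):
        terminase_db = load_protein_fasta(terminase_db)
    if not terminase_db:
        raise ConfigurationError("terminase database is empty")
    candidates: list[TerminaseCall] = []
    for draft, protein in zip(cds_drafts, proteins):
        hits = search(protein, terminase_db, max_evalue=10.0)
        for hit in hits:
            qcov = (hit.q_end - hit.q_start + 1) / len(protein)
            if hit.evalue <= thresholds.terminase_max_evalue and qcov >= thresholds.terminase_min_qcov:
                candidates.append(
                    TerminaseCall(
                        feature=draft,
                        subunit=_subunit_from_header(
                            hit.subject_id, hit.subject_description
                        ),
                        best_evalue=hit.evalue,
                        query_coverage=qcov,
                    )
                )
                break
    if not candidates:
        return None
    best_by_subunit: dict[str, TerminaseCall] = {}
    for cand in candidates:
        prev = best_by_subunit.get(cand.subunit)
        if prev is None or cand.best_evalue < prev.best_evalue:
            best_by_subunit[cand.subunit] = cand
    large = best_by_subunit.get("large")
    small = best_by_subunit.get("small")
    if large and small:
        if large.feature.strand == small.feature.strand:
            if large.feature.strand == "+":
                return min((large, small), key=lambda c: c.feature.start)
            return max((large, small), key=lambda c: c.feature.start)
        log.warning(
            "terminase subunits on opposite strands; falling back to the"
            " lowest-e-value candidate"
        )
    return min(candidates, key=lambda c: c.best_evalue)


def _rc_feature(draft: FeatureDraft, n: int) -> FeatureDraft:
    new_start = (n - draft.stop) % n if draft.wraps_origin else n - draft.stop
    new_stop = n - draft.start
    if draft.wraps_origin:
        new_stop = n - draft.start
    strand = "-" if draft.strand == "+" else "+"
    return replace(draft, start=new_start, stop=new_stop, strand=strand)


def _rotate_feature(draft: FeatureDraft, offset: int, n: int) -> FeatureDraft:
    length = draft.length(n)
    new_start = (draft.start - offset) % n
    end_abs = new_start + length
    if end_abs <= n:
        return replace(draft, start=new_start, stop=end_abs, wraps_origin=False)
    return replace(draft, start=new_start, stop=end_abs - n, wraps_origin=True)


def reorient_genome(
    sequence: str,
    features: Sequence[FeatureDraft],
    call: TerminaseCall | FeatureDraft,
) -> tuple[str, list[FeatureDraft]]:
    """Re-orient a genome so the terminase feature starts at coordinate 0.

    If the terminase lies on the minus strand the whole genome is
    reverse-complemented first; the sequence is then rotated so the terminase
    start becomes position 0.  Feature lengths, the feature count and CDS
    translations are preserved; features split by the rotation become
    origin-wrapping.
    """
    anchor = call.feature if isinstance(call, TerminaseCall) else call
    features = list(features)
    if anchor not in features:
        raise ValidationError("terminase feature does not belong to this genome")
    n = len(sequence)
    if anchor.strand == "-":
        sequence = revcomp(sequence)
        features = [_rc_feature(f, n) for f in features]
        anchor = _rc_feature(anchor, n)
    offset = anchor.start
    if offset:
        sequence = sequence[offset:] + sequence[:offset]
        features = [_rotate_feature(f, offset, n) for f in features]
    return sequence, features


# ---------------------------------------------------------------------------
# Upload orchestration
# ---------------------------------------------------------------------------

def upload_genome(
    store: Store, fasta_path: str | Path, name: str, options: UploadOptions
) -> GenomeRecord:
    """Full upload: read, call genes, optionally re-orient, persist.

    The upload is atomic: any failure leaves the store unchanged.  New
    protein annotations are created UNANNOTATED (shared across genomes when
    the protein is identical), tRNA annotations get the TRNA flag, and all
    annotations created by this upload are assigned to ``options.assign_to``
    when set.
    """
    options.validate()
    if store.has_genome(name):
        raise UniquenessError(f"genome name {name!r} already exists")
    header, sequence = read_single_fasta(fasta_path)

    if options.mode == "custom":
        drafts = load_user_features(options.features_path, len(sequence))
    elif options.gene_caller == "builtin":
        drafts = call_genes_builtin(
            sequence, min_aa_len=options.min_aa_len, genetic_code=options.genetic_code
        )
    elif options.gene_caller.startswith("external:"):
        adapter = options.gene_caller.split(":", 1)[1]
        drafts = run_external_caller(sequence, adapter, options.adapters or {})
    else:
        raise ValidationError(f"unknown gene caller: {options.gene_caller!r}")

    def _translate_all(seq: str, ds: list[FeatureDraft]) -> list[str]:
        return [
            translate_cds(
                seq, d.start, d.stop, d.strand,
                genetic_code=options.genetic_code, wraps_origin=d.wraps_origin,
            )
            for d in ds
            if d.kind == "CDS"
        ]

    cds_drafts = [d for d in drafts if d.kind == "CDS"]
    proteins = _translate_all(sequence, drafts)

    if options.mode == "phage" and options.reorient_terminase:
        if options.terminase_db is None:
            raise ConfigurationError(
                "terminase re-orientation requires a terminase database"
            )
        call = detect_terminase(
            cds_drafts, proteins, options.terminase_db, options.thresholds
        )
        if call is not None:
            sequence, drafts = reorient_genome(sequence, drafts, call)
            cds_drafts = [d for d in drafts if d.kind == "CDS"]
            proteins = _translate_all(sequence, drafts)
        else:
            log.info("no terminase evidence passed thresholds; genome kept as-is")

    if options.dtr_length is not None:
        if not options.dtr_length < len(sequence) / 2:
            raise ValidationError(
                "dtr_length must be less than half the genome length"
            )
        drafts = drafts + add_terminal_repeats(len(sequence), options.dtr_length)

    # Pair each draft with the sequence its annotation will be keyed on,
    # then persist everything in one transaction.
    protein_iter = iter(proteins)
    payloads: list[tuple[FeatureDraft, str, str, str | None]] = []
    for draft in drafts:
        if draft.kind == "CDS":
            payloads.append((draft, next(protein_iter), "protein", None))
        elif draft.kind == "tRNA":
            payloads.append(
                (draft, feature_nt_sequence(sequence, draft), "rna", "TRNA")
            )
        else:
            payloads.append(
                (draft, feature_nt_sequence(sequence, draft), "dna", "NONE")
            )
    payloads.sort(key=lambda p: (p[0].start, p[0].stop))

    with store.transaction():
        store.add_genome(
            name, sequence, topology=options.topology,
            organism_kind=options.mode if options.mode != "custom" else "custom",
        )
        for draft, seq_key, mol, flag in payloads:
            ann, _created = store.get_or_create_annotation(
                seq_key, mol, flag=flag,
                assigned_to=options.assign_to if options.assign_to else None,
            )
            store.add_feature(
                name, draft.kind, draft.start, draft.stop, draft.strand,
                ann.accession, wraps_origin=draft.wraps_origin,
            )
        store.mark_internal_db_stale(True)
    return store.get_genome(name)
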