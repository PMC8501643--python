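"""Homology evidence: parsers, the builtin protein search, and the internal DB.

Three search tools are modelled: protein-protein BLAST (``blastp``), profile
search against a domain database (``rpsblast``) and HMM-HMM search
(``hhsearch``).  Real searches run through external adapters; for offline use
the package ships a builtin Smith-Waterman search (BLOSUM62, affine gaps)
whose e-values come from the standard Karlin-Altschul bit-score formula with
published gapped-BLOSUM62 constants.  The builtin statistics are approximate
and intended for the internal and terminase databases, not as a BLAST
replacement.

The *internal database* holds one entry per distinct CDS protein in the
store, labelled ``accession|flag|label`` so previous curation decisions are
visible from search results.  It is rebuilt automatically whenever it is
searched after an edit or upload marked it stale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .errors import (
    AdapterUnavailableError,
    ConfigurationError,
    FormatError,
    NotFoundError,
    ValidationError,
)
from .config import Thresholds, DEFAULT_THRESHOLDS
from .store import Store

# Gapped BLOSUM62 Karlin-Altschul constants (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

BLAST_TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send"
    " evalue bitscore slen stitle"
).split()

SUPPORTED_COMBOS = {
    ("blastp", "swissprot"),
    ("blastp", "nr"),
    ("blastp", "internal"),
    ("blastp", "terminase"),
    ("rpsblast", "cdd"),
    ("hhsearch", "pdb"),
}


def is_supported_combo(tool: str, database: str) -> bool:
    if tool == "blastp" and database.startswith("custom:"):
        return True
    return (tool, database) in SUPPORTED_COMBOS


@dataclass(frozen=True)
class Hit:
    """One alignment between a query protein and a database subject.

    ``score`` is a bit score for blastp/rpsblast hits and the match
    probability (0-100) for hhsearch hits.  Coordinates are 1-based
    inclusive, matching the conventions of the source formats.
    """

    subject_id: str
    subject_description: str
    subject_length: int
    evalue: float
    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_query: Optional[str] = None
    aligned_subject: Optional[str] = None


@dataclass
class SearchResult:
    accession: str
    tool: str
    database: str
    run_time: str
    hits: list[Hit]
    raw_path: Optional[str] = None


@dataclass
class InternalDb:
    """Protein database of every distinct CDS annotation in a store."""

    entries: dict[str, tuple[str, str, str]]  # protein -> (accession, label, flag)
    built_at: str
    stale: bool = False

    def to_fasta(self) -> str:
        lines = []
        for protein, (acc, label, flag) in sorted(
            self.entries.items(), key=lambda kv: kv[1][0]
        ):
            lines.append(f">{acc}|{flag}|{label}")
            lines.extend(protein[i : i + 70] for i in range(0, len(protein), 70))
        return "\n".join(lines) + ("\n" if lines else "")

    def as_search_db(self) -> list[tuple[str, str, str]]:
        return [
            (acc, f"{acc}|{flag}|{label}", protein)
            for protein, (acc, label, flag) in sorted(
                self.entries.items(), key=lambda kv: kv[1][0]
            )
        ]


# ---------------------------------------------------------------------------
# Result-file parsers
# ---------------------------------------------------------------------------

def parse_blast_tabular(text: str, has_comments: bool = False) -> list[Hit]:
    """Parse NCBI BLAST tabular output (outfmt ``6 std slen stitle``).

    outfmt 7 (with ``#`` comment lines) is accepted when ``has_comments``.
    Hits are returned sorted by ascending e-value.
    """
    hits: list[Hit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if has_comments:
                continue
            raise FormatError("unexpected comment line in outfmt-6 input", lineno)
        fields = line.split("\t", maxsplit=13)
        if len(fields) != 14:
            raise FormatError(
                f"expected 14 columns ({' '.join(BLAST_TABULAR_COLUMNS)}),"
                f" got {len(fields)}",
                lineno,
            )
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            bitscore = float(fields[11])
            slen = int(fields[12])
        except ValueError as exc:
            raise FormatError(f"unparsable numeric field: {exc}", lineno) from exc
        if qstart > qend:
            raise FormatError(f"qstart {qstart} > qend {qend}", lineno)
        if sstart > send:
            raise FormatError(f"sstart {sstart} > send {send}", lineno)
        if evalue < 0:
            raise FormatError(f"negative e-value {evalue}", lineno)
        hits.append(
            Hit(
                subject_id=fields[1],
                subject_description=fields[13],
                subject_length=slen,
                evalue=evalue,
                score=bitscore,
                q_start=qstart,
                q_end=qend,
                s_start=sstart,
                s_end=send,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score))
    return hits


def write_blast_tabular(hits: list[Hit], query_id: str = "query") -> str:
    """Serialize hits back to the tabular dialect (round-trips with the parser)."""
    lines = []
    for h in hits:
        if h.aligned_query and h.aligned_subject:
            pairs = list(zip(h.aligned_query, h.aligned_subject))
            length = len(pairs)
            mismatch = sum(1 for a, b in pairs if a != b and a != "-" and b != "-")
            gapopen = 0
            prev_gap = False
            for a, b in pairs:
                gap = a == "-" or b == "-"
                if gap and not prev_gap:
                    gapopen += 1
                prev_gap = gap
            ident = sum(1 for a, b in pairs if a == b)
            pident = 100.0 * ident / length if length else 0.0
        else:
            length = h.q_end - h.q_start + 1
            mismatch = 0
            gapopen = 0
            pident = 100.0
        lines.append(
            "\t".join(
                [
                    query_id,
                    h.subject_id,
                    f"{pident:.3f}",
                    str(length),
                    str(mismatch),
                    str(gapopen),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    f"{h.evalue:.3g}",
                    f"{h.score:.1f}",
                    str(h.subject_length),
                    h.subject_description,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


_HHR_ROW = re.compile(
    r"^\s*(\d+)\s+(.+?)\s+([\d.]+)\s+(\S+)\s+(\S+)\s+([\d.-]+)\s+([\d.-]+)\s+"
    r"(\d+)\s+(\d+)-(\d+)\s+(\d+)-(\d+)\s*\((\d+)\)\s*$"
)


def parse_hhr(text: str) -> list[Hit]:
    """Parse an HH-suite ``.hhr`` report.

    One hit per summary-table row; ``score`` carries the Prob column (0-100)
    and ``evalue`` the E-value column.  Full subject descriptions are taken
    from the per-hit ``>`` header blocks when present.  Hits are returned in
    descending-probability order.
    """
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if re.match(r"^\s*No\s+Hit\s+Prob\s+E-value", line):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError("missing .hhr summary header ('No Hit Prob E-value ...')")

    hits: list[Hit] = []
    i = header_idx + 1
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            break
        m = _HHR_ROW.match(line)
        if m is None:
            raise FormatError("unparsable summary row", i + 1)
        (_, name, prob, evalue, _pval, _score, _ss, _cols,
         qs, qe, ts, te, tlen) = m.groups()
        subject_id = name.split()[0]
        desc = name[len(subject_id):].strip()
        try:
            hits.append(
                Hit(
                    subject_id=subject_id,
                    subject_description=desc,
                    subject_length=int(tlen),
                    evalue=float(evalue),
                    score=float(prob),
                    q_start=int(qs),
                    q_end=int(qe),
                    s_start=int(ts),
                    s_end=int(te),
                )
            )
        except ValueError as exc:
            raise FormatError(f"unparsable numeric field: {exc}", i + 1) from exc
        i += 1

    # Per-hit blocks carry untruncated descriptions.
    full_desc: dict[int, str] = {}
    current = None
    for line in lines[i:]:
        m = re.match(r"^No (\d+)\s*$", line)
        if m:
            current = int(m.group(1))
            continue
        if current is not None and line.startswith(">"):
            body = line[1:].strip()
            parts = body.split(None, 1)
            full_desc[current] = parts[1] if len(parts) == 2 else ""
            current = None
    if full_desc:
        hits = [
            Hit(
                h.subject_id, full_desc.get(rank, h.subject_description),
                h.subject_length, h.evalue, h.score,
                h.q_start, h.q_end, h.s_start, h.s_end,
                h.aligned_query, h.aligned_subject,
            )
            for rank, h in enumerate(hits, start=1)
        ]
    hits.sort(key=lambda h: (-h.score, h.evalue))
    return hits


# ---------------------------------------------------------------------------
# Builtin protein search
# ---------------------------------------------------------------------------

_BLOSUM62 = _balign.SubstitutionMatrix.std_protein_matrix()


def smith_waterman(query: str, subject: str):
    """Best local alignment (BLOSUM62, gap open 11 / extend 1).

    Returns ``(raw_score, q_start, q_end, s_start, s_end, aligned_q,
    aligned_s)`` with 1-based inclusive coordinates, or None when the best
    local score is 0.
    """
    try:
        q = _bseq.ProteinSequence(query)
        s = _bseq.ProteinSequence(subject)
    except Exception as exc:
        raise ValidationError(f"invalid protein sequence: {exc}") from exc
    aln = _balign.align_optimal(
        q, s, _BLOSUM62, gap_penalty=(-GAP_OPEN, -GAP_EXTEND), local=True
    )[0]
    if aln.score <= 0 or len(aln.trace) == 0:
        return None
    qcols = aln.trace[:, 0]
    scols = aln.trace[:, 1]
    gq, gs = aln.get_gapped_sequences()
    return (
        int(aln.score),
        int(qcols[qcols >= 0].min()) + 1,
        int(qcols[qcols >= 0].max()) + 1,
        int(scols[scols >= 0].min()) + 1,
        int(scols[scols >= 0].max()) + 1,
        gq,
        gs,
    )


def bit_score(raw_score: float) -> float:
    """Karlin-Altschul normalized score: (lambda*S - ln K) / ln 2."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def expect_value(bits: float, query_length: int, database_length: int) -> float:
    """E = m * n * 2^(-S')."""
    return query_length * database_length * math.pow(2.0, -bits)


def builtin_protein_search(
    query: str,
    database: list[tuple[str, str, str]],
    max_evalue: float = 10.0,
) -> list[Hit]:
    """Search a query protein against an in-memory database.

    ``database`` is a list of ``(id, description, protein)`` tuples.  Hits
    with e-value <= ``max_evalue`` are returned sorted by ascending e-value.
    """
    if not query:
        raise ValidationError("empty query protein")
    if not database:
        raise ConfigurationError("empty search database")
    m = len(query)
    n = sum(len(entry[2]) for entry in database)
    hits = []
    for subject_id, description, subject in database:
        res = smith_waterman(query, subject)
        if res is None:
            continue
        raw, qs, qe, ss, se, gq, gs = res
        bits = bit_score(raw)
        evalue = expect_value(bits, m, n)
        if evalue > max_evalue:
            continue
        hits.append(
            Hit(
                subject_id=subject_id,
                subject_description=description,
                subject_length=len(subject),
                evalue=evalue,
                score=bits,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                aligned_query=gq,
                aligned_subject=gs,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score))
    return hits


def load_protein_fasta(source: str | Path) -> list[tuple[str, str, str]]:
    """Read a protein FASTA file (or FASTA text) into (id, description, seq)."""
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith(">") and Path(source).exists()
    ):
        text = Path(source).read_text()
    entries: list[tuple[str, str, str]] = []
    header = None
    chunks: list[str] = []
    for line in str(text).splitlines():
        if line.startswith(">"):
            if header is not None:
                entries.append((*header, "".join(chunks)))
            body = line[1:].strip()
            parts = body.split(None, 1)
            header = (parts[0], parts[1] if len(parts) == 2 else "")
            chunks = []
        elif header is not None:
            chunks.append(line.strip())
    if header is not None:
        entries.append((*header, "".join(chunks)))
    return [(i, d, s.upper()) for (i, d, s) in entries if s]


# ---------------------------------------------------------------------------
# Internal database
# ---------------------------------------------------------------------------

def rebuild_internal_db(store: Store) -> InternalDb:
    """Rebuild the internal protein database from current store state.

    One entry per distinct CDS protein; metadata reflects the annotation's
    current accession, label and flag.
    """
    entries = {
        ann.sequence: (ann.accession, ann.label, ann.flag)
        for ann in store.distinct_proteins()
    }
    store.mark_internal_db_stale(False)
    return InternalDb(entries=entries, built_at=store.clock(), stale=False)


# ---------------------------------------------------------------------------
# Backends and orchestration
# ---------------------------------------------------------------------------

class BuiltinBackend:
    """Offline backend for blastp-style searches.

    Supports the internal database (built from the store), the terminase
    database, and arbitrary ``custom:<name>`` protein FASTA databases.
    Swiss-Prot / nr / CDD / PDB searches require external adapters and raise
    :class:`AdapterUnavailableError` here.
    """

    def __init__(
        self,
        store: Store | None = None,
        terminase_db: str | Path | list | None = None,
        custom_dbs: dict[str, str | Path | list] | None = None,
        max_evalue: float = 10.0,
    ):
        self.store = store
        self.terminase_db = terminase_db
        self.custom_dbs = custom_dbs or {}
        self.max_evalue = max_evalue
        self._internal: InternalDb | None = None

    def _resolve(self, source) -> list[tuple[str, str, str]]:
        if isinstance(source, list):
            return source
        return load_protein_fasta(source)

    def search(self, accession: str, protein: str, tool: str, database: str) -> list[Hit]:
        if tool != "blastp":
            raise AdapterUnavailableError(
                f"{tool} searches require an external adapter"
            )
        if database == "internal":
            if self.store is None:
                raise ConfigurationError("builtin internal search requires a store")
            if self._internal is None or self.store.internal_db_stale:
                self._internal = rebuild_internal_db(self.store)
            db = self._internal.as_search_db()
            # never report the query's own database entry as evidence
            db = [e for e in db if e[0] != accession]
            if not db:
                return []
        elif database == "terminase":
            if self.terminase_db is None:
                raise ConfigurationError("no terminase database configured")
            db = self._resolve(self.terminase_db)
        elif database.startswith("custom:"):
            name = database.split(":", 1)[1]
            if name not in self.custom_dbs:
                raise ConfigurationError(f"unknown custom database {name!r}")
            db = self._resolve(self.custom_dbs[name])
        else:
            raise AdapterUnavailableError(
                f"blastp vs {database} requires an external adapter"
            )
        return builtin_protein_search(protein, db, max_evalue=self.max_evalue)


class RecordedBackend:
    """Backend replaying pre-recorded result files (tests, mock evidence).

    ``files`` maps ``(tool, database)`` to ``{accession_or_'*': text}``; blast
    tabular text is parsed with :func:`parse_blast_tabular`, hhsearch text
    with :func:`parse_hhr`.
    """

    def __init__(self, files: dict[tuple[str, str], dict[str, str]]):
        self.files = files

    def search(self, accession: str, protein: str, tool: str, database: str) -> list[Hit]:
        key = (tool, database)
        if key not in self.files:
            raise AdapterUnavailableError(f"no recorded output for {tool} vs {database}")
        per_query = self.files[key]
        text = per_query.get(accession, per_query.get("*"))
        if text is None:
            return []
        if tool == "hhsearch":
            return parse_hhr(text)
        return parse_blast_tabular(text, has_comments=text.lstrip().startswith("#"))


def run_search(
    store: Store,
    accession: str,
    tool: str,
    database: str,
    backend,
    raw_dir: str | Path | None = None,
) -> SearchResult:
    """Execute one (tool, database) search for one annotation and persist it.

    Reruns supersede the stored result for the same (annotation, tool,
    database).  Searching the internal database after an edit or upload
    rebuilds it first.
    """
    if not is_supported_combo(tool, database):
        raise ValidationError(f"unsupported search combination: {tool} vs {database}")
    ann = store.get_annotation(accession)
    if ann.molecule_kind != "protein":
        raise ValidationError("only protein (CDS) annotations are searchable")
    hits = backend.search(accession, ann.sequence, tool, database)
    raw_path = None
    if raw_dir is not None:
        raw_dir = Path(raw_dir)
        raw_dir.mkdir(parents=True, exist_ok=True)
        raw_path = str(raw_dir / f"{accession}_{tool}_{database.replace(':', '_')}.tsv")
        Path(raw_path).write_text(write_blast_tabular(hits, query_id=accession))
    store.save_search_result(accession, tool, database, hits, raw_path)
    return SearchResult(accession, tool, database, store.clock(), hits, raw_path)


@dataclass
class GenomeSearchSummary:
    results: list[SearchResult] = field(default_factory=list)
    failures: list[tuple[str, str, str, str]] = field(default_factory=list)


def run_genome_searches(
    store: Store,
    genome_name: str,
    combos: list[tuple[str, str]],
    backend,
    raw_dir: str | Path | None = None,
) -> GenomeSearchSummary:
    """Search every CDS annotation of a genome for every combo.

    Per-search failures are collected in the summary rather than raised.
    """
    genome = store.get_genome(genome_name)
    seen: list[str] = []
    for feat in genome.features:
        if feat.kind == "CDS" and feat.accession not in seen:
            seen.append(feat.accession)
    summary = GenomeSearchSummary()
    for accession in seen:
        for tool, database in combos:
            try:
                summary.results.append(
                    run_search(store, accession, tool, database, backend, raw_dir)
                )
            except Exception as exc:  # collected, not fatal
                summary.failures.append((accession, tool, database, str(exc)))
    return summary
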