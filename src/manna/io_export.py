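"""Standard-format export and spreadsheet import.

Writers convert the store's 0-based half-open coordinates to the 1-based
inclusive convention of GenBank and GFF3.  Private notes are deliberately
excluded from every sequence-format export; they appear only in the
annotation table, which is the editable interchange format (TSV always, an
Office Open XML workbook optionally).

The per-genome export bundle is a gzip tarball of genome FASTA, CDS
translations, GFF3, annotation table and GenBank flat file; with a fixed
store clock the archive is byte-reproducible.
"""

from __future__ import annotations

import gzip
import io
import tarfile
from datetime import datetime
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, NotFoundError, ValidationError
from .ingest import feature_nt_sequence, translate_cds
from .store import GenomeRecord, Store

ANNOTATION_TABLE_COLUMNS = [
    "accession", "label", "flag", "public_notes", "private_notes",
    "assigned_to", "sequence", "genome", "start", "stop", "strand",
]

_DIVISIONS = {"phage": "PHG", "bacterial": "BCT", "custom": "UNA"}


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_genome_fasta(genome: GenomeRecord) -> str:
    """Single-record FASTA, header = genome name, 70-column wrapping."""
    return f">{genome.name}\n{_wrap(genome.sequence)}\n"


def write_cds_translations(store: Store, genome: GenomeRecord) -> str:
    """Multi-FASTA of CDS translations in genomic order, 'accession label' headers."""
    records = []
    for f in genome.features:
        if f.kind != "CDS":
            continue
        ann = store.get_annotation(f.accession)
        header = f"{ann.accession} {ann.label}".rstrip()
        records.append(f">{header}\n{_wrap(ann.sequence)}")
    return "\n".join(records) + ("\n" if records else "")


def write_gff3(store: Store, genome: GenomeRecord) -> str:
    """GFF3 with 1-based inclusive coordinates; wrapped features as two lines."""
    lines = ["##gff-version 3", f"##sequence-region {genome.name} 1 {len(genome)}"]
    for f in genome.features:
        ann = store.get_annotation(f.accession)
        attrs = f"ID={ann.accession};product={ann.label};mas_flag={ann.flag}"
        if f.wraps_origin:
            segments = [(f.start + 1, len(genome)), (1, f.stop)]
        else:
            segments = [(f.start + 1, f.stop)]
        for a, b in segments:
            lines.append(
                "\t".join(
                    [genome.name, "manna", f.kind, str(a), str(b), ".", f.strand,
                     "0" if f.kind == "CDS" else ".", attrs]
                )
            )
    return "\n".join(lines) + "\n"


def _biopython_location(f, genome_length: int):
    strand = 1 if f.strand == "+" else -1
    if not f.wraps_origin:
        return FeatureLocation(f.start, f.stop, strand=strand)
    parts = [
        FeatureLocation(f.start, genome_length, strand=strand),
        FeatureLocation(0, f.stop, strand=strand),
    ]
    if strand == -1:
        parts.reverse()
    return CompoundLocation(parts)


def write_genbank(store: Store, genome: GenomeRecord) -> str:
    """GenBank flat file; public notes exported, private notes never."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.name.replace(" ", "_")[:16] or "genome",
        name=genome.name.replace(" ", "_")[:16] or "genome",
        description=genome.name,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    record.annotations["data_file_division"] = _DIVISIONS.get(
        genome.organism_kind, "UNA"
    )
    try:
        stamp = datetime.strptime(genome.upload_time[:10], "%Y-%m-%d")
        record.annotations["date"] = stamp.strftime("%d-%b-%Y").upper()
    except ValueError:
        pass  # Biopython falls back to a fixed default date
    record.features.append(
        SeqFeature(
            FeatureLocation(0, len(genome), strand=1),
            type="source",
            qualifiers={"organism": [genome.name]},
        )
    )
    for f in genome.features:
        ann = store.get_annotation(f.accession)
        qualifiers: dict[str, list[str]] = {}
        if f.kind == "CDS":
            qualifiers["product"] = [ann.label or "hypothetical protein"]
            qualifiers["protein_id"] = [ann.accession]
            qualifiers["translation"] = [ann.sequence]
        elif f.kind == "tRNA":
            qualifiers["product"] = [ann.label or "tRNA"]
        else:
            qualifiers["rpt_type"] = ["direct"]
        if ann.public_notes:
            qualifiers.setdefault("note", []).append(ann.public_notes)
        record.features.append(
            SeqFeature(
                _biopython_location(f, len(genome)), type=f.kind, qualifiers=qualifiers
            )
        )
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


def write_annotation_table(
    store: Store, genome: GenomeRecord | None = None, scope: str = "genome"
) -> pd.DataFrame:
    """Feature/annotation table.

    ``scope='genome'``: one row per feature of ``genome`` with 1-based
    inclusive coordinates.  ``scope='store'``: one row per annotation, genome
    columns blank.
    """
    rows = []
    if scope == "genome":
        if genome is None:
            raise ValidationError("genome scope requires a genome")
        for f in genome.features:
            ann = store.get_annotation(f.accession)
            rows.append(
                [ann.accession, ann.label, ann.flag, ann.public_notes,
                 ann.private_notes, ann.assigned_to or "", ann.sequence,
                 genome.name, f.start + 1, f.stop if not f.wraps_origin else f.stop,
                 f.strand]
            )
    elif scope == "store":
        for ann in store.annotations():
            rows.append(
                [ann.accession, ann.label, ann.flag, ann.public_notes,
                 ann.private_notes, ann.assigned_to or "", ann.sequence,
                 "", "", "", ""]
            )
    else:
        raise ValidationError(f"unknown scope: {scope!r}")
    return pd.DataFrame(rows, columns=ANNOTATION_TABLE_COLUMNS)


def annotation_table_tsv(table: pd.DataFrame) -> str:
    return table.to_csv(sep="\t", index=False)


def annotation_table_xlsx(table: pd.DataFrame, path: str | Path) -> None:
    """Optional Office Open XML rendering of the annotation table."""
    table.to_excel(path, index=False)


def import_annotation_table(store: Store, source, user: str) -> dict:
    """Import label/notes/flag edits, matching rows to annotations by sequence.

    ``source`` may be a DataFrame, a TSV path/text, or an .xlsx path.  Rows
    must have ``sequence`` and ``label`` columns; ``flag``, ``public_notes``
    and ``private_notes`` are applied when present.  Matching is exact and
    case-insensitive on the sequence.  Returns
    ``{"matched": int, "updated": int, "unmatched": [row dicts]}``.
    """
    if isinstance(source, pd.DataFrame):
        table = source
    elif "\n" in str(source) or "\t" in str(source):
        table = pd.read_csv(io.StringIO(str(source)), sep="\t", dtype=str).fillna("")
    else:
        path = Path(str(source))
        if path.suffix.lower() in (".xlsx", ".xlsm"):
            table = pd.read_excel(path, dtype=str).fillna("")
        else:
            table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sequence", "label"} - set(table.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")

    # proteins take precedence; tRNA/repeat annotations are matchable too so a
    # re-imported genome export is a clean fixed point
    by_sequence = {}
    for ann in store.annotations():
        if ann.molecule_kind != "protein":
            by_sequence.setdefault(ann.sequence.upper(), ann.accession)
    for ann in store.distinct_proteins():
        by_sequence[ann.sequence.upper()] = ann.accession
    matched = updated = 0
    unmatched = []
    optional = [c for c in ("flag", "public_notes", "private_notes") if c in table.columns]
    for _, row in table.iterrows():
        seq = str(row["sequence"]).strip().upper()
        accession = by_sequence.get(seq)
        if accession is None:
            unmatched.append({c: row[c] for c in table.columns})
            continue
        matched += 1
        changes = {"label": str(row["label"])}
        for col in optional:
            value = row[col]
            if pd.notna(value) and str(value) != "":
                changes[col] = str(value)
        before = len(store.get_history(accession))
        store.update_annotation(accession, changes, user)
        if len(store.get_history(accession)) > before:
            updated += 1
    return {"matched": matched, "updated": updated, "unmatched": unmatched}


def export_bundle(store: Store, genome_name: str, out_path: str | Path) -> Path:
    """Write the per-genome export tarball.

    Members, in fixed order: ``<name>.fasta``, ``<name>_proteins.faa``,
    ``<name>.gff3``, ``<name>_annotations.tsv``, ``<name>.gbk``.  Timestamps
    inside the archive are fixed so identical store state produces identical
    bytes.  On failure no partial file is left behind.
    """
    genome = store.get_genome(genome_name)
    safe = genome_name.replace(" ", "_")
    members = [
        (f"{safe}.fasta", write_genome_fasta(genome)),
        (f"{safe}_proteins.faa", write_cds_translations(store, genome)),
        (f"{safe}.gff3", write_gff3(store, genome)),
        (
            f"{safe}_annotations.tsv",
            annotation_table_tsv(write_annotation_table(store, genome, "genome")),
        ),
        (f"{safe}.gbk", write_genbank(store, genome)),
    ]
    out_path = Path(out_path)
    tmp_path = out_path.with_suffix(out_path.suffix + ".part")
    try:
        with open(tmp_path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
                with tarfile.open(fileobj=gz, mode="w") as tar:
                    for member_name, text in members:
                        data = text.encode()
                        info = tarfile.TarInfo(name=member_name)
                        info.size = len(data)
                        info.mtime = 0
                        info.uid = info.gid = 0
                        info.uname = info.gname = ""
                        tar.addfile(info, io.BytesIO(data))
        tmp_path.replace(out_path)
    except BaseException:
        tmp_path.unlink(missing_ok=True)
        raise
    return out_path
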