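"""Embedded annotation store.

A single-file sqlite database holds genomes, their located features, and the
sequence-deduplicated annotations those features point at.  The central
modelling rule: two features share one annotation exactly when their
sequences are identical (protein sequence for CDS features, nucleotide
sequence for tRNA / repeat features).  Annotations carry an auto-assigned
accession, a label, a triage flag, public/private notes and an optional user
assignment; every edit is recorded as an append-only event so the history of
an annotation can be replayed.

Coordinates are stored 0-based half-open.  A feature that spans the origin of
a (conceptually circular) genome has ``wraps_origin=True`` and ``start >
stop``; its length is ``N - start + stop``.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from .errors import (
    NotFoundError,
    StoreError,
    UniquenessError,
    ValidationError,
)

FLAGS = (
    "UNANNOTATED",
    "REVIEW_NAME",
    "TRNA",
    "GREEN",
    "RED",
    "BLUE",
    "PURPLE",
    "YELLOW",
    "ORANGE",
    "NONE",
)

FEATURE_KINDS = ("CDS", "tRNA", "repeat_region")
MOLECULE_KINDS = ("protein", "rna", "dna")
EDITABLE_FIELDS = ("label", "flag", "public_notes", "private_notes", "assigned_to")

ACCESSION_FORMAT = "MAS_{:07d}"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (
    key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS genome (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    sequence TEXT NOT NULL,
    topology TEXT NOT NULL DEFAULT 'linear',
    organism_kind TEXT NOT NULL DEFAULT 'phage',
    upload_time TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS annotation (
    id INTEGER PRIMARY KEY,
    accession TEXT NOT NULL UNIQUE,
    sequence TEXT NOT NULL,
    molecule_kind TEXT NOT NULL,
    label TEXT NOT NULL DEFAULT '',
    flag TEXT NOT NULL DEFAULT 'NONE',
    public_notes TEXT NOT NULL DEFAULT '',
    private_notes TEXT NOT NULL DEFAULT '',
    assigned_to TEXT,
    UNIQUE (sequence, molecule_kind));
CREATE TABLE IF NOT EXISTS feature (
    id INTEGER PRIMARY KEY,
    genome_id INTEGER NOT NULL REFERENCES genome(id),
    kind TEXT NOT NULL,
    start INTEGER NOT NULL,
    stop INTEGER NOT NULL,
    strand TEXT NOT NULL,
    wraps_origin INTEGER NOT NULL DEFAULT 0,
    annotation_id INTEGER NOT NULL REFERENCES annotation(id));
CREATE TABLE IF NOT EXISTS annotation_event (
    id INTEGER PRIMARY KEY,
    annotation_id INTEGER NOT NULL REFERENCES annotation(id),
    timestamp TEXT NOT NULL,
    user TEXT NOT NULL,
    field_changed TEXT NOT NULL,
    old_value TEXT NOT NULL,
    new_value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS search_result (
    id INTEGER PRIMARY KEY,
    annotation_id INTEGER NOT NULL REFERENCES annotation(id),
    tool TEXT NOT NULL,
    database TEXT NOT NULL,
    run_time TEXT NOT NULL,
    raw_path TEXT,
    UNIQUE (annotation_id, tool, database));
CREATE TABLE IF NOT EXISTS hit (
    id INTEGER PRIMARY KEY,
    search_result_id INTEGER NOT NULL REFERENCES search_result(id) ON DELETE CASCADE,
    rank INTEGER NOT NULL,
    subject_id TEXT NOT NULL,
    subject_description TEXT NOT NULL DEFAULT '',
    subject_length INTEGER NOT NULL,
    evalue REAL NOT NULL,
    score REAL NOT NULL,
    q_start INTEGER NOT NULL,
    q_end INTEGER NOT NULL,
    s_start INTEGER NOT NULL,
    s_end INTEGER NOT NULL,
    aligned_query TEXT,
    aligned_subject TEXT);
CREATE INDEX IF NOT EXISTS ix_feature_genome ON feature(genome_id, start);
CREATE INDEX IF NOT EXISTS ix_event_annotation ON annotation_event(annotation_id, id);
"""


@dataclass(frozen=True)
class Annotation:
    accession: str
    sequence: str
    molecule_kind: str
    label: str = ""
    flag: str = "UNANNOTATED"
    public_notes: str = ""
    private_notes: str = ""
    assigned_to: Optional[str] = None


@dataclass(frozen=True)
class Feature:
    genome: str
    kind: str
    start: int
    stop: int
    strand: str
    wraps_origin: bool
    accession: str
    feature_id: int = 0

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.stop
        return self.stop - self.start


@dataclass(frozen=True)
class GenomeRecord:
    name: str
    sequence: str
    topology: str
    organism_kind: str
    upload_time: str
    features: tuple[Feature, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationEvent:
    accession: str
    timestamp: str
    user: str
    field_changed: str
    old_value: str
    new_value: str


def replay_history(initial: dict, events: Iterable[AnnotationEvent]) -> dict:
    """Fold events over an initial field map; returns the resulting state."""
    state = dict(initial)
    for ev in events:
        state[ev.field_changed] = ev.new_value
    return state


def _utcnow() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


class Store:
    """Transactional handle over the single-file annotation database.

    Parameters
    ----------
    path:
        Database file ("" or ":memory:" for an in-memory store).
    clock:
        Callable returning the timestamp string to stamp on new rows;
        override with a constant for reproducible exports.
    """

    def __init__(self, path: str | Path, clock: Callable[[], str] | None = None):
        self.path = str(path)
        self.clock = clock or _utcnow
        try:
            self._db = sqlite3.connect(self.path, timeout=30.0)
            self._db.execute("PRAGMA foreign_keys = ON")
            self._db.executescript(_SCHEMA)
            self._db.execute(
                "INSERT OR IGNORE INTO meta VALUES ('accession_counter', '0')"
            )
            self._db.execute(
                "INSERT OR IGNORE INTO meta VALUES ('internal_db_stale', '1')"
            )
            self._db.commit()
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"cannot open store at {self.path}: {exc}") from exc

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self._db.close()

    from contextlib import contextmanager as _contextmanager

    @_contextmanager
    def transaction(self):
        """Group several store operations into one atomic unit.

        On any exception everything since entry is rolled back, including
        accession-counter advances that never reached a committed state.
        """
        if getattr(self, "_in_txn", False):
            yield self
            return
        self._in_txn = True
        try:
            yield self
            self._db.commit()
        except BaseException:
            self._db.rollback()
            raise
        finally:
            self._in_txn = False

    def _commit(self) -> None:
        if not getattr(self, "_in_txn", False):
            self._db.commit()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- meta --------------------------------------------------------------

    def _get_meta(self, key: str) -> str:
        row = self._db.execute("SELECT value FROM meta WHERE key=?", (key,)).fetchone()
        return row[0]

    def _set_meta(self, key: str, value: str) -> None:
        self._db.execute(
            "INSERT INTO meta VALUES (?,?) ON CONFLICT(key) DO UPDATE SET value=excluded.value",
            (key, value),
        )

    @property
    def internal_db_stale(self) -> bool:
        return self._get_meta("internal_db_stale") == "1"

    def mark_internal_db_stale(self, stale: bool = True) -> None:
        self._set_meta("internal_db_stale", "1" if stale else "0")
        self._commit()

    # -- accessions --------------------------------------------------------

    def assign_accession(self) -> str:
        """Next accession: zero-padded monotone counter, never reused."""
        n = int(self._get_meta("accession_counter")) + 1
        self._set_meta("accession_counter", str(n))
        return ACCESSION_FORMAT.format(n)

    # -- annotations -------------------------------------------------------

    def get_or_create_annotation(
        self,
        sequence: str,
        molecule_kind: str,
        *,
        flag: str | None = None,
        assigned_to: str | None = None,
    ) -> tuple[Annotation, bool]:
        """Return the unique annotation for (sequence, molecule_kind).

        Creates it with a fresh accession when absent (created=True).  New
        protein annotations default to the UNANNOTATED flag; tRNA callers
        pass flag="TRNA".
        """
        if not sequence:
            raise ValidationError("annotation sequence must be non-empty")
        if molecule_kind not in MOLECULE_KINDS:
            raise ValidationError(f"unknown molecule kind: {molecule_kind!r}")
        sequence = sequence.upper()
        row = self._db.execute(
            "SELECT accession FROM annotation WHERE sequence=? AND molecule_kind=?",
            (sequence, molecule_kind),
        ).fetchone()
        if row:
            return self.get_annotation(row[0]), False
        if flag is None:
            flag = "UNANNOTATED" if molecule_kind == "protein" else "NONE"
        if flag not in FLAGS:
            raise ValidationError(f"unknown flag: {flag!r}")
        accession = self.assign_accession()
        self._db.execute(
            "INSERT INTO annotation (accession, sequence, molecule_kind, flag, assigned_to)"
            " VALUES (?,?,?,?,?)",
            (accession, sequence, molecule_kind, flag, assigned_to),
        )
        self._commit()
        return self.get_annotation(accession), True

    def get_annotation(self, accession: str) -> Annotation:
        row = self._db.execute(
            "SELECT accession, sequence, molecule_kind, label, flag, public_notes,"
            " private_notes, assigned_to FROM annotation WHERE accession=?",
            (accession,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no annotation with accession {accession!r}")
        return Annotation(*row)

    def _annotation_id(self, accession: str) -> int:
        row = self._db.execute(
            "SELECT id FROM annotation WHERE accession=?", (accession,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no annotation with accession {accession!r}")
        return row[0]

    def update_annotation(self, accession: str, changes: dict, user: str) -> Annotation:
        """Apply field edits; one history event per actually-changed field."""
        current = self.get_annotation(accession)
        ann_id = self._annotation_id(accession)
        bad = set(changes) - set(EDITABLE_FIELDS)
        if bad:
            raise ValidationError(f"fields not editable: {sorted(bad)}")
        if "flag" in changes and changes["flag"] not in FLAGS:
            raise ValidationError(f"unknown flag: {changes['flag']!r}")
        now = self.clock()
        touched = False
        for fld, new in changes.items():
            old = getattr(current, fld)
            old_txt = "" if old is None else str(old)
            new_txt = "" if new is None else str(new)
            if old_txt == new_txt:
                continue  # no-op edits leave no trace
            self._db.execute(
                f"UPDATE annotation SET {fld}=? WHERE id=?", (new, ann_id)
            )
            self._db.execute(
                "INSERT INTO annotation_event"
                " (annotation_id, timestamp, user, field_changed, old_value, new_value)"
                " VALUES (?,?,?,?,?,?)",
                (ann_id, now, user, fld, old_txt, new_txt),
            )
            touched = True
        if touched:
            self._set_meta("internal_db_stale", "1")
        self._commit()
        return self.get_annotation(accession)

    def get_history(self, accession: str) -> list[AnnotationEvent]:
        ann_id = self._annotation_id(accession)
        rows = self._db.execute(
            "SELECT timestamp, user, field_changed, old_value, new_value"
            " FROM annotation_event WHERE annotation_id=? ORDER BY id",
            (ann_id,),
        ).fetchall()
        return [AnnotationEvent(accession, *r) for r in rows]

    def annotations(self) -> list[Annotation]:
        rows = self._db.execute(
            "SELECT accession FROM annotation ORDER BY accession"
        ).fetchall()
        return [self.get_annotation(r[0]) for r in rows]

    def delete_annotation(self, accession: str) -> None:
        """Remove an orphaned annotation; its accession is never reissued."""
        ann_id = self._annotation_id(accession)
        used = self._db.execute(
            "SELECT COUNT(*) FROM feature WHERE annotation_id=?", (ann_id,)
        ).fetchone()[0]
        if used:
            raise ValidationError("annotation is referenced by features")
        self._db.execute("DELETE FROM annotation_event WHERE annotation_id=?", (ann_id,))
        self._db.execute("DELETE FROM annotation WHERE id=?", (ann_id,))
        self._commit()

    # -- genomes & features --------------------------------------------------

    def add_genome(
        self,
        name: str,
        sequence: str,
        topology: str = "linear",
        organism_kind: str = "phage",
    ) -> GenomeRecord:
        if not name:
            raise ValidationError("genome name must be non-empty")
        if not sequence:
            raise ValidationError("genome sequence must be non-empty")
        if organism_kind not in ("phage", "bacterial", "custom"):
            raise ValidationError(f"unknown organism kind: {organism_kind!r}")
        try:
            self._db.execute(
                "INSERT INTO genome (name, sequence, topology, organism_kind, upload_time)"
                " VALUES (?,?,?,?,?)",
                (name, sequence.upper(), topology, organism_kind, self.clock()),
            )
        except sqlite3.IntegrityError as exc:
            raise UniquenessError(f"genome name {name!r} already exists") from exc
        self._commit()
        return self.get_genome(name)

    def _genome_id(self, name: str) -> int:
        row = self._db.execute("SELECT id FROM genome WHERE name=?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"no genome named {name!r}")
        return row[0]

    def has_genome(self, name: str) -> bool:
        return (
            self._db.execute("SELECT 1 FROM genome WHERE name=?", (name,)).fetchone()
            is not None
        )

    def get_genome(self, name: str) -> GenomeRecord:
        row = self._db.execute(
            "SELECT id, name, sequence, topology, organism_kind, upload_time"
            " FROM genome WHERE name=?",
            (name,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no genome named {name!r}")
        gid, name, seq, topo, kind, t = row
        feats = self._features_of(gid, name)
        return GenomeRecord(name, seq, topo, kind, t, tuple(feats))

    def genome_names(self) -> list[str]:
        return [
            r[0]
            for r in self._db.execute("SELECT name FROM genome ORDER BY id").fetchall()
        ]

    def _features_of(self, genome_id: int, genome_name: str) -> list[Feature]:
        rows = self._db.execute(
            "SELECT f.kind, f.start, f.stop, f.strand, f.wraps_origin, a.accession, f.id"
            " FROM feature f JOIN annotation a ON a.id = f.annotation_id"
            " WHERE f.genome_id=? ORDER BY f.start, f.stop",
            (genome_id,),
        ).fetchall()
        return [
            Feature(genome_name, k, s, e, st, bool(w), acc, fid)
            for (k, s, e, st, w, acc, fid) in rows
        ]

    def add_feature(
        self,
        genome_name: str,
        kind: str,
        start: int,
        stop: int,
        strand: str,
        accession: str,
        wraps_origin: bool = False,
    ) -> Feature:
        gid = self._genome_id(genome_name)
        n = len(
            self._db.execute(
                "SELECT sequence FROM genome WHERE id=?", (gid,)
            ).fetchone()[0]
        )
        if kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind: {kind!r}")
        if strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
        if not wraps_origin and not (0 <= start < stop <= n):
            raise ValidationError(
                f"feature [{start},{stop}) outside genome of length {n}"
            )
        if wraps_origin and not (0 <= stop < start < n):
            raise ValidationError(
                f"wrapped feature requires stop < start, got [{start},{stop})"
            )
        ann_id = self._annotation_id(accession)
        cur = self._db.execute(
            "INSERT INTO feature (genome_id, kind, start, stop, strand, wraps_origin,"
            " annotation_id) VALUES (?,?,?,?,?,?,?)",
            (gid, kind, start, stop, strand, int(wraps_origin), ann_id),
        )
        self._commit()
        return Feature(genome_name, kind, start, stop, strand, wraps_origin, accession, cur.lastrowid)

    # -- list views ----------------------------------------------------------

    def list_genomes(
        self, filter: str | None = None, sort_key: str | None = None, ascending: bool = True
    ) -> pd.DataFrame:
        """Genome summary table: name, length, features, one count per flag."""
        names = self.genome_names()
        if filter:
            needle = filter.lower()
            names = [n for n in names if needle in n.lower()]
        rows = []
        for name in names:
            g = self.get_genome(name)
            counts = dict.fromkeys(FLAGS, 0)
            for f in g.features:
                counts[self.get_annotation(f.accession).flag] += 1
            rows.append(
                {"name": name, "length": len(g), "features": len(g.features), **counts}
            )
        table = pd.DataFrame(rows, columns=["name", "length", "features", *FLAGS])
        if sort_key is not None:
            if sort_key not in table.columns:
                raise ValidationError(f"unknown sort key: {sort_key!r}")
            table = table.sort_values(sort_key, ascending=ascending, kind="stable")
        return table.reset_index(drop=True)

    def list_annotations(
        self,
        flag: str | None = None,
        assigned_to: str | None = None,
        text: str | None = None,
        order: str = "accession",
        genome: str | None = None,
    ) -> pd.DataFrame:
        """Annotation table ordered by accession, or genomic order in a genome.

        Flag / assignment navigation sorts by accession; genome navigation
        sorts by feature start coordinate and requires ``genome``.
        """
        if order not in ("accession", "genomic"):
            raise ValidationError(f"unknown order: {order!r}")
        if order == "genomic":
            if genome is None:
                raise ValidationError("genomic order requires a genome name")
            g = self.get_genome(genome)
            anns = [(self.get_annotation(f.accession), f) for f in g.features]
            rows = [
                {
                    "accession": a.accession,
                    "label": a.label,
                    "flag": a.flag,
                    "assigned_to": a.assigned_to,
                    "molecule_kind": a.molecule_kind,
                    "genome": genome,
                    "start": f.start,
                    "stop": f.stop,
                    "strand": f.strand,
                }
                for a, f in anns
            ]
            cols = [
                "accession", "label", "flag", "assigned_to", "molecule_kind",
                "genome", "start", "stop", "strand",
            ]
        else:
            rows = [
                {
                    "accession": a.accession,
                    "label": a.label,
                    "flag": a.flag,
                    "assigned_to": a.assigned_to,
                    "molecule_kind": a.molecule_kind,
                }
                for a in self.annotations()
            ]
            cols = ["accession", "label", "flag", "assigned_to", "molecule_kind"]
        table = pd.DataFrame(rows, columns=cols)
        if flag is not None:
            if flag not in FLAGS:
                raise ValidationError(f"unknown flag: {flag!r}")
            table = table[table["flag"] == flag]
        if assigned_to is not None:
            table = table[table["assigned_to"] == assigned_to]
        if text:
            needle = text.lower()
            mask = table["label"].str.lower().str.contains(needle, regex=False) | table[
                "accession"
            ].str.lower().str.contains(needle, regex=False)
            table = table[mask]
        if order == "accession":
            table = table.sort_values("accession", kind="stable")
        else:
            table = table.sort_values(["start", "stop"], kind="stable")
        return table.reset_index(drop=True)

    # -- search results -------------------------------------------------------

    def save_search_result(
        self, accession: str, tool: str, database: str, hits, raw_path: str | None = None
    ) -> None:
        """Persist a search result; a rerun of (accession, tool, db) supersedes."""
        ann_id = self._annotation_id(accession)
        old = self._db.execute(
            "SELECT id FROM search_result WHERE annotation_id=? AND tool=? AND database=?",
            (ann_id, tool, database),
        ).fetchone()
        if old:
            self._db.execute("DELETE FROM hit WHERE search_result_id=?", (old[0],))
            self._db.execute("DELETE FROM search_result WHERE id=?", (old[0],))
        cur = self._db.execute(
            "INSERT INTO search_result (annotation_id, tool, database, run_time, raw_path)"
            " VALUES (?,?,?,?,?)",
            (ann_id, tool, database, self.clock(), raw_path),
        )
        sr_id = cur.lastrowid
        for rank, h in enumerate(hits):
            self._db.execute(
                "INSERT INTO hit (search_result_id, rank, subject_id, subject_description,"
                " subject_length, evalue, score, q_start, q_end, s_start, s_end,"
                " aligned_query, aligned_subject) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
                (
                    sr_id, rank, h.subject_id, h.subject_description, h.subject_length,
                    h.evalue, h.score, h.q_start, h.q_end, h.s_start, h.s_end,
                    h.aligned_query, h.aligned_subject,
                ),
            )
        self._commit()

    def search_results_for(self, accession: str) -> dict[tuple[str, str], list]:
        """All stored hits for one annotation, keyed by (tool, database)."""
        from .homology import Hit  # local import: avoids a module cycle

        ann_id = self._annotation_id(accession)
        out: dict[tuple[str, str], list] = {}
        for sr_id, tool, db in self._db.execute(
            "SELECT id, tool, database FROM search_result WHERE annotation_id=?",
            (ann_id,),
        ).fetchall():
            rows = self._db.execute(
                "SELECT subject_id, subject_description, subject_length, evalue, score,"
                " q_start, q_end, s_start, s_end, aligned_query, aligned_subject"
                " FROM hit WHERE search_result_id=? ORDER BY rank",
                (sr_id,),
            ).fetchall()
            out[(tool, db)] = [Hit(*r) for r in rows]
        return out

    # -- internal-db support ---------------------------------------------------

    def distinct_proteins(self) -> list[Annotation]:
        """One annotation per distinct CDS protein in the store."""
        rows = self._db.execute(
            "SELECT accession FROM annotation WHERE molecule_kind='protein'"
            " ORDER BY accession"
        ).fetchall()
        return [self.get_annotation(r[0]) for r in rows]

    def counts(self) -> dict[str, int]:
        """Row counts per entity, used by atomicity checks."""
        out = {}
        for table in ("genome", "feature", "annotation", "annotation_event"):
            out[table] = self._db.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
        return out


def open_store(path: str | Path, clock: Callable[[], str] | None = None) -> Store:
    """Open (creating if needed) the annotation store at ``path``."""
    return Store(path, clock=clock)
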