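"""Star-schema warehouse for immunological assay results.

The dimensional model has a single fact table, ``aliquot_fact`` -- one row
per experimental data point (an analyte measured on one aliquot) -- joined
to four dimension tables: ``person`` (time-invariant participant
characteristics), ``sample`` (a blood draw, carrying the study-event time
hierarchy year/month/week/day/draw -- ordinals, never calendar dates),
``analyte`` (what was measured) and ``source`` (the batch-results file the
row came from, with run metadata such as kit lot and PI/project).

Persistence is a single SQLite file so a whole warehouse is one portable
artifact; ``":memory:"`` is accepted for transient stores.
"""

from __future__ import annotations

import csv
import math
import sqlite3
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

from .errors import DuplicateLoadError, StoreError, ValidationError

SCHEMA_VERSION = "1"

QUANTIFICATIONS = ("in_range", "below_loq", "above_loq")

#: Sentinel accepted by vocabulary-controlled fields for absent metadata.
UNKNOWN = "unknown"

_AGE_BANDS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]


def age_band(age_years: int | None) -> str | None:
    """Band an enrollment age into decades: "<20", "20-29", ..., "80+".

    Returns None iff ``age_years`` is None (the two are always null
    together on a person record).
    """
    if age_years is None:
        return None
    if age_years < 0:
        raise ValidationError("age_years", "must be non-negative")
    if age_years < 20:
        return "<20"
    if age_years >= 80:
        return "80+"
    return _AGE_BANDS[(age_years - 20) // 10]


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValidationError(fieldname, msg)


@dataclass
class PersonRecord:
    """Time-invariant characteristics of a study participant.

    ``person_id_ext`` is the verbatim external identifier, unique within a
    ``project`` scope. Vocabulary fields default to the "unknown" sentinel,
    which is a real member in the cube.
    """

    person_id_ext: str
    project: str = ""
    gender: str = UNKNOWN
    ethnicity: str = UNKNOWN
    condition: str = UNKNOWN
    treatment: str = UNKNOWN
    response: str = UNKNOWN
    age_years: int | None = None

    def validate(self) -> None:
        _require(bool(self.person_id_ext), "person_id_ext", "must be non-empty")
        for f in ("gender", "ethnicity", "condition", "treatment", "response"):
            _require(bool(getattr(self, f)), f, "must be non-empty (use 'unknown')")
        if self.age_years is not None:
            _require(int(self.age_years) == self.age_years and self.age_years >= 0,
                     "age_years", "must be a non-negative integer")

    @property
    def age_band(self) -> str | None:
        return age_band(self.age_years)


@dataclass
class SampleRecord:
    """One sampling event (e.g. a blood draw) of a person.

    year/month/week/day/draw are study-event ordinals describing where in
    the study design the draw sits; they are NOT calendar dates.
    """

    sample_id_ext: str
    year: int | None = None
    month: int | None = None
    week: int | None = None
    day: int | None = None
    draw: int | None = None

    TIME_FIELDS = ("year", "month", "week", "day", "draw")

    def validate(self) -> None:
        _require(bool(self.sample_id_ext), "sample_id_ext", "must be non-empty")
        for f in self.TIME_FIELDS:
            v = getattr(self, f)
            if v is not None:
                _require(int(v) == v and v >= 0, f, "must be a non-negative integer ordinal")


@dataclass
class AnalyteRecord:
    """A measured quantity, scoped per assay family.

    Cross-assay identity (e.g. IL-6 measured by both a bead multiplex and
    an electrochemiluminescence kit) is resolved by name match at query
    time, not at storage time.
    """

    analyte_name: str
    assay_family: str

    def validate(self) -> None:
        _require(bool(self.analyte_name), "analyte_name", "must be non-empty")
        _require(bool(self.assay_family), "assay_family", "must be non-empty")


@dataclass
class SourceRecord:
    """Provenance of one batch-results file (one kit lot per file)."""

    file_name: str
    file_hash: str
    upload_date: str
    assay: str
    run_date: str = ""
    operator: str = ""
    instrument: str = ""
    lot: str = ""
    pi: str = ""
    project: str = ""

    def validate(self) -> None:
        _require(bool(self.file_name), "file_name", "must be non-empty")
        _require(bool(self.file_hash), "file_hash", "must be non-empty")
        _require(bool(self.assay), "assay", "must be non-empty")


@dataclass
class AliquotFact:
    """A single experimental data point.

    The three generic fields -- analyte (via FK), readout and units -- let
    one table hold results from bead immunoassays (units like "MFI" or
    "pg/ml"), flow phenotyping ("percent of parent population") and
    phospho-flow alike. ``quantification`` classifies the readout against
    the assay's calibrated range; ``tissue`` and ``stim`` live on the fact
    because a single sample is processed into aliquots of different tissues
    and stimulation conditions ("none" = unstimulated).
    """

    aliquot_id_ext: str
    analyte_key: int
    source_key: int
    readout: float
    units: str
    quantification: str = "in_range"
    tissue: str = UNKNOWN
    stim: str = "none"
    sample_key: int | None = None

    def validate(self) -> None:
        _require(bool(self.aliquot_id_ext), "aliquot_id_ext", "must be non-empty")
        _require(bool(self.units), "units", "must be non-empty")
        _require(math.isfinite(self.readout), "readout", "must be finite")
        _require(self.quantification in QUANTIFICATIONS, "quantification",
                 f"must be one of {QUANTIFICATIONS}")
        _require(bool(self.tissue), "tissue", "must be non-empty (use 'unknown')")
        _require(bool(self.stim), "stim", "must be non-empty (use 'none')")


@dataclass
class IntegrityReport:
    """Full-scan health counts of a store."""

    facts: int = 0
    facts_unmapped: int = 0          # facts whose sample_key is null
    samples: int = 0
    samples_unmapped: int = 0        # samples whose person_key is null
    persons: int = 0
    analytes: int = 0
    sources: int = 0
    orphan_fact_analytes: int = 0    # non-null FKs that do not resolve
    orphan_fact_sources: int = 0
    orphan_fact_samples: int = 0
    orphan_sample_persons: int = 0

    @property
    def orphans(self) -> int:
        return (self.orphan_fact_analytes + self.orphan_fact_sources
                + self.orphan_fact_samples + self.orphan_sample_persons)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)} | {
            "orphans": self.orphans
        }


_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);

CREATE TABLE IF NOT EXISTS person (
    person_key    INTEGER PRIMARY KEY AUTOINCREMENT,
    person_id_ext TEXT NOT NULL,
    project       TEXT NOT NULL DEFAULT '',
    gender        TEXT NOT NULL,
    ethnicity     TEXT NOT NULL,
    condition     TEXT NOT NULL,
    treatment     TEXT NOT NULL,
    response      TEXT NOT NULL,
    age_years     INTEGER,
    age_band      TEXT,
    UNIQUE (project, person_id_ext)
);

CREATE TABLE IF NOT EXISTS sample (
    sample_key    INTEGER PRIMARY KEY AUTOINCREMENT,
    sample_id_ext TEXT NOT NULL UNIQUE,
    person_key    INTEGER REFERENCES person(person_key),
    year INTEGER, month INTEGER, week INTEGER, day INTEGER, draw INTEGER
);

CREATE TABLE IF NOT EXISTS analyte (
    analyte_key  INTEGER PRIMARY KEY AUTOINCREMENT,
    analyte_name TEXT NOT NULL,
    assay_family TEXT NOT NULL,
    UNIQUE (analyte_name, assay_family)
);

CREATE TABLE IF NOT EXISTS source (
    source_key  INTEGER PRIMARY KEY AUTOINCREMENT,
    file_name   TEXT NOT NULL,
    file_hash   TEXT NOT NULL,
    upload_date TEXT NOT NULL,
    assay       TEXT NOT NULL,
    run_date    TEXT NOT NULL DEFAULT '',
    operator    TEXT NOT NULL DEFAULT '',
    instrument  TEXT NOT NULL DEFAULT '',
    lot         TEXT NOT NULL DEFAULT '',
    pi          TEXT NOT NULL DEFAULT '',
    project     TEXT NOT NULL DEFAULT '',
    UNIQUE (file_name, file_hash)
);

CREATE TABLE IF NOT EXISTS aliquot_fact (
    fact_key       INTEGER PRIMARY KEY AUTOINCREMENT,
    aliquot_id_ext TEXT NOT NULL,
    analyte_key    INTEGER NOT NULL REFERENCES analyte(analyte_key),
    sample_key     INTEGER REFERENCES sample(sample_key),
    source_key     INTEGER NOT NULL REFERENCES source(source_key),
    tissue         TEXT NOT NULL,
    stim           TEXT NOT NULL,
    readout        REAL NOT NULL,
    units          TEXT NOT NULL,
    quantification TEXT NOT NULL
        CHECK (quantification IN ('in_range', 'below_loq', 'above_loq')),
    UNIQUE (aliquot_id_ext, analyte_key, source_key, stim)
);
CREATE INDEX IF NOT EXISTS idx_fact_sample ON aliquot_fact(sample_key);
CREATE INDEX IF NOT EXISTS idx_fact_aliquot ON aliquot_fact(aliquot_id_ext);

CREATE TABLE IF NOT EXISTS vocabulary (
    attribute TEXT NOT NULL,
    scope     TEXT NOT NULL,
    PRIMARY KEY (attribute, scope)
);
CREATE TABLE IF NOT EXISTS vocab_value (
    attribute TEXT NOT NULL,
    scope     TEXT NOT NULL,
    value     TEXT NOT NULL,
    PRIMARY KEY (attribute, scope, value)
);
CREATE TABLE IF NOT EXISTS vocab_map (
    attribute TEXT NOT NULL,
    scope     TEXT NOT NULL,
    incoming  TEXT NOT NULL,
    valid     TEXT NOT NULL,
    PRIMARY KEY (attribute, scope, incoming)
);

CREATE TABLE IF NOT EXISTS audit (
    audit_id INTEGER PRIMARY KEY AUTOINCREMENT,
    stamp    TEXT NOT NULL,
    action   TEXT NOT NULL,
    payload  TEXT NOT NULL
);
"""

#: Fixed CSV export column order, per table.
TABLE_COLUMNS = {
    "person": ["person_key", "person_id_ext", "project", "gender", "ethnicity",
               "condition", "treatment", "response", "age_years", "age_band"],
    "sample": ["sample_key", "sample_id_ext", "person_key",
               "year", "month", "week", "day", "draw"],
    "analyte": ["analyte_key", "analyte_name", "assay_family"],
    "source": ["source_key", "file_name", "file_hash", "upload_date", "assay",
               "run_date", "operator", "instrument", "lot", "pi", "project"],
    "aliquot_fact": ["fact_key", "aliquot_id_ext", "analyte_key", "sample_key",
                     "source_key", "tissue", "stim", "readout", "units",
                     "quantification"],
}


class Store:
    """Handle on an open warehouse.

    All mutating methods bump ``mutation_count`` so higher layers (the OLAP
    engine) can cache derived frames safely.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        try:
            self.conn = sqlite3.connect(self.path)
            self.conn.execute("PRAGMA foreign_keys = ON")
            self.conn.executescript(_SCHEMA)
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"cannot open store at {self.path!r}: {exc}") from exc
        cur = self.conn.execute("SELECT value FROM meta WHERE key='schema_version'")
        row = cur.fetchone()
        if row is None:
            self.conn.execute(
                "INSERT INTO meta(key, value) VALUES ('schema_version', ?)",
                (SCHEMA_VERSION,))
            self.conn.commit()
        elif row[0] != SCHEMA_VERSION:
            raise StoreError(
                f"store schema version {row[0]!r} != supported {SCHEMA_VERSION!r}")
        self.mutation_count = 0

    # -- low-level helpers -------------------------------------------------

    def _touch(self) -> None:
        self.mutation_count += 1

    def execute(self, sql: str, params=()):
        return self.conn.execute(sql, params)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def count(self, table: str) -> int:
        if table not in TABLE_COLUMNS:
            raise StoreError(f"unknown table {table!r}")
        return self.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    # -- dimension upserts -------------------------------------------------

    def upsert_person(self, rec: PersonRecord) -> int:
        rec.validate()
        row = self.conn.execute(
            "SELECT person_key, gender, ethnicity, condition, treatment,"
            " response, age_years FROM person WHERE project=? AND person_id_ext=?",
            (rec.project, rec.person_id_ext)).fetchone()
        if row is not None:
            # merge: an incoming 'unknown'/None never clobbers known metadata
            key, g, e, c, t, r, a = row
            merged = [
                rec.gender if rec.gender != UNKNOWN else g,
                rec.ethnicity if rec.ethnicity != UNKNOWN else e,
                rec.condition if rec.condition != UNKNOWN else c,
                rec.treatment if rec.treatment != UNKNOWN else t,
                rec.response if rec.response != UNKNOWN else r,
                rec.age_years if rec.age_years is not None else a,
            ]
            merged.append(age_band(merged[-1]))
            self.conn.execute(
                "UPDATE person SET gender=?, ethnicity=?, condition=?, treatment=?,"
                " response=?, age_years=?, age_band=? WHERE person_key=?",
                (*merged, key))
            self._touch()
            return key
        cur = self.conn.execute(
            "INSERT INTO person (person_id_ext, project, gender, ethnicity,"
            " condition, treatment, response, age_years, age_band)"
            " VALUES (?,?,?,?,?,?,?,?,?)",
            (rec.person_id_ext, rec.project, rec.gender, rec.ethnicity,
             rec.condition, rec.treatment, rec.response, rec.age_years,
             rec.age_band))
        self._touch()
        return cur.lastrowid

    def upsert_sample(self, rec: SampleRecord, person_key: int | None = None) -> int:
        rec.validate()
        row = self.conn.execute(
            "SELECT sample_key, year, month, week, day, draw FROM sample"
            " WHERE sample_id_ext=?", (rec.sample_id_ext,)).fetchone()
        tvals = tuple(getattr(rec, f) for f in SampleRecord.TIME_FIELDS)
        if row is not None:
            key, *existing = row
            merged = tuple(v if v is not None else old
                           for v, old in zip(tvals, existing))
            sets = "year=?, month=?, week=?, day=?, draw=?"
            params: tuple = merged
            if person_key is not None:
                sets += ", person_key=?"
                params = merged + (person_key,)
            self.conn.execute(
                f"UPDATE sample SET {sets} WHERE sample_key=?", params + (key,))
            self._touch()
            return key
        cur = self.conn.execute(
            "INSERT INTO sample (sample_id_ext, person_key, year, month, week,"
            " day, draw) VALUES (?,?,?,?,?,?,?)",
            (rec.sample_id_ext, person_key) + tvals)
        self._touch()
        return cur.lastrowid

    def upsert_analyte(self, rec: AnalyteRecord) -> int:
        rec.validate()
        row = self.conn.execute(
            "SELECT analyte_key FROM analyte WHERE analyte_name=? AND assay_family=?",
            (rec.analyte_name, rec.assay_family)).fetchone()
        if row is not None:
            return row[0]
        cur = self.conn.execute(
            "INSERT INTO analyte (analyte_name, assay_family) VALUES (?,?)",
            (rec.analyte_name, rec.assay_family))
        self._touch()
        return cur.lastrowid

    def find_source(self, file_name: str, file_hash: str):
        """Return (source_key, upload_date) of a prior identical upload, or None."""
        return self.conn.execute(
            "SELECT source_key, upload_date FROM source"
            " WHERE file_name=? AND file_hash=?",
            (file_name, file_hash)).fetchone()

    def insert_source(self, rec: SourceRecord) -> int:
        """Register a new source document; duplicate (file_name, hash) is rejected."""
        rec.validate()
        prior = self.find_source(rec.file_name, rec.file_hash)
        if prior is not None:
            raise DuplicateLoadError(
                f"file {rec.file_name!r} with identical content was already "
                f"loaded on {prior[1]} (source_key={prior[0]})")
        cur = self.conn.execute(
            "INSERT INTO source (file_name, file_hash, upload_date, assay,"
            " run_date, operator, instrument, lot, pi, project)"
            " VALUES (?,?,?,?,?,?,?,?,?,?)",
            (rec.file_name, rec.file_hash, rec.upload_date, rec.assay,
             rec.run_date, rec.operator, rec.instrument, rec.lot, rec.pi,
             rec.project))
        self._touch()
        return cur.lastrowid

    def upsert_dimension(self, table: str, rec) -> int:
        """Generic dispatch used by the CLI; returns the surrogate key."""
        dispatch = {"person": self.upsert_person, "sample": self.upsert_sample,
                    "analyte": self.upsert_analyte, "source": self.insert_source}
        if table not in dispatch:
            raise StoreError(f"unknown dimension table {table!r}")
        return dispatch[table](rec)

    # -- facts -------------------------------------------------------------

    def insert_facts(self, facts: list[AliquotFact]) -> int:
        """Bulk-insert validated facts in one transaction. Returns the count."""
        rows = []
        for f in facts:
            f.validate()
            rows.append((f.aliquot_id_ext, f.analyte_key, f.sample_key,
                         f.source_key, f.tissue, f.stim, f.readout, f.units,
                         f.quantification))
        with self.conn:
            self.conn.executemany(
                "INSERT INTO aliquot_fact (aliquot_id_ext, analyte_key,"
                " sample_key, source_key, tissue, stim, readout, units,"
                " quantification) VALUES (?,?,?,?,?,?,?,?,?)", rows)
        self._touch()
        return len(rows)

    # -- reporting / export ------------------------------------------------

    def integrity_report(self) -> IntegrityReport:
        q = self.conn.execute
        rep = IntegrityReport(
            facts=q("SELECT COUNT(*) FROM aliquot_fact").fetchone()[0],
            facts_unmapped=q("SELECT COUNT(*) FROM aliquot_fact"
                             " WHERE sample_key IS NULL").fetchone()[0],
            samples=q("SELECT COUNT(*) FROM sample").fetchone()[0],
            samples_unmapped=q("SELECT COUNT(*) FROM sample"
                               " WHERE person_key IS NULL").fetchone()[0],
            persons=q("SELECT COUNT(*) FROM person").fetchone()[0],
            analytes=q("SELECT COUNT(*) FROM analyte").fetchone()[0],
            sources=q("SELECT COUNT(*) FROM source").fetchone()[0],
            orphan_fact_analytes=q(
                "SELECT COUNT(*) FROM aliquot_fact f LEFT JOIN analyte a"
                " USING (analyte_key) WHERE a.analyte_key IS NULL").fetchone()[0],
            orphan_fact_sources=q(
                "SELECT COUNT(*) FROM aliquot_fact f LEFT JOIN source s"
                " USING (source_key) WHERE s.source_key IS NULL").fetchone()[0],
            orphan_fact_samples=q(
                "SELECT COUNT(*) FROM aliquot_fact f LEFT JOIN sample s"
                " USING (sample_key) WHERE f.sample_key IS NOT NULL"
                " AND s.sample_key IS NULL").fetchone()[0],
            orphan_sample_persons=q(
                "SELECT COUNT(*) FROM sample s LEFT JOIN person p"
                " USING (person_key) WHERE s.person_key IS NOT NULL"
                " AND p.person_key IS NULL").fetchone()[0],
        )
        return rep

    def export_table(self, table: str, path: str | Path) -> None:
        """Write a dimension or fact table to CSV in a fixed column order."""
        if table not in TABLE_COLUMNS:
            raise StoreError(f"unknown table {table!r}")
        cols = TABLE_COLUMNS[table]
        rows = self.conn.execute(
            f"SELECT {', '.join(cols)} FROM {table} ORDER BY {cols[0]}").fetchall()
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            w.writerows(rows)

    def audit(self, action: str, payload: str, stamp: str = "") -> None:
        self.conn.execute(
            "INSERT INTO audit (stamp, action, payload) VALUES (?,?,?)",
            (stamp, action, payload))
        self.conn.commit()


def create_store(path: str | Path) -> Store:
    """Create (or re-open) a warehouse at ``path``.

    Creating on a fresh path yields an empty schema; re-opening preserves
    contents; a file that is not a warehouse raises :class:`StoreError`.
    """
    return Store(path)
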