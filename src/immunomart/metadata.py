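"""Flexible-format metadata upload with controlled-vocabulary harmonization.

Metadata sheets carry clinical/demographic data with records in rows and
attributes in columns -- the only layout constraint. The user (or a JSON
directive file) maps sheet columns to warehouse attributes, and maps
incoming terminology onto controlled vocabularies of valid values, so that
"M"/"F" on one sheet and "male"/"female" on another land as the same stored
terms. Condition, ethnicity and gender vocabularies are global; response,
treatment and time-point labels are project-scoped.

Metadata may be loaded before or after batch results; no ordering is
assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError, VocabularyError
from .warehouse import PersonRecord, SampleRecord, Store, UNKNOWN

PERSON_ATTRS = ("gender", "ethnicity", "condition", "treatment", "response",
                "age_years")
SAMPLE_ATTRS = ("year", "month", "week", "day", "draw")
ID_ATTRS = ("person_id", "sample_id")
ALL_ATTRS = ID_ATTRS + PERSON_ATTRS + SAMPLE_ATTRS

#: Vocabulary-controlled attributes and their scoping rule.
GLOBAL_VOCAB_ATTRS = ("condition", "ethnicity", "gender")
PROJECT_VOCAB_ATTRS = ("response", "treatment", "timepoint")
VOCAB_ATTRS = GLOBAL_VOCAB_ATTRS + PROJECT_VOCAB_ATTRS

#: Editable seed vocabularies; defaults, not a replication of any site's lists.
DEFAULT_VOCABULARIES = {
    "gender": {"male", "female", UNKNOWN},
    "ethnicity": {"asian", "black", "hispanic", "native american",
                  "pacific islander", "white", "other", UNKNOWN},
    "condition": {"healthy", "lupus", "rheumatoid arthritis", "diabetes",
                  "pregnant", UNKNOWN},
}


@dataclass
class ControlledVocabulary:
    """A valid-value set plus accumulated incoming-value mappings."""

    attribute: str
    valid_values: set[str]
    value_map: dict[str, str] = field(default_factory=dict)
    scope: str = "global"

    def validate(self) -> None:
        if self.attribute not in VOCAB_ATTRS:
            raise ValidationError("attribute",
                                  f"{self.attribute!r} is not vocabulary-controlled")
        expect_global = self.attribute in GLOBAL_VOCAB_ATTRS
        if expect_global != (self.scope == "global"):
            raise ValidationError(
                "scope", f"{self.attribute!r} must be"
                f" {'global' if expect_global else 'project'}-scoped")
        bad = {v for v in self.value_map.values() if v not in self.valid_values}
        if bad:
            raise ValidationError("value_map",
                                  f"targets {sorted(bad)} not in valid_values")

    def resolve(self, incoming: str) -> str | None:
        """Resolve one incoming value, or None if it is unresolved."""
        s = incoming.strip()
        if s in self.value_map:
            return self.value_map[s]
        folded = s.casefold()
        for v in self.valid_values:
            if folded == v.casefold():
                return v
        return None


@dataclass
class ValueMapProposal:
    """Outcome of auto-matching incoming values against a vocabulary."""

    auto: dict[str, str]
    unresolved: set[str]


@dataclass
class ColumnMapping:
    """Sheet-column -> warehouse-attribute assignments.

    Person attributes are only active when a person-ID column is mapped,
    and sample attributes (the time-point ordinals) only when a sample-ID
    column is mapped.
    """

    entries: dict[str, str]  # column name -> attribute

    def validate(self) -> None:
        attrs = list(self.entries.values())
        for a in attrs:
            if a not in ALL_ATTRS:
                raise ValidationError("entries", f"unknown attribute {a!r}")
        for a in set(attrs):
            if attrs.count(a) > 1:
                raise ValidationError("entries",
                                      f"attribute {a!r} mapped from two columns")
        has_pid = "person_id" in attrs
        has_sid = "sample_id" in attrs
        if not (has_pid or has_sid):
            raise ValidationError(
                "entries", "at least one of person_id/sample_id must be mapped")
        if not has_pid and any(a in PERSON_ATTRS for a in attrs):
            raise ValidationError(
                "entries", "person attributes require a person_id column")
        if not has_sid and any(a in SAMPLE_ATTRS for a in attrs):
            raise ValidationError(
                "entries", "sample attributes require a sample_id column")

    def column_for(self, attribute: str) -> str | None:
        for col, attr in self.entries.items():
            if attr == attribute:
                return col
        return None


@dataclass
class MetadataLoadSummary:
    persons_created: int = 0
    persons_updated: int = 0
    samples_created: int = 0
    samples_updated: int = 0
    rows_read: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def read_metadata_sheet(path: str | Path) -> pd.DataFrame:
    """Read a metadata sheet (CSV or XLSX) as trimmed strings.

    The first row is the header; fully-empty rows are dropped; duplicate
    header names raise :class:`FormatError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        header = [("" if c is None else str(c).strip())
                  for c in next(wb.worksheets[0].iter_rows(values_only=True))]
        wb.close()
        df = pd.read_excel(path, dtype=str, engine="openpyxl")
    else:
        import csv as _csv

        with open(path, newline="", encoding="utf-8-sig") as fh:
            header = [c.strip() for c in next(_csv.reader(fh))]
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         encoding="utf-8-sig")
    dup = [c for c in header if header.count(c) > 1]
    if dup:
        raise FormatError(f"duplicate header names {sorted(set(dup))}", row=1)
    df.columns = [str(c).strip() for c in df.columns]
    df = df.fillna("").map(lambda s: str(s).strip())
    df = df[~(df == "").all(axis=1)].reset_index(drop=True)
    return df


# -- vocabulary persistence -----------------------------------------------

def _scope_str(attribute: str, project: str) -> str:
    return "global" if attribute in GLOBAL_VOCAB_ATTRS else f"project:{project}"


def register_vocabulary(store: Store, vocab: ControlledVocabulary) -> None:
    """Persist (or extend) a vocabulary and its value map in the store."""
    vocab.validate()
    with store.conn:
        store.execute(
            "INSERT OR IGNORE INTO vocabulary (attribute, scope) VALUES (?,?)",
            (vocab.attribute, vocab.scope))
        for v in sorted(vocab.valid_values):
            store.execute(
                "INSERT OR IGNORE INTO vocab_value (attribute, scope, value)"
                " VALUES (?,?,?)", (vocab.attribute, vocab.scope, v))
        for k, v in sorted(vocab.value_map.items()):
            store.execute(
                "INSERT OR REPLACE INTO vocab_map (attribute, scope, incoming,"
                " valid) VALUES (?,?,?,?)", (vocab.attribute, vocab.scope, k, v))
    store._touch()


def seed_default_vocabularies(store: Store) -> None:
    """Install the editable global seed vocabularies (gender, ethnicity,
    condition)."""
    for attr, values in DEFAULT_VOCABULARIES.items():
        register_vocabulary(store, ControlledVocabulary(attr, set(values)))


def get_vocabulary(store: Store, attribute: str,
                   project: str = "") -> ControlledVocabulary | None:
    scope = _scope_str(attribute, project)
    values = {r[0] for r in store.execute(
        "SELECT value FROM vocab_value WHERE attribute=? AND scope=?",
        (attribute, scope))}
    if not values:
        return None
    vmap = {r[0]: r[1] for r in store.execute(
        "SELECT incoming, valid FROM vocab_map WHERE attribute=? AND scope=?",
        (attribute, scope))}
    return ControlledVocabulary(attribute, values, vmap, scope)


def export_vocabularies(store: Store) -> dict:
    """All vocabularies as a JSON-ready dict."""
    out: dict = {}
    for attr, scope in store.execute(
            "SELECT attribute, scope FROM vocabulary ORDER BY attribute, scope"):
        values = sorted(r[0] for r in store.execute(
            "SELECT value FROM vocab_value WHERE attribute=? AND scope=?",
            (attr, scope)))
        vmap = {r[0]: r[1] for r in store.execute(
            "SELECT incoming, valid FROM vocab_map WHERE attribute=? AND"
            " scope=? ORDER BY incoming", (attr, scope))}
        out.setdefault(attr, {})[scope] = {"valid_values": values,
                                           "value_map": vmap}
    return out


def propose_value_mapping(raw_values: set[str],
                          vocab: ControlledVocabulary) -> ValueMapProposal:
    """Auto-map incoming values that case-fold-equal a valid value.

    Matching is case-folded and whitespace-trimmed only -- never fuzzy; all
    other values are left for explicit assignment.
    """
    auto: dict[str, str] = {}
    unresolved: set[str] = set()
    for raw in raw_values:
        target = vocab.resolve(raw)
        if target is None:
            unresolved.add(raw)
        else:
            auto[raw] = target
    return ValueMapProposal(auto=auto, unresolved=unresolved)


def _parse_ordinal(text: str, attr: str, row: int) -> int | None:
    s = text.strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        raise FormatError(f"non-integer value {text!r} in time-point column"
                          f" {attr!r}", row=row) from None
    if v != int(v) or v < 0:
        raise FormatError(f"time-point column {attr!r} requires a"
                          f" non-negative integer, got {text!r}", row=row)
    return int(v)


def load_metadata(store: Store, raw: pd.DataFrame, colmap: ColumnMapping,
                  value_maps: dict[str, dict[str, str]] | None = None,
                  project: str = "") -> MetadataLoadSummary:
    """Upsert persons/samples from a metadata sheet under a column mapping.

    ``value_maps`` supplies explicit incoming->valid assignments per
    vocabulary attribute (the scriptable stand-in for interactive
    drag-and-drop); they are merged with the store's persisted maps and the
    case-fold auto-match. Any vocabulary value left unresolved rejects the
    whole load, listing the offending values -- no silent coercion.
    """
    colmap.validate()
    value_maps = value_maps or {}
    summary = MetadataLoadSummary(rows_read=len(raw))

    for col in colmap.entries:
        if col not in raw.columns:
            raise FormatError(f"mapped column {col!r} not present in sheet")

    # resolve vocabulary columns up front; reject on any unresolved value
    resolved: dict[str, dict[str, str]] = {}
    for col, attr in colmap.entries.items():
        if attr not in VOCAB_ATTRS:
            continue
        vocab = get_vocabulary(store, attr, project)
        if vocab is None:
            raise VocabularyError(
                f"no vocabulary registered for attribute {attr!r}"
                f" (scope {_scope_str(attr, project)!r})")
        merged = ControlledVocabulary(
            attr, set(vocab.valid_values),
            {**vocab.value_map, **value_maps.get(attr, {})}, vocab.scope)
        merged.validate()
        incoming = {v for v in raw[col] if v != ""}
        proposal = propose_value_mapping(incoming, merged)
        if proposal.unresolved:
            raise VocabularyError(
                f"unresolved values for attribute {attr!r}:"
                f" {sorted(proposal.unresolved)}")
        resolved[col] = proposal.auto
        register_vocabulary(store, merged)  # persist accepted mappings

    pid_col = colmap.column_for("person_id")
    sid_col = colmap.column_for("sample_id")

    def vocab_value(row, attr: str) -> str:
        col = colmap.column_for(attr)
        if col is None:
            return UNKNOWN
        v = row[col]
        if v == "":
            return UNKNOWN
        return resolved[col][v] if col in resolved else v

    for i, row in raw.iterrows():
        rowno = i + 2  # 1-based, after header
        person_key = None
        if pid_col is not None:
            pid = row[pid_col]
            if not pid:
                raise FormatError("blank person ID", row=rowno)
            age_col = colmap.column_for("age_years")
            age = None
            if age_col is not None and row[age_col] != "":
                age = _parse_ordinal(row[age_col], "age_years", rowno)
            before = store.execute(
                "SELECT * FROM person WHERE project=? AND person_id_ext=?",
                (project, pid)).fetchone()
            person_key = store.upsert_person(PersonRecord(
                person_id_ext=pid, project=project,
                gender=vocab_value(row, "gender"),
                ethnicity=vocab_value(row, "ethnicity"),
                condition=vocab_value(row, "condition"),
                treatment=vocab_value(row, "treatment"),
                response=vocab_value(row, "response"),
                age_years=age))
            after = store.execute(
                "SELECT * FROM person WHERE person_key=?",
                (person_key,)).fetchone()
            if before is None:
                summary.persons_created += 1
            elif before != after:
                summary.persons_updated += 1
        if sid_col is not None:
            sid = row[sid_col]
            if not sid:
                raise FormatError("blank sample ID", row=rowno)
            ordinals = {}
            for attr in SAMPLE_ATTRS:
                col = colmap.column_for(attr)
                ordinals[attr] = (_parse_ordinal(row[col], attr, rowno)
                                  if col is not None else None)
            before = store.execute(
                "SELECT * FROM sample WHERE sample_id_ext=?", (sid,)).fetchone()
            skey = store.upsert_sample(SampleRecord(sample_id_ext=sid,
                                                    **ordinals),
                                       person_key=person_key)
            after = store.execute(
                "SELECT * FROM sample WHERE sample_key=?", (skey,)).fetchone()
            if before is None:
                summary.samples_created += 1
            elif before != after:
                summary.samples_updated += 1

    store.audit("load_metadata", summary.to_json())
    return summary
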