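"""Identifier reconciliation: aliquot->sample and sample->person mapping.

Lab software decorates aliquot IDs with prefixes/suffixes, so batch-result
IDs rarely equal the sample IDs on metadata sheets verbatim. A
:class:`LinkSession` holds both ID lists as *working strings* derived from
the verbatim external IDs by an ordered, recorded list of phrase-removal
transforms; once the strings are made equal, ``map_equals`` proposes every
unambiguous 1:1 match at once, single pairs can be proposed explicitly, and
``commit`` atomically writes the foreign keys and an audit record.

Matching is exact string equality after the explicit transforms -- never
fuzzy, and case-sensitive unless a case-fold transform is applied;
ambiguity (one working string on the parent side occurring twice, or a
child matching two parents) is surfaced, never auto-resolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import LinkageError
from .warehouse import Store

LEVELS = ("aliquot_sample", "sample_person")


@dataclass
class CommitSummary:
    pairs_committed: int = 0
    children_unmapped: int = 0  # children left without a proposal

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class LinkSession:
    """A reviewable, replayable ID-mapping session.

    ``children``/``parents`` map an entity key to ``[external_id,
    working_string]``; child keys are aliquot-ID strings at the
    aliquot->sample level and sample surrogate keys at sample->person.
    """

    level: str
    children: dict = field(default_factory=dict)
    parents: dict = field(default_factory=dict)
    transforms: list = field(default_factory=list)   # [side, kind, phrase]
    proposed: dict = field(default_factory=dict)     # child_key -> parent_key
    ambiguous: dict = field(default_factory=dict)    # child_key -> [parent keys]
    source_filter: dict | None = None

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "level": self.level,
            "children": {str(k): v for k, v in self.children.items()},
            "parents": {str(k): v for k, v in self.parents.items()},
            "transforms": self.transforms,
            "proposed": {str(k): v for k, v in self.proposed.items()},
            "ambiguous": {str(k): v for k, v in self.ambiguous.items()},
            "source_filter": self.source_filter,
        }, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LinkSession":
        d = json.loads(text)

        def keyfix(m):
            # sample->person child keys and all parent keys are integers
            return {int(k) if k.lstrip("-").isdigit() else k: v
                    for k, v in m.items()}

        return cls(level=d["level"], children=keyfix(d["children"]),
                   parents=keyfix(d["parents"]), transforms=d["transforms"],
                   proposed=keyfix(d["proposed"]),
                   ambiguous=keyfix(d["ambiguous"]),
                   source_filter=d.get("source_filter"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LinkSession":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _source_keys_for(store: Store, source_filter: dict | None) -> list[int] | None:
    """Resolve a source predicate ({column: value} on the source table)."""
    if not source_filter:
        return None
    allowed = {"file_name", "assay", "lot", "pi", "project", "operator",
               "instrument", "source_key"}
    clauses, params = [], []
    for col, val in source_filter.items():
        if col not in allowed:
            raise LinkageError(f"unknown source filter column {col!r}")
        clauses.append(f"{col}=?")
        params.append(val)
    rows = store.execute(
        f"SELECT source_key FROM source WHERE {' AND '.join(clauses)}",
        tuple(params)).fetchall()
    return [r[0] for r in rows]


def open_session(store: Store, level: str,
                 source_filter: dict | None = None) -> LinkSession:
    """Start a mapping session over the currently-unmapped children.

    At the aliquot->sample level the child side holds the distinct aliquot
    IDs of facts with a null sample FK (optionally filtered by source
    document) and the parent side all samples; at sample->person, samples
    with a null person FK versus all persons.
    """
    if level not in LEVELS:
        raise LinkageError(f"unknown level {level!r}; expected one of {LEVELS}")
    sess = LinkSession(level=level, source_filter=source_filter)
    if level == "aliquot_sample":
        keys = _source_keys_for(store, source_filter)
        where = "sample_key IS NULL"
        params: tuple = ()
        if keys is not None:
            if not keys:
                return sess  # empty under filter: valid, empty session
            where += f" AND source_key IN ({','.join('?' * len(keys))})"
            params = tuple(keys)
        for (aid,) in store.execute(
                f"SELECT DISTINCT aliquot_id_ext FROM aliquot_fact WHERE"
                f" {where} ORDER BY aliquot_id_ext", params):
            sess.children[aid] = [aid, aid]
        for skey, sid in store.execute(
                "SELECT sample_key, sample_id_ext FROM sample"
                " ORDER BY sample_key"):
            sess.parents[skey] = [sid, sid]
    else:
        for skey, sid in store.execute(
                "SELECT sample_key, sample_id_ext FROM sample"
                " WHERE person_key IS NULL ORDER BY sample_key"):
            sess.children[skey] = [sid, sid]
        for pkey, pid in store.execute(
                "SELECT person_key, person_id_ext FROM person"
                " ORDER BY person_key"):
            sess.parents[pkey] = [pid, pid]
    return sess


def _side(session: LinkSession, side: str) -> dict:
    if side not in ("child", "parent"):
        raise LinkageError(f"side must be 'child' or 'parent', got {side!r}")
    return session.children if side == "child" else session.parents


def strip_phrase(session: LinkSession, side: str, phrase: str) -> LinkSession:
    """Remove every occurrence of ``phrase`` from one side's working strings.

    External IDs are untouched; the transform is recorded so working
    strings are replayable from the verbatim IDs.
    """
    if not phrase:
        raise LinkageError("phrase must be non-empty")
    entries = _side(session, side)
    for key, (ext, working) in entries.items():
        entries[key] = [ext, working.replace(phrase, "")]
    session.transforms.append([side, "strip", phrase])
    return session


def casefold_side(session: LinkSession, side: str) -> LinkSession:
    """Optional case-fold transform (matching is case-sensitive by default)."""
    entries = _side(session, side)
    for key, (ext, working) in entries.items():
        entries[key] = [ext, working.casefold()]
    session.transforms.append([side, "casefold", ""])
    return session


def replay_transforms(external_id: str, transforms: list, side: str) -> str:
    """Re-derive a working string from a verbatim ID and the recorded
    transform list (the determinism oracle for session replayability)."""
    s = external_id
    for t_side, kind, phrase in transforms:
        if t_side != side:
            continue
        if kind == "strip":
            s = s.replace(phrase, "")
        elif kind == "casefold":
            s = s.casefold()
        else:
            raise LinkageError(f"unknown transform kind {kind!r}")
    return s


def map_equals(session: LinkSession) -> LinkSession:
    """Propose a pair for every child whose working string matches exactly
    one parent working string; zero- or multi-match children are left
    unproposed (multi-matches recorded as ambiguous)."""
    by_working: dict[str, list] = {}
    for pkey, (_, working) in session.parents.items():
        by_working.setdefault(working, []).append(pkey)
    session.ambiguous = {}
    for ckey, (_, working) in session.children.items():
        if ckey in session.proposed:
            continue
        matches = by_working.get(working, [])
        if len(matches) == 1:
            session.proposed[ckey] = matches[0]
        elif len(matches) > 1:
            session.ambiguous[ckey] = sorted(matches)
    return session


def map_pair(session: LinkSession, child_key, parent_key,
             override: bool = False) -> LinkSession:
    """Propose one explicit pair (the drag-and-drop equivalent).

    Re-mapping an already-proposed child requires ``override=True``.
    """
    if child_key not in session.children:
        raise LinkageError(f"unknown child key {child_key!r}")
    if parent_key not in session.parents:
        raise LinkageError(f"unknown parent key {parent_key!r}")
    if child_key in session.proposed and not override:
        raise LinkageError(
            f"child {child_key!r} already proposed -> "
            f"{session.proposed[child_key]!r}; pass override=True to replace")
    session.proposed[child_key] = parent_key
    session.ambiguous.pop(child_key, None)
    return session


def commit(session: LinkSession, store: Store) -> CommitSummary:
    """Atomically write the proposed foreign keys into the store.

    All pairs commit or none do: if any child was mapped concurrently since
    the session opened, the whole commit aborts and the store is unchanged.
    An audit record captures the transforms and pairs.
    """
    if not session.proposed:
        raise LinkageError("nothing to commit: no proposed pairs")
    summary = CommitSummary(
        pairs_committed=len(session.proposed),
        children_unmapped=len(session.children) - len(session.proposed))
    conn = store.conn
    conn.commit()  # close any implicit transaction before our explicit one
    try:
        conn.execute("BEGIN")
        if session.level == "aliquot_sample":
            keys = _source_keys_for(store, session.source_filter)
            extra, extra_params = "", ()
            if keys is not None:
                extra = f" AND source_key IN ({','.join('?' * len(keys))})"
                extra_params = tuple(keys)
            for aid, skey in session.proposed.items():
                conflict = conn.execute(
                    f"SELECT COUNT(*) FROM aliquot_fact WHERE aliquot_id_ext=?"
                    f" AND sample_key IS NOT NULL{extra}",
                    (aid,) + extra_params).fetchone()[0]
                if conflict:
                    raise LinkageError(
                        f"aliquot {aid!r} was mapped concurrently; aborting")
                conn.execute(
                    f"UPDATE aliquot_fact SET sample_key=? WHERE"
                    f" aliquot_id_ext=? AND sample_key IS NULL{extra}",
                    (skey, aid) + extra_params)
        else:
            for skey, pkey in session.proposed.items():
                conflict = conn.execute(
                    "SELECT person_key FROM sample WHERE sample_key=?",
                    (skey,)).fetchone()
                if conflict is None or conflict[0] is not None:
                    raise LinkageError(
                        f"sample {skey!r} missing or mapped concurrently;"
                        " aborting")
                conn.execute(
                    "UPDATE sample SET person_key=? WHERE sample_key=?",
                    (pkey, skey))
        conn.execute(
            "INSERT INTO audit (stamp, action, payload) VALUES ('', ?, ?)",
            (f"link_commit:{session.level}", session.to_json()))
        conn.commit()
    except Exception:
        conn.rollback()
        raise
    store._touch()
    return summary
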