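"""ROLAP cube over the star schema.

The cube is computed logically over the relational store (no special
storage format): a query names dimension levels for the row and column
axes, member filters, and measures; the engine denormalizes the fact table
once, groups, and returns a pivot grid with roll-up subtotal members
("(all)") plus back-links for drill-through to the underlying rows.

Dimension levels
----------------
* Assay -> Analyte -> Units (assay hierarchy)
* Year -> Month -> Week -> Day -> Draw (study-event time hierarchy)
* Gender | AgeBand | Ethnicity | Condition | Treatment | Response
  (person attributes, flat)
* PI -> Project -> Lot -> Document (source hierarchy)
* Tissue, Stim, Quantification (fact attributes, flat)

Facts not yet linked to a sample (or samples not linked to a person)
appear under an ``"(unmapped)"`` member of person/time levels rather than
being dropped, so integrity gaps stay visible. Null time ordinals and
blank source fields roll into ``"(unspecified)"``.

Units safety: a cell never pools facts carrying different units strings
(e.g. "MFI" with "pg/ml"). Units acts as an implicit finest row grouping
when not explicitly placed on an axis, and the Units level is never rolled
up into an "(all)" subtotal.

Measures: N, mean, median, min, max, plus sd (sample, n-1) and cv (sd/mean)
as extensions beyond the original measure set.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import QueryError
from .warehouse import Store

UNMAPPED = "(unmapped)"
UNSPECIFIED = "(unspecified)"
ALL = "(all)"

MEASURES = ("n", "mean", "median", "min", "max", "sd", "cv")
EXTENSION_MEASURES = ("sd", "cv")

HIERARCHIES = (
    ("Assay", "Analyte", "Units"),
    ("Year", "Month", "Week", "Day", "Draw"),
    ("PI", "Project", "Lot", "Document"),
)

PERSON_LEVELS = ("Gender", "AgeBand", "Ethnicity", "Condition", "Treatment",
                 "Response")
FACT_LEVELS = ("Tissue", "Stim", "Quantification")
TIME_LEVELS = ("Year", "Month", "Week", "Day", "Draw")

LEVELS: tuple[str, ...] = (
    "Assay", "Analyte", "Units", *TIME_LEVELS, *PERSON_LEVELS,
    "PI", "Project", "Lot", "Document", *FACT_LEVELS)

#: Detail columns returned by drill-through (Table-S1 style).
DETAIL_COLUMNS = [
    "fact_key", "person_id_ext", "sample_id_ext", "aliquot_id_ext",
    "Year", "Month", "Week", "Day", "Draw", "Gender", "AgeBand",
    "Assay", "Analyte", "Tissue", "Stim", "readout", "Units",
    "Quantification", "Lot", "PI", "Project", "Document",
]


def child_level(level: str) -> str | None:
    """The next-finer level in ``level``'s hierarchy, or None at a leaf."""
    for h in HIERARCHIES:
        if level in h:
            i = h.index(level)
            return h[i + 1] if i + 1 < len(h) else None
    return None


# -- denormalized frame ----------------------------------------------------

_FRAME_SQL = """
SELECT f.fact_key, f.aliquot_id_ext, f.readout, f.units, f.tissue, f.stim,
       f.quantification, f.sample_key,
       a.analyte_name,
       s.assay, s.pi, s.project, s.lot, s.file_name,
       sa.sample_id_ext, sa.year, sa.month, sa.week, sa.day, sa.draw,
       sa.person_key,
       p.person_id_ext, p.gender, p.age_band, p.ethnicity, p.condition,
       p.treatment, p.response
FROM aliquot_fact f
JOIN analyte a USING (analyte_key)
JOIN source  s USING (source_key)
LEFT JOIN sample sa USING (sample_key)
LEFT JOIN person p ON sa.person_key = p.person_key
"""


def fact_frame(store: Store) -> pd.DataFrame:
    """Denormalized fact view with one string column per cube level.

    Cached on the store and invalidated by its mutation counter.
    """
    cache = getattr(store, "_olap_frame_cache", None)
    if cache is not None and cache[0] == store.mutation_count:
        return cache[1]
    df = pd.read_sql_query(_FRAME_SQL, store.conn)
    no_sample = df["sample_key"].isna()
    no_person = df["person_key"].isna()

    df["Assay"] = df["assay"]
    df["Analyte"] = df["analyte_name"]
    df["Units"] = df["units"]
    for lvl, col in zip(TIME_LEVELS, ("year", "month", "week", "day", "draw")):
        s = df[col].astype("Int64").astype(str).where(df[col].notna(),
                                                      UNSPECIFIED)
        df[lvl] = s.where(~no_sample, UNMAPPED)
    for lvl, col in zip(PERSON_LEVELS, ("gender", "age_band", "ethnicity",
                                        "condition", "treatment", "response")):
        s = df[col].where(df[col].notna() & (df[col] != ""), UNSPECIFIED)
        df[lvl] = s.where(~no_person, UNMAPPED)
    for lvl, col in zip(("PI", "Project", "Lot", "Document"),
                        ("pi", "project", "lot", "file_name")):
        df[lvl] = df[col].where(df[col] != "", UNSPECIFIED)
    df["Tissue"] = df["tissue"]
    df["Stim"] = df["stim"]
    df["Quantification"] = df["quantification"]
    store._olap_frame_cache = (store.mutation_count, df)
    return df


# -- queries and results ---------------------------------------------------

@dataclass
class CubeQuery:
    """A structured cube request, serializable as JSON (no MDX)."""

    rows: list[str] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)
    filters: list[tuple[str, list[str]]] = field(default_factory=list)
    measures: list[str] = field(default_factory=lambda: ["n", "mean"])

    def validate(self) -> None:
        for lvl in list(self.rows) + list(self.columns):
            if lvl not in LEVELS:
                raise QueryError(f"unknown dimension level {lvl!r}")
        overlap = set(self.rows) & set(self.columns)
        if overlap:
            raise QueryError(
                f"level(s) {sorted(overlap)} appear on both axes")
        for axis in (self.rows, self.columns):
            if len(axis) != len(set(axis)):
                raise QueryError("a level appears twice on one axis")
        for lvl, members in self.filters:
            if lvl not in LEVELS:
                raise QueryError(f"filter references unknown level {lvl!r}")
            if not members:
                raise QueryError(f"filter on {lvl!r} has an empty member set")
        for m in self.measures:
            if m not in MEASURES:
                raise QueryError(f"unknown measure {m!r}")

    def to_dict(self) -> dict:
        return {"rows": list(self.rows), "columns": list(self.columns),
                "filters": [[lvl, list(m)] for lvl, m in self.filters],
                "measures": list(self.measures)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CubeQuery":
        return cls(rows=list(d.get("rows", [])),
                   columns=list(d.get("columns", [])),
                   filters=[(lvl, list(m)) for lvl, m in d.get("filters", [])],
                   measures=list(d.get("measures", ["n", "mean"])))


def compute_measures(values) -> dict:
    """All measures of one multiset of readouts.

    N=0 leaves every other measure null; sd needs N>=2; cv is null when the
    mean is zero. Median of an even N is the mean of the two central order
    statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    out: dict = {"n": int(n), "mean": None, "median": None, "min": None,
                 "max": None, "sd": None, "cv": None}
    if n == 0:
        return out
    out["mean"] = float(arr.mean())
    out["median"] = float(np.median(arr))
    out["min"] = float(arr.min())
    out["max"] = float(arr.max())
    if n >= 2:
        sd = float(arr.std(ddof=1))
        out["sd"] = sd
        out["cv"] = None if out["mean"] == 0 else sd / out["mean"]
    return out


def _member_key(member: str):
    # subtotals first, then numeric members in numeric order, then strings
    if member == ALL:
        return (0, 0.0, "")
    try:
        return (1, float(member), "")
    except ValueError:
        return (2, 0.0, member)


def _tuple_key(tup: tuple) -> tuple:
    return tuple(_member_key(m) for m in tup)


@dataclass
class PivotResult:
    """A computed pivot: nested headers, per-cell measure vectors, and the
    query needed to drill back through to the underlying facts."""

    query: CubeQuery
    row_levels: list[str]
    col_levels: list[str]
    row_headers: list[tuple]
    col_headers: list[tuple]
    cells: dict            # (row_tuple, col_tuple) -> {measure: value}
    implicit_units: bool = False
    notice: str | None = None

    def cell(self, row: tuple, col: tuple) -> dict | None:
        return self.cells.get((tuple(row), tuple(col)))

    def leaf_rows(self) -> list[tuple]:
        """Row headers at full depth (no "(all)" component)."""
        return [r for r in self.row_headers if ALL not in r]

    def leaf_cols(self) -> list[tuple]:
        return [c for c in self.col_headers if ALL not in c]


def _axis_variants(levels: list[str]) -> list[tuple[bool, ...]]:
    """Roll-up masks for one axis: True = concrete, False = "(all)".

    Prefix cuts at every depth; the Units level is exempt from roll-up and
    stays concrete in every variant.
    """
    variants = []
    n = len(levels)
    for depth in range(n + 1):
        mask = tuple(i < depth or levels[i] == "Units" for i in range(n))
        if mask not in variants:
            variants.append(mask)
    return variants


def _filter_mask(frame: pd.DataFrame, query: CubeQuery):
    """Combined boolean mask of all filters, or None when unfiltered.

    A filter naming a member absent from the level's domain is a query
    error.
    """
    mask = None
    for lvl, members in query.filters:
        members = [str(m) for m in members]
        domain = set(frame[lvl].unique())
        unknown = [m for m in members if m not in domain]
        if unknown:
            raise QueryError(
                f"filter on {lvl!r} names unknown member(s) {unknown}")
        m = frame[lvl].isin(members)
        mask = m if mask is None else (mask & m)
    return mask


def _apply_filters(frame: pd.DataFrame, query: CubeQuery) -> pd.DataFrame:
    mask = _filter_mask(frame, query)
    return frame if mask is None else frame[mask]


def aggregate(store: Store, query: CubeQuery) -> PivotResult:
    """Evaluate a cube query against the store.

    Every cell aggregates exactly the facts whose level members match the
    cell's row/column tuples and all filters. Roll-up subtotal members
    ("(all)") are included for every prefix depth of each axis, except over
    the Units level.
    """
    query.validate()
    full = fact_frame(store)

    row_levels = list(query.rows)
    col_levels = list(query.columns)
    implicit_units = "Units" not in row_levels + col_levels
    if implicit_units:
        row_levels = row_levels + ["Units"]

    # work on just the columns this query touches; filters copy the frame
    needed = list(dict.fromkeys(
        row_levels + col_levels + [lvl for lvl, _ in query.filters]
        + ["readout"]))
    mask = _filter_mask(full, query)
    frame = full[needed] if mask is None else full.loc[mask, needed]

    cells: dict = {}
    row_headers: set = set()
    col_headers: set = set()
    for rmask in _axis_variants(row_levels):
        for cmask in _axis_variants(col_levels):
            concrete = ([lvl for lvl, keep in zip(row_levels, rmask) if keep]
                        + [lvl for lvl, keep in zip(col_levels, cmask) if keep])
            if not concrete:
                groups = [((), frame)] if len(frame) else []
            else:
                groups = frame.groupby(concrete, sort=False, observed=True)
                groups = [(k if isinstance(k, tuple) else (k,), g)
                          for k, g in groups]
            for key, g in groups:
                it = iter(key)
                members = {lvl: next(it) for lvl in concrete}
                rt = tuple(members[lvl] if keep else ALL
                           for lvl, keep in zip(row_levels, rmask))
                ct = tuple(members[lvl] if keep else ALL
                           for lvl, keep in zip(col_levels, cmask))
                cells[(rt, ct)] = compute_measures(g["readout"].to_numpy())
                row_headers.add(rt)
                col_headers.add(ct)

    return PivotResult(
        query=query, row_levels=row_levels, col_levels=col_levels,
        row_headers=sorted(row_headers, key=_tuple_key),
        col_headers=sorted(col_headers, key=_tuple_key),
        cells=cells, implicit_units=implicit_units)


def drill_down(store: Store, result: PivotResult, axis: str,
               member: str) -> PivotResult:
    """Expand ``member`` on an axis by appending its child hierarchy level.

    Parent cells are retained as "(all)" subtotal tuples of the re-run
    query. Expanding a leaf member (or a level already expanded) is a
    no-op carrying a notice.
    """
    if axis not in ("rows", "columns"):
        raise QueryError(f"axis must be 'rows' or 'columns', got {axis!r}")
    user_levels = result.query.rows if axis == "rows" else result.query.columns
    axis_levels = result.row_levels if axis == "rows" else result.col_levels
    headers = result.row_headers if axis == "rows" else result.col_headers
    member = str(member)

    found_level = None
    for i in reversed(range(len(user_levels))):
        pos = axis_levels.index(user_levels[i])
        if any(t[pos] == member for t in headers):
            found_level = user_levels[i]
            break
    if found_level is None:
        raise QueryError(f"member {member!r} not found on axis {axis!r}")
    child = child_level(found_level)
    if child is None:
        result.notice = f"{found_level!r} member {member!r} is a leaf; no-op"
        return result
    if child in result.query.rows + result.query.columns or (
            child == "Units" and result.implicit_units):
        result.notice = f"level {child!r} is already displayed; no-op"
        return result
    q = CubeQuery.from_dict(result.query.to_dict())
    (q.rows if axis == "rows" else q.columns).append(child)
    return aggregate(store, q)


def drill_through(store: Store, result: PivotResult, row: tuple,
                  col: tuple) -> pd.DataFrame:
    """All and only the facts behind one cell, with person/sample/source
    context columns. The number of returned rows equals the cell's N."""
    row, col = tuple(row), tuple(col)
    if (row, col) not in result.cells:
        raise QueryError(f"no such cell: {row!r} x {col!r}")
    frame = _apply_filters(fact_frame(store), result.query)
    for lvl, member in list(zip(result.row_levels, row)) + list(
            zip(result.col_levels, col)):
        if member != ALL:
            frame = frame[frame[lvl] == member]
    detail = frame.copy()
    for c in ("person_id_ext", "sample_id_ext"):
        detail[c] = detail[c].where(detail[c].notna(), UNMAPPED)
    return detail[DETAIL_COLUMNS].reset_index(drop=True)


# -- export / import -------------------------------------------------------

def _flatten(tup: tuple) -> str:
    return "/".join(tup) if tup else ALL


def export_pivot(result: PivotResult, path: str | Path,
                 format: str = "csv") -> None:
    """Lossless flat export of a pivot; nested headers are flattened with
    "/" (CSV) or kept as arrays (JSON)."""
    if not result.cells:
        raise QueryError("cannot export an empty pivot")
    if format == "csv":
        _export_csv(result, path)
    elif format == "json":
        Path(path).write_text(json.dumps(pivot_to_json_obj(result),
                                         sort_keys=True, indent=1),
                              encoding="utf-8")
    else:
        raise QueryError(f"unknown export format {format!r}")


def _export_csv(result: PivotResult, path: str | Path) -> None:
    measures = result.query.measures
    header = list(result.row_levels) + [
        f"{_flatten(ct)}|{m}" for ct in result.col_headers for m in measures]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for rt in result.row_headers:
            rowvals: list = list(rt)
            for ct in result.col_headers:
                cell = result.cells.get((rt, ct))
                for m in measures:
                    v = None if cell is None else cell[m]
                    rowvals.append("" if v is None else repr(v))
            w.writerow(rowvals)


def import_pivot_csv(path: str | Path, n_row_levels: int) -> dict:
    """Re-read an exported pivot CSV back into a cells mapping
    ``(row_tuple, col_tuple) -> {measure: value}`` (round-trip check)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        col_specs = []
        for h in header[n_row_levels:]:
            flat, measure = h.rsplit("|", 1)
            col_specs.append((tuple(flat.split("/")), measure))
        cells: dict = {}
        for rec in reader:
            rt = tuple(rec[:n_row_levels])
            for (ct, m), text in zip(col_specs, rec[n_row_levels:]):
                if text == "":
                    continue
                v = float(text)
                if m == "n":
                    v = int(v)
                cells.setdefault((rt, ct), {})[m] = v
    return cells


def pivot_to_json_obj(result: PivotResult) -> dict:
    return {
        "row_levels": list(result.row_levels),
        "col_levels": list(result.col_levels),
        "measures": list(result.query.measures),
        "row_headers": [list(t) for t in result.row_headers],
        "col_headers": [list(t) for t in result.col_headers],
        "cells": [
            {"row": list(rt), "col": list(ct),
             "measures": {m: cell[m] for m in result.query.measures}}
            for (rt, ct), cell in sorted(result.cells.items(),
                                         key=lambda kv: (_tuple_key(kv[0][0]),
                                                         _tuple_key(kv[0][1])))
        ],
    }


def load_pivot_schema() -> dict:
    """The shipped structural schema for JSON pivot exports."""
    text = resources.files("immunomart").joinpath("pivot_schema.json") \
                    .read_text(encoding="utf-8")
    return json.loads(text)


def validate_pivot_json(obj: dict) -> None:
    """Validate a JSON pivot export against the shipped schema.

    Implements the subset of JSON-schema keywords the shipped file uses
    (type, required, properties, items, enum); raises QueryError on the
    first violation.
    """
    schema = load_pivot_schema()

    def check(node, sch, where):
        t = sch.get("type")
        types = {"object": dict, "array": list, "string": str,
                 "integer": int, "number": (int, float), "null": type(None)}
        if t is not None:
            allowed = t if isinstance(t, list) else [t]
            if not any(isinstance(node, types[a]) and not (
                    a in ("integer",) and isinstance(node, bool))
                    for a in allowed):
                raise QueryError(f"{where}: expected {t}, got"
                                 f" {type(node).__name__}")
        if "enum" in sch and node not in sch["enum"]:
            raise QueryError(f"{where}: {node!r} not in {sch['enum']}")
        if isinstance(node, dict):
            for req in sch.get("required", []):
                if req not in node:
                    raise QueryError(f"{where}: missing key {req!r}")
            for k, sub in sch.get("properties", {}).items():
                if k in node:
                    check(node[k], sub, f"{where}.{k}")
        if isinstance(node, list) and "items" in sch:
            for i, item in enumerate(node):
                check(item, sch["items"], f"{where}[{i}]")

    check(obj, schema, "$")
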