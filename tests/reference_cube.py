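"""Independent flat filter-group-aggregate reference for cube checks.

Deliberately avoids the package's OLAP code path: the denormalized view is
rebuilt from the store's CSV table exports with pandas merges, level
values are derived by plain Python, and measures come from the stdlib
``statistics`` module. Also provides seeded random-store and random-query
generators for oracle batteries.
"""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd

from immunomart.olap import ALL, CubeQuery, PivotResult
from immunomart.warehouse import (AliquotFact, AnalyteRecord, PersonRecord,
                                  SampleRecord, SourceRecord, Store,
                                  create_store)

UNMAPPED = "(unmapped)"
UNSPECIFIED = "(unspecified)"


def reference_measures(values: list[float]) -> dict:
    n = len(values)
    out = {"n": n, "mean": None, "median": None, "min": None, "max": None,
           "sd": None, "cv": None}
    if n == 0:
        return out
    out["mean"] = statistics.fmean(values)
    out["median"] = statistics.median(values)
    out["min"] = min(values)
    out["max"] = max(values)
    if n >= 2:
        out["sd"] = statistics.stdev(values)
        out["cv"] = None if out["mean"] == 0 else out["sd"] / out["mean"]
    return out


def reference_frame(store: Store, tmpdir) -> pd.DataFrame:
    """Denormalize via CSV exports + pandas merges (independent of the
    engine's SQL join)."""
    paths = {}
    for table in ("aliquot_fact", "analyte", "source", "sample", "person"):
        p = tmpdir / f"{table}.csv"
        store.export_table(table, p)
        paths[table] = pd.read_csv(p)
    f = paths["aliquot_fact"]
    df = f.merge(paths["analyte"], on="analyte_key", how="left")
    df = df.merge(paths["source"], on="source_key", how="left")
    df = df.merge(paths["sample"], on="sample_key", how="left")
    df = df.merge(paths["person"], on="person_key", how="left",
                  suffixes=("", "_person"))

    rows = []
    for rec in df.to_dict("records"):
        has_sample = not pd.isna(rec.get("sample_key"))
        has_person = has_sample and not pd.isna(rec.get("person_key"))

        def timeval(col):
            if not has_sample:
                return UNMAPPED
            v = rec.get(col)
            return UNSPECIFIED if pd.isna(v) else str(int(v))

        def personval(col):
            if not has_person:
                return UNMAPPED
            v = rec.get(col)
            return UNSPECIFIED if (pd.isna(v) or v == "") else str(v)

        def sourceval(col):
            v = rec.get(col)
            return UNSPECIFIED if (pd.isna(v) or v == "") else str(v)

        rows.append({
            "Assay": rec["assay"], "Analyte": rec["analyte_name"],
            "Units": rec["units"],
            "Year": timeval("year"), "Month": timeval("month"),
            "Week": timeval("week"), "Day": timeval("day"),
            "Draw": timeval("draw"),
            "Gender": personval("gender"), "AgeBand": personval("age_band"),
            "Ethnicity": personval("ethnicity"),
            "Condition": personval("condition"),
            "Treatment": personval("treatment"),
            "Response": personval("response"),
            "PI": sourceval("pi"), "Project": sourceval("project"),
            "Lot": sourceval("lot"), "Document": sourceval("file_name"),
            "Tissue": rec["tissue"], "Stim": rec["stim"],
            "Quantification": rec["quantification"],
            "readout": rec["readout"],
        })
    cols = ["Assay", "Analyte", "Units", "Year", "Month", "Week", "Day",
            "Draw", "Gender", "AgeBand", "Ethnicity", "Condition",
            "Treatment", "Response", "PI", "Project", "Lot", "Document",
            "Tissue", "Stim", "Quantification", "readout"]
    return pd.DataFrame(rows, columns=cols)


def reference_cell(frame: pd.DataFrame, query: CubeQuery,
                   result: PivotResult, row: tuple, col: tuple) -> dict:
    """Recompute one pivot cell by flat filtering and aggregating."""
    sub = frame
    for lvl, members in query.filters:
        sub = sub[sub[lvl].isin([str(m) for m in members])]
    for lvl, member in list(zip(result.row_levels, row)) + list(
            zip(result.col_levels, col)):
        if member != ALL:
            sub = sub[sub[lvl] == member]
    return reference_measures(list(sub["readout"]))


def assert_cells_match(result: PivotResult, frame: pd.DataFrame,
                       rel: float = 1e-9) -> int:
    """Check every engine cell against the reference; returns #cells."""
    checked = 0
    for (row, col), cell in result.cells.items():
        expect = reference_cell(frame, result.query, result, row, col)
        assert cell["n"] == expect["n"], (row, col)
        for m in ("mean", "median", "min", "max", "sd", "cv"):
            a, b = cell[m], expect[m]
            if b is None:
                assert a is None, (row, col, m)
            else:
                assert a == b or abs(a - b) <= rel * max(abs(a), abs(b)), \
                    (row, col, m, a, b)
        checked += 1
    return checked


# -- random fixtures for oracle batteries ----------------------------------

_TISSUES = ["cryopreserved serum", "cryopreserved PBMC", "fresh plasma"]
_STIMS = ["none", "IL-6", "IFNg"]
_UNITS = ["MFI", "pg/ml", "percent of parent population"]


def random_store(rng: np.random.Generator, n_facts: int = 400) -> Store:
    """A messy random store: several sources/assays, partially linked
    samples and persons, null ordinals, mixed units."""
    store = create_store(":memory:")
    n_persons = int(rng.integers(3, 10))
    person_keys = []
    for i in range(n_persons):
        person_keys.append(store.upsert_person(PersonRecord(
            person_id_ext=f"P{i:03d}",
            gender=str(rng.choice(["male", "female", "unknown"])),
            ethnicity=str(rng.choice(["white", "asian", "unknown"])),
            condition=str(rng.choice(["healthy", "lupus"])),
            age_years=(None if rng.random() < 0.2
                       else int(rng.integers(18, 90))))))
    n_samples = int(rng.integers(5, 15))
    sample_keys = []
    for i in range(n_samples):
        pkey = None if rng.random() < 0.2 else int(rng.choice(person_keys))
        day = None if rng.random() < 0.3 else int(rng.choice([0, 7, 28]))
        week = None if rng.random() < 0.7 else int(rng.integers(0, 5))
        sample_keys.append(store.upsert_sample(
            SampleRecord(sample_id_ext=f"S{i:03d}", day=day, week=week),
            person_key=pkey))
    n_sources = int(rng.integers(1, 4))
    source_keys = []
    for i in range(n_sources):
        source_keys.append(store.insert_source(SourceRecord(
            file_name=f"batch_{i}.csv", file_hash=f"h{i}",
            upload_date="2011-01-01",
            assay=str(rng.choice(["Human Luminex 51plex", "MSD 4plex"])),
            lot=str(rng.choice(["H51-1", "H51-2", ""])),
            pi="PI-01", project=str(rng.choice(["A", "B"])))))
    n_analytes = int(rng.integers(2, 7))
    analyte_keys = [store.upsert_analyte(AnalyteRecord(f"A{i}", "luminex"))
                    for i in range(n_analytes)]

    facts = []
    for i in range(n_facts):
        facts.append(AliquotFact(
            aliquot_id_ext=f"ALQ{i:05d}",
            analyte_key=int(rng.choice(analyte_keys)),
            source_key=int(rng.choice(source_keys)),
            sample_key=(None if rng.random() < 0.15
                        else int(rng.choice(sample_keys))),
            readout=float(np.round(rng.lognormal(5, 1), 2)),
            units=str(rng.choice(_UNITS)),
            quantification=str(rng.choice(
                ["in_range", "in_range", "in_range", "below_loq",
                 "above_loq"])),
            tissue=str(rng.choice(_TISSUES)),
            stim=str(rng.choice(_STIMS))))
    store.insert_facts(facts)
    return store


_LEVEL_POOL = ["Assay", "Analyte", "Units", "Day", "Week", "Gender",
               "AgeBand", "Condition", "Lot", "Project", "Tissue", "Stim",
               "Quantification", "Document"]


def random_query(rng: np.random.Generator, frame: pd.DataFrame) -> CubeQuery:
    levels = list(rng.choice(_LEVEL_POOL, size=int(rng.integers(1, 5)),
                             replace=False))
    n_rows = int(rng.integers(0, len(levels) + 1))
    rows, cols = levels[:n_rows], levels[n_rows:]
    filters = []
    if rng.random() < 0.7:
        remaining = [lvl for lvl in _LEVEL_POOL if lvl not in levels]
        for lvl in rng.choice(remaining, size=int(rng.integers(1, 3)),
                              replace=False):
            domain = sorted(frame[lvl].unique())
            if not domain:
                continue
            k = int(rng.integers(1, min(3, len(domain)) + 1))
            members = [str(m) for m in
                       rng.choice(domain, size=k, replace=False)]
            filters.append((str(lvl), members))
    return CubeQuery(rows=[str(r) for r in rows],
                     columns=[str(c) for c in cols], filters=filters,
                     measures=list(("n", "mean", "median", "min", "max",
                                    "sd", "cv")))
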