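"""End-to-end workflows: build a warehouse from a generated or on-disk
study, and run the mean-by-gender cube screen.

These functions are thin orchestration over the module APIs -- the same
calls a user would script by hand (or drive through the CLI), packaged for
examples and for reproducibility checks.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import linkage, metadata, olap
from .batch import load_batch, parse_batch_sheet, SourceAttributes
from .synthetic import (GeneratedStudy, Manifest, StudySpec,
                        generate_study_data, PERSON_COLMAP, SAMPLE_COLMAP,
                        PERSON_COLUMNS, SAMPLE_COLUMNS, GENDER_VALUE_MAP)
from .warehouse import Store, create_store


def _load_all(store: Store, person_df: pd.DataFrame, sample_df: pd.DataFrame,
              sheets, project: str, strip_phrases: list[str]) -> None:
    metadata.seed_default_vocabularies(store)
    metadata.load_metadata(store, person_df,
                           metadata.ColumnMapping(dict(PERSON_COLMAP)),
                           value_maps={"gender": dict(GENDER_VALUE_MAP)},
                           project=project)
    metadata.load_metadata(store, sample_df,
                           metadata.ColumnMapping(dict(SAMPLE_COLMAP)),
                           project=project)
    for sheet, attrs in sheets:
        load_batch(store, sheet, attrs)
    sess = linkage.open_session(store, "aliquot_sample")
    if sess.children:
        for phrase in strip_phrases:
            linkage.strip_phrase(sess, "child", phrase)
        linkage.map_equals(sess)
        linkage.commit(sess, store)


def build_study_store(study: GeneratedStudy,
                      store_path: str | Path = ":memory:") -> Store:
    """Ingest and link an in-memory generated study into a (new) store."""
    store = create_store(store_path)
    person_df = pd.DataFrame(study.person_rows, columns=PERSON_COLUMNS)
    sample_df = pd.DataFrame(study.sample_rows, columns=SAMPLE_COLUMNS)
    _load_all(store, person_df, sample_df, study.sheets,
              study.spec.project, study.manifest.strip_phrases)
    return store


def load_study_dir(study_dir: str | Path,
                   store_path: str | Path = ":memory:") -> Store:
    """Ingest and link a study previously written by ``generate_study``."""
    study_dir = Path(study_dir)
    manifest = Manifest.from_json(
        (study_dir / "manifest.json").read_text(encoding="utf-8"))
    store = create_store(store_path)
    person_df = metadata.read_metadata_sheet(study_dir / "person_metadata.csv")
    sample_df = metadata.read_metadata_sheet(study_dir / "sample_metadata.csv")
    sheets = []
    for entry in manifest.files:
        sheet = parse_batch_sheet(study_dir / entry["file_name"],
                                  entry["assay_family"])
        sheets.append((sheet, SourceAttributes(**entry["attrs"])))
    _load_all(store, person_df, sample_df, sheets,
              manifest.spec["project"], manifest.strip_phrases)
    return store


def gender_fold_table(store: Store, assay: str = "Human Luminex 51plex",
                      lot: str | None = None) -> pd.DataFrame:
    """Cube screen of mean-by-gender: one row per analyte with the female
    and male means, their N's, and the female/male fold ratio."""
    filters: list = [("Assay", [assay])]
    if lot is not None:
        filters.append(("Lot", [lot]))
    result = olap.aggregate(store, olap.CubeQuery(
        rows=["Analyte"], columns=["Gender"], filters=filters,
        measures=["n", "mean"]))
    records = []
    for rt in result.leaf_rows():
        analyte = rt[0]
        cell_f = result.cell(rt, ("female",))
        cell_m = result.cell(rt, ("male",))
        mean_f = cell_f["mean"] if cell_f else None
        mean_m = cell_m["mean"] if cell_m else None
        fold = (mean_f / mean_m
                if mean_f is not None and mean_m not in (None, 0) else None)
        records.append({"analyte": analyte,
                        "n_female": cell_f["n"] if cell_f else 0,
                        "n_male": cell_m["n"] if cell_m else 0,
                        "mean_female": mean_f, "mean_male": mean_m,
                        "fold_female_over_male": fold})
    return pd.DataFrame.from_records(records)


def screen_gender_bias(store: Store, threshold_pct: float = 20.0,
                       assay: str = "Human Luminex 51plex",
                       lot: str | None = None) -> set[str]:
    """Analytes whose empirical female/male mean ratio differs from 1 by
    more than ``threshold_pct`` percent (the ">20% difference" screen)."""
    table = gender_fold_table(store, assay=assay, lot=lot)
    out = set()
    for rec in table.itertuples():
        if rec.fold_female_over_male is None:
            continue
        if abs(rec.fold_female_over_male - 1.0) * 100.0 > threshold_pct:
            out.add(rec.analyte)
    return out


def run_gender_screen_trial(seed: int, n_persons: int = 434,
                            threshold_pct: float = 20.0) -> dict:
    """One full generation -> ingest -> link -> screen pass (bead-assay
    family only) against the planted ground truth.

    Returns the truth set, the pooled and per-lot detected sets, and
    whether the per-lot effect directions agree for every planted analyte.
    """
    from .synthetic import ground_truth_screen

    spec = StudySpec(n_persons=n_persons, seed=seed)
    study = generate_study_data(spec, families=("luminex",))
    store = build_study_store(study)
    truth = ground_truth_screen(study.manifest, threshold_pct)
    pooled = screen_gender_bias(store, threshold_pct)
    lot_tables = {lot: gender_fold_table(store, lot=lot)
                  for lot in spec.lots}
    per_lot = {}
    for lot, table in lot_tables.items():
        per_lot[lot] = {
            rec.analyte for rec in table.itertuples()
            if rec.fold_female_over_male is not None
            and abs(rec.fold_female_over_male - 1.0) * 100.0 > threshold_pct}
    directions_agree = True
    for analyte in truth:
        signs = []
        for lot in spec.lots:
            table = lot_tables[lot]
            fold = table.loc[table["analyte"] == analyte,
                             "fold_female_over_male"].iloc[0]
            signs.append(bool(fold > 1.0))
        if len(set(signs)) > 1:
            directions_agree = False
    store.close()
    return {"truth": truth, "pooled": pooled, "per_lot": per_lot,
            "directions_agree": directions_agree}
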