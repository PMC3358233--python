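"""Parsing and loading of batch-results sheets.

The canonical wide layout accepted here (CSV or XLSX, first worksheet):

* header row 1: ID column label, optional ``stim`` column label
  (phospho-flow), then one analyte name per column;
* header row 2: blank under the ID/stim columns, then the units string for
  each analyte column (e.g. ``MFI``, ``pg/ml``, ``percent of parent
  population``);
* one data row per aliquot (per aliquot x stim for phospho-flow): the
  verbatim aliquot ID, the stim name if present, then one readout cell per
  analyte.

Readout cell grammar: a plain number is quantified ``in_range``; a ``<``
prefix marks a value below the limit of quantification (``below_loq``) and
``>`` above it (``above_loq``), with the numeric part kept as the readout;
a blank cell emits no fact. Lab-native exports (xPONENT, FlowJo) must be
pre-converted to this layout.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import datetime as _dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import DuplicateLoadError, FormatError
from .warehouse import AliquotFact, AnalyteRecord, SourceRecord, Store, UNKNOWN

#: Registered assay families and their default assay label.
ASSAY_FAMILIES = {
    "luminex": "Human Luminex 51plex",
    "msd": "MSD 4plex",
    "phospho_flow": "Cytokine-stimulated phospho-flow",
    "flow_phenotyping": "Flow phenotyping",
}

Cell = tuple[float, str]  # (readout, quantification)


@dataclass
class BatchSheet:
    """Parsed canonical wide-format batch sheet."""

    file_name: str
    file_hash: str
    assay_family: str
    analytes: list[str]
    units: list[str]
    #: one entry per data row: (aliquot_id_ext, stim, cells); a cell is
    #: (readout, quantification) or None for a blank.
    rows: list[tuple[str, str, list[Cell | None]]]
    has_stim_column: bool = False

    def non_blank_cells(self) -> int:
        return sum(1 for _, _, cells in self.rows for c in cells if c is not None)


@dataclass
class SourceAttributes:
    """User-supplied classification of a batch file at upload time."""

    assay: str
    tissue: str = UNKNOWN
    operator: str = ""
    run_date: str = ""
    instrument: str = ""
    lot: str = ""
    pi: str = ""
    project: str = ""
    timepoint_hint: str = ""   # advisory only; time points live on samples

    def validate(self) -> None:
        if not self.assay:
            raise FormatError("source attribute 'assay' must be non-empty")


@dataclass
class LoadSummary:
    """Outcome of one load operation, JSON-serializable."""

    source_key: int | None = None
    facts_loaded: int = 0
    analytes_created: int = 0
    cells_skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def parse_cell(text: str) -> Cell | None:
    """Apply the readout-cell grammar; None for blank; FormatError otherwise."""
    s = text.strip()
    if not s:
        return None
    quant = "in_range"
    if s.startswith("<"):
        quant, s = "below_loq", s[1:].strip()
    elif s.startswith(">"):
        quant, s = "above_loq", s[1:].strip()
    try:
        return float(s), quant
    except ValueError:
        raise FormatError(f"cell {text!r} is neither blank, a number, nor a"
                          " '<'/'>' quantification marker") from None


def _read_grid(path: Path) -> tuple[list[list[str]], bytes]:
    """Read an XLSX (first worksheet) or CSV file as a grid of strings."""
    data = path.read_bytes()
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        import openpyxl

        wb = openpyxl.load_workbook(io.BytesIO(data), read_only=True,
                                    data_only=True)
        ws = wb.worksheets[0]
        grid = [["" if c is None else str(c) for c in row]
                for row in ws.iter_rows(values_only=True)]
        wb.close()
    else:
        text = data.decode("utf-8-sig")
        grid = [list(row) for row in csv.reader(io.StringIO(text))]
    return grid, data


def parse_batch_sheet(path: str | Path, assay_family: str) -> BatchSheet:
    """Parse one canonical wide-format batch sheet.

    Raises :class:`FormatError` with 1-based row/column coordinates on a
    ragged header or an unparseable cell.
    """
    path = Path(path)
    if assay_family not in ASSAY_FAMILIES:
        raise FormatError(f"assay family {assay_family!r} is not registered"
                          f" (known: {sorted(ASSAY_FAMILIES)})")
    grid, data = _read_grid(path)
    if len(grid) < 2:
        raise FormatError("sheet must have two header rows"
                          " (analyte names, units)", row=1)
    head, unit_row = grid[0], grid[1]
    n_meta = 1
    has_stim = len(head) > 1 and head[1].strip().lower() == "stim"
    if has_stim:
        n_meta = 2
    if len(unit_row) < len(head):
        unit_row = unit_row + [""] * (len(head) - len(unit_row))
    elif len(unit_row) > len(head):
        raise FormatError("units header row is longer than the analyte"
                          " header row", row=2, col=len(head) + 1)
    analytes = [a.strip() for a in head[n_meta:]]
    units = [u.strip() for u in unit_row[n_meta:]]
    if not analytes:
        raise FormatError("no analyte columns found", row=1, col=n_meta + 1)
    for j, (a, u) in enumerate(zip(analytes, units), start=n_meta + 1):
        if not a:
            raise FormatError("blank analyte name", row=1, col=j)
        if not u:
            raise FormatError(f"analyte {a!r} has no units entry", row=2, col=j)
    if len(set(analytes)) != len(analytes):
        dup = sorted({a for a in analytes if analytes.count(a) > 1})
        raise FormatError(f"duplicate analyte columns {dup}", row=1)

    rows: list[tuple[str, str, list[Cell | None]]] = []
    seen: set[tuple[str, str]] = set()
    for i, raw in enumerate(grid[2:], start=3):
        if not any(c.strip() for c in raw):
            continue
        if len(raw) < len(head):
            raw = raw + [""] * (len(head) - len(raw))
        elif len(raw) > len(head):
            raise FormatError("data row longer than header", row=i,
                              col=len(head) + 1)
        aliquot_id = raw[0].strip()
        if not aliquot_id:
            raise FormatError("blank aliquot ID", row=i, col=1)
        stim = raw[1].strip() if has_stim else "none"
        if has_stim and not stim:
            raise FormatError("blank stim value", row=i, col=2)
        if (aliquot_id, stim) in seen:
            raise FormatError(f"duplicate aliquot ID {aliquot_id!r}"
                              f" (stim {stim!r})", row=i, col=1)
        seen.add((aliquot_id, stim))
        cells: list[Cell | None] = []
        for j, text in enumerate(raw[n_meta:], start=n_meta + 1):
            try:
                cells.append(parse_cell(text))
            except FormatError as exc:
                raise FormatError(str(exc), row=i, col=j) from None
        rows.append((aliquot_id, stim, cells))

    return BatchSheet(file_name=path.name,
                      file_hash=hashlib.sha256(data).hexdigest(),
                      assay_family=assay_family, analytes=analytes,
                      units=units, rows=rows, has_stim_column=has_stim)


def load_batch(store: Store, sheet: BatchSheet, attrs: SourceAttributes,
               upload_date: str | None = None) -> LoadSummary:
    """Load a parsed sheet: one source row, new analytes, one fact per cell.

    Facts are created with ``sample_key`` null; identifier linkage happens
    later and in any order relative to metadata upload. A file whose
    (name, content-hash) pair was already loaded is rejected, naming the
    prior upload date.
    """
    attrs.validate()
    if upload_date is None:
        upload_date = _dt.date.today().isoformat()
    prior = store.find_source(sheet.file_name, sheet.file_hash)
    if prior is not None:
        raise DuplicateLoadError(
            f"file {sheet.file_name!r} with identical content was already"
            f" loaded on {prior[1]} (source_key={prior[0]})")

    summary = LoadSummary()
    n_before = store.count("analyte")
    analyte_keys = [
        store.upsert_analyte(AnalyteRecord(name, sheet.assay_family))
        for name in sheet.analytes
    ]
    summary.analytes_created = store.count("analyte") - n_before

    source_key = store.insert_source(SourceRecord(
        file_name=sheet.file_name, file_hash=sheet.file_hash,
        upload_date=upload_date, assay=attrs.assay, run_date=attrs.run_date,
        operator=attrs.operator, instrument=attrs.instrument, lot=attrs.lot,
        pi=attrs.pi, project=attrs.project))
    summary.source_key = source_key

    facts: list[AliquotFact] = []
    for aliquot_id, stim, cells in sheet.rows:
        for key, units, cell in zip(analyte_keys, sheet.units, cells):
            if cell is None:
                summary.cells_skipped += 1
                continue
            readout, quant = cell
            facts.append(AliquotFact(
                aliquot_id_ext=aliquot_id, analyte_key=key,
                source_key=source_key, readout=readout, units=units,
                quantification=quant, tissue=attrs.tissue, stim=stim))
    summary.facts_loaded = store.insert_facts(facts)
    store.audit("load_batch", summary.to_json(), stamp=upload_date)
    return summary


def export_source_sheet(store: Store, source_key: int, path: str | Path) -> None:
    """Re-pivot the facts of one source back into the canonical wide CSV.

    The numeric cells of a round-tripped export reproduce the original
    sheet's parsed values exactly (quantification markers included).
    """
    rows = store.execute(
        "SELECT f.aliquot_id_ext, f.stim, a.analyte_name, f.readout,"
        " f.units, f.quantification FROM aliquot_fact f"
        " JOIN analyte a USING (analyte_key) WHERE f.source_key=?"
        " ORDER BY f.fact_key", (source_key,)).fetchall()
    analytes: list[str] = []
    units: dict[str, str] = {}
    grid: dict[tuple[str, str], dict[str, str]] = {}
    order: list[tuple[str, str]] = []
    has_stim = any(r[1] != "none" for r in rows)
    for aliquot, stim, name, readout, u, quant in rows:
        if name not in units:
            analytes.append(name)
            units[name] = u
        key = (aliquot, stim)
        if key not in grid:
            grid[key] = {}
            order.append(key)
        prefix = {"in_range": "", "below_loq": "<", "above_loq": ">"}[quant]
        grid[key][name] = f"{prefix}{readout!r}"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        meta = ["aliquot_id"] + (["stim"] if has_stim else [])
        w.writerow(meta + analytes)
        w.writerow([""] * len(meta) + [units[a] for a in analytes])
        for aliquot, stim in order:
            cells = [grid[(aliquot, stim)].get(a, "") for a in analytes]
            w.writerow([aliquot] + ([stim] if has_stim else []) + cells)
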