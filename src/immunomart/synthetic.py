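"""Synthetic influenza-vaccination cohort generator.

Emulates a flu-vaccine monitoring study: healthy participants each sampled
at days 0, 7 and 28 relative to vaccination, assayed with a 51-plex
bead immunoassay (two kit lots, a fraction of samples re-tested on the
second lot), a 4-plex electrochemiluminescence cytokine panel (IL-1β,
IL-6, IL-8, TNF) and phosphoepitope flow cytometry (seven cytokine
stimulations plus an unstimulated baseline, read out as pSTAT1/3/5 MFI).

Readouts are drawn log-normally around per-analyte baselines, multiplied
by a per-lot factor and by planted female/male fold-ratios on a chosen
analyte subset -- the ground truth a cube screen of mean-by-gender should
recover. Sheets are emitted in the canonical wide dialect the ingestion
modules read, with aliquot IDs decorated by a lab-style prefix/suffix that
the linkage workflow must strip, and metadata sheets carrying deliberately
unharmonized terminology ("M"/"F", mixed-case ethnicity).

Nothing here claims biological realism of absolute concentrations; the
generator exists so every workflow is testable end-to-end without any
external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .batch import BatchSheet, SourceAttributes
from .errors import ValidationError

LUMINEX_51PLEX = [
    "CD40Ligand", "ENA-78", "Eotaxin", "FGF-basic", "G-CSF", "GM-CSF",
    "GRO-alpha", "HGF", "ICAM-1", "IFN-alpha", "IFN-gamma", "IL-10",
    "IL-12p40", "IL-12p70", "IL-13", "IL-15", "IL-17A", "IL-17F", "IL-18",
    "IL-1alpha", "IL-1beta", "IL-1RA", "IL-2", "IL-21", "IL-22", "IL-23",
    "IL-27", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8", "IP-10", "I-TAC",
    "Leptin", "LIF", "MCP-1", "MCP-3", "M-CSF", "MIG", "MIP-1alpha",
    "MIP-1beta", "NGF-beta", "PAI-1", "PDGF-BB", "RANTES", "SCF",
    "TGF-beta", "TNF-alpha", "TRAIL", "VEGF",
]

MSD_4PLEX = ["IL-1β", "IL-6", "IL-8", "TNF"]
STIMS = ["IFNα", "IFNγ", "IL-2", "IL-6", "IL-7", "IL-10", "IL-21"]
PHOSPHO_READOUTS = ["pSTAT1", "pSTAT3", "pSTAT5"]

#: Default planted female/male fold-ratios (>= 1.25 on four analytes,
#: 1.0 everywhere else).
DEFAULT_GENDER_EFFECT = {
    "ENA-78": 1.35,
    "GM-CSF": 1.30,
    "Leptin": 1.60,
    "PDGF-BB": 1.40,
}

_ETHNICITIES = ["White", "Black", "Asian", "Hispanic", "Other"]


@dataclass
class StudySpec:
    """Parameters of the synthetic cohort; the seed fully determines all
    output."""

    n_persons: int = 434
    visit_days: list[int] = field(default_factory=lambda: [0, 7, 28])
    luminex_analytes: list[str] = field(
        default_factory=lambda: list(LUMINEX_51PLEX))
    msd_analytes: list[str] = field(default_factory=lambda: list(MSD_4PLEX))
    stims: list[str] = field(default_factory=lambda: list(STIMS))
    phospho_readouts: list[str] = field(
        default_factory=lambda: list(PHOSPHO_READOUTS))
    lots: list[str] = field(default_factory=lambda: ["H51-1", "H51-2"])
    lot_factors: dict[str, float] = field(
        default_factory=lambda: {"H51-1": 1.0, "H51-2": 1.25})
    retest_fraction: float = 0.15
    gender_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_EFFECT))
    sigma: float = 0.3                     # log-scale noise SD
    baseline_range: tuple[float, float] = (500.0, 20000.0)   # MFI-like
    msd_baseline_range: tuple[float, float] = (1.0, 100.0)   # pg/ml-like
    phospho_baseline_range: tuple[float, float] = (50.0, 500.0)
    below_loq_rate: float = 0.01
    id_prefix: str = "HIMC-"
    id_suffix: str = "_A"
    il6_pstat1_coupling: float = 0.0       # optional cross-assay effect
    project: str = "FluVax"
    pi: str = "PI-01"
    seed: int = 12345

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValidationError("n_persons", "must be >= 1")
        if self.sigma <= 0:
            raise ValidationError("sigma", "must be > 0")
        for a, f in self.gender_effect.items():
            if f <= 0:
                raise ValidationError("gender_effect",
                                      f"fold for {a!r} must be > 0")
        for lot in self.lots:
            if self.lot_factors.get(lot, 0) <= 0:
                raise ValidationError("lot_factors",
                                      f"factor for {lot!r} must be > 0")
        if not (0 <= self.retest_fraction <= 1):
            raise ValidationError("retest_fraction", "must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_range"] = list(self.baseline_range)
        d["msd_baseline_range"] = list(self.msd_baseline_range)
        d["phospho_baseline_range"] = list(self.phospho_baseline_range)
        return d


@dataclass
class Manifest:
    """Everything a consumer needs to ingest, link and verify the study."""

    spec: dict
    files: list[dict]                  # file_name, assay_family, attrs
    strip_phrases: list[str]
    column_maps: dict                  # per metadata file: column -> attribute
    value_maps: dict                   # attribute -> incoming -> valid
    true_folds: dict                   # analyte -> female/male fold
    true_means: dict                   # "analyte|gender|lot" -> noise-free mean
    n_persons: int = 0
    n_samples: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1,
                          ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        return cls(**json.loads(text))


@dataclass
class GeneratedStudy:
    """In-memory form of one generated study (pre-serialization)."""

    spec: StudySpec
    person_rows: list[list[str]]       # Participant, Sex, Ethnicity, Age
    sample_rows: list[list[str]]       # Sample, Participant, Day
    sheets: list[tuple[BatchSheet, SourceAttributes]]
    manifest: Manifest


PERSON_COLUMNS = ["Participant", "Sex", "Ethnicity", "Age"]
SAMPLE_COLUMNS = ["Sample", "Participant", "Day"]

PERSON_COLMAP = {"Participant": "person_id", "Sex": "gender",
                 "Ethnicity": "ethnicity", "Age": "age_years"}
SAMPLE_COLMAP = {"Sample": "sample_id", "Participant": "person_id",
                 "Day": "day"}
GENDER_VALUE_MAP = {"M": "male", "F": "female"}


def _fold(spec: StudySpec, analyte: str, is_female: bool) -> float:
    return spec.gender_effect.get(analyte, 1.0) if is_female else 1.0


def _round1(x: float) -> float:
    return float(f"{x:.1f}")


def generate_study_data(spec: StudySpec,
                        families: tuple[str, ...] = ("luminex", "msd",
                                                     "phospho_flow")
                        ) -> GeneratedStudy:
    """Draw the whole study (persons, samples, batch sheets) in memory.

    ``families`` selects which assay families to generate; the metadata
    sheets and ground truth are always produced.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    person_ids = [f"P{i + 1:04d}" for i in range(spec.n_persons)]
    is_female = rng.random(spec.n_persons) < 0.5
    ages = rng.integers(20, 90, size=spec.n_persons)
    eth = rng.choice(len(_ETHNICITIES), size=spec.n_persons)
    person_rows = [[pid, "F" if f else "M", _ETHNICITIES[e], str(a)]
                   for pid, f, e, a in zip(person_ids, is_female, eth, ages)]
    female_of = dict(zip(person_ids, (bool(f) for f in is_female)))

    samples = [(f"{pid}-D{day:02d}", pid, day)
               for pid in person_ids for day in spec.visit_days]
    sample_rows = [[sid, pid, str(day)] for sid, pid, day in samples]

    sheets: list[tuple[BatchSheet, SourceAttributes]] = []
    true_means: dict[str, float] = {}

    if "luminex" in families:
        lum_base = np.exp(rng.uniform(np.log(spec.baseline_range[0]),
                                      np.log(spec.baseline_range[1]),
                                      size=len(spec.luminex_analytes)))
        primary = rng.integers(0, len(spec.lots), size=len(samples))
        retest = rng.random(len(samples)) < spec.retest_fraction
        for li, lot in enumerate(spec.lots):
            lot_factor = spec.lot_factors[lot]
            rows = []
            for si, (sid, pid, _day) in enumerate(samples):
                if primary[si] != li and not retest[si]:
                    continue
                female = female_of[pid]
                folds = np.array([_fold(spec, a, female)
                                  for a in spec.luminex_analytes])
                noise = np.exp(rng.normal(0.0, spec.sigma,
                                          size=len(spec.luminex_analytes)))
                vals = lum_base * lot_factor * folds * noise
                loq = rng.random(len(vals)) < spec.below_loq_rate
                cells = [(_round1(v), "below_loq" if q else "in_range")
                         for v, q in zip(vals, loq)]
                rows.append((f"{spec.id_prefix}{sid}{spec.id_suffix}",
                             "none", cells))
            sheets.append((
                BatchSheet(
                    file_name=f"luminex_{lot}.csv", file_hash=f"mem:{lot}",
                    assay_family="luminex",
                    analytes=list(spec.luminex_analytes),
                    units=["MFI"] * len(spec.luminex_analytes), rows=rows),
                SourceAttributes(assay="Human Luminex 51plex",
                                 tissue="cryopreserved serum", lot=lot,
                                 pi=spec.pi, project=spec.project,
                                 run_date="2010-06-01")))
            for a, b in zip(spec.luminex_analytes, lum_base):
                for g in ("female", "male"):
                    f = spec.gender_effect.get(a, 1.0) if g == "female" else 1.0
                    true_means[f"{a}|{g}|{lot}"] = b * lot_factor * f

    if "msd" in families:
        msd_base = np.exp(rng.uniform(np.log(spec.msd_baseline_range[0]),
                                      np.log(spec.msd_baseline_range[1]),
                                      size=len(spec.msd_analytes)))
        rows = []
        for sid, pid, _day in samples:
            female = female_of[pid]
            folds = np.array([_fold(spec, a, female)
                              for a in spec.msd_analytes])
            noise = np.exp(rng.normal(0.0, spec.sigma,
                                      size=len(spec.msd_analytes)))
            vals = msd_base * folds * noise
            cells = [(_round1(v), "in_range") for v in vals]
            rows.append((f"{spec.id_prefix}{sid}{spec.id_suffix}", "none",
                         cells))
        sheets.append((
            BatchSheet(file_name="msd_4plex.csv", file_hash="mem:msd",
                       assay_family="msd", analytes=list(spec.msd_analytes),
                       units=["pg/ml"] * len(spec.msd_analytes), rows=rows),
            SourceAttributes(assay="MSD 4plex", tissue="cryopreserved serum",
                             lot="MSD-1", pi=spec.pi, project=spec.project,
                             run_date="2010-06-15")))
        for a, b in zip(spec.msd_analytes, msd_base):
            for g in ("female", "male"):
                f = spec.gender_effect.get(a, 1.0) if g == "female" else 1.0
                true_means[f"{a}|{g}|MSD-1"] = b * f

    if "phospho_flow" in families:
        ph_base = np.exp(rng.uniform(np.log(spec.phospho_baseline_range[0]),
                                     np.log(spec.phospho_baseline_range[1]),
                                     size=len(spec.phospho_readouts)))
        induction = np.exp(rng.uniform(np.log(1.5), np.log(4.0),
                                       size=(len(spec.stims),
                                             len(spec.phospho_readouts))))
        rows = []
        for sid, pid, _day in samples:
            female = female_of[pid]
            aliquot = f"{spec.id_prefix}{sid}{spec.id_suffix}"
            for ki, stim in enumerate(["none"] + list(spec.stims)):
                mult = np.ones(len(spec.phospho_readouts)) if stim == "none" \
                    else induction[ki - 1].copy()
                if (female and spec.il6_pstat1_coupling > 0
                        and stim == "IL-6"):
                    j = spec.phospho_readouts.index("pSTAT1")
                    mult[j] *= (1.0 - spec.il6_pstat1_coupling)
                noise = np.exp(rng.normal(0.0, spec.sigma,
                                          size=len(spec.phospho_readouts)))
                vals = ph_base * mult * noise
                rows.append((aliquot, stim,
                             [(_round1(v), "in_range") for v in vals]))
        sheets.append((
            BatchSheet(file_name="phospho_flow.csv", file_hash="mem:phospho",
                       assay_family="phospho_flow",
                       analytes=list(spec.phospho_readouts),
                       units=["MFI"] * len(spec.phospho_readouts), rows=rows,
                       has_stim_column=True),
            SourceAttributes(assay="Cytokine-stimulated phospho-flow",
                             tissue="cryopreserved PBMC", lot="PF-1",
                             pi=spec.pi, project=spec.project,
                             run_date="2010-07-01")))

    manifest = Manifest(
        spec=spec.to_dict(),
        files=[{"file_name": sh.file_name, "assay_family": sh.assay_family,
                "attrs": dataclasses.asdict(attrs)}
               for sh, attrs in sheets],
        strip_phrases=[p for p in (spec.id_prefix, spec.id_suffix) if p],
        column_maps={"person_metadata.csv": dict(PERSON_COLMAP),
                     "sample_metadata.csv": dict(SAMPLE_COLMAP)},
        value_maps={"gender": dict(GENDER_VALUE_MAP)},
        true_folds={a: spec.gender_effect.get(a, 1.0)
                    for a in spec.luminex_analytes},
        true_means=true_means,
        n_persons=spec.n_persons,
        n_samples=len(samples))
    return GeneratedStudy(spec=spec, person_rows=person_rows,
                          sample_rows=sample_rows, sheets=sheets,
                          manifest=manifest)


def _write_csv(path: Path, rows: list[list[str]]) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh).writerows(rows)


def _sheet_to_rows(sheet: BatchSheet) -> list[list[str]]:
    meta = ["aliquot_id"] + (["stim"] if sheet.has_stim_column else [])
    out = [meta + sheet.analytes, [""] * len(meta) + sheet.units]
    marker = {"in_range": "", "below_loq": "<", "above_loq": ">"}
    for aliquot, stim, cells in sheet.rows:
        rec = [aliquot] + ([stim] if sheet.has_stim_column else [])
        for cell in cells:
            if cell is None:
                rec.append("")
            else:
                v, q = cell
                rec.append(f"{marker[q]}{v:.1f}")
        out.append(rec)
    return out


def generate_study(spec: StudySpec, outdir: str | Path,
                   families: tuple[str, ...] = ("luminex", "msd",
                                                "phospho_flow")) -> Manifest:
    """Write the full study to ``outdir`` as CSV files plus manifest.json.

    Identical specs (including the seed) produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study_data(spec, families=families)
    _write_csv(outdir / "person_metadata.csv",
               [PERSON_COLUMNS] + study.person_rows)
    _write_csv(outdir / "sample_metadata.csv",
               [SAMPLE_COLUMNS] + study.sample_rows)
    for sheet, _attrs in study.sheets:
        _write_csv(outdir / sheet.file_name, _sheet_to_rows(sheet))
    (outdir / "manifest.json").write_text(study.manifest.to_json() + "\n",
                                          encoding="utf-8")
    return study.manifest


def ground_truth_screen(manifest: Manifest,
                        threshold_pct: float = 20.0) -> set[str]:
    """Analytes whose TRUE (noise-free) female/male fold differs from 1 by
    more than ``threshold_pct`` percent -- the answer key for the
    mean-by-gender cube screen."""
    return {a for a, fold in manifest.true_folds.items()
            if abs(fold - 1.0) * 100.0 > threshold_pct}
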