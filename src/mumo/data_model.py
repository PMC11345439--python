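"""Cohort schema, manifest I/O and outcome labelling.

A cohort is a list of :class:`PatientRecord`. Each record bundles structured
patient information, optional pathology and radiology modalities (a structured
report plus image assets each) and the treatment outcome (RECIST category and
PFS/OS times with event flags).

The on-disk manifest is JSON-lines: one canonically serialised record per line
(sorted keys, fixed separators), so a valid manifest round-trips through
:func:`read_manifest` / :func:`write_manifest` byte-identically. A flat CSV
export is provided for interoperability.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "PatientInfo",
    "RadReport",
    "PathReport",
    "Outcome",
    "PatientRecord",
    "ManifestError",
    "CohortValidationError",
    "read_manifest",
    "write_manifest",
    "write_csv",
    "read_csv",
    "label_responder",
    "responder_threshold",
    "split_cohort",
]

SEX = ("male", "female")
TUMOR_SITE = ("GEJ", "nonGEJ")
DIFFERENTIATION = ("poor", "moderate", "well")
LAUREN = ("intestinal", "diffuse", "mixed", "NA")
TRI_STATE = ("pos", "neg", "NA")
MMR = ("pMMR", "dMMR", "NA")
TNM = ("III", "IV")
RECIST = ("CR", "PR", "SD", "PD")
COHORTS = ("antiHER2", "combo", "external")
HER2_LEVELS = ("0", "1+", "2+", "3+")
LN_SITES = ("perigastric", "celiac", "hepatoduodenal", "retroperitoneal",
            "mediastinal", "supraclavicular")
LESION_ORGANS = ("stomach", "liver", "lung", "lymph_node", "peritoneum",
                 "spleen", "bone", "soft_tissue")

#: RECIST v1.1 target-lesion caps applied to radiology assets.
MAX_LESIONS_TOTAL = 5
MAX_LESIONS_PER_ORGAN = 2

#: Cohort-specific PFS thresholds (months) for the responder definition.
#: The external cohort received the same anti-HER2 therapy, so it shares the
#: 8-month threshold.
PFS_THRESHOLD_MONTHS = {"antiHER2": 8.0, "combo": 10.0, "external": 8.0}


class ManifestError(ValueError):
    """Malformed manifest content (names the offending row/field)."""


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (names the patient_id)."""


def _check_enum(value, vocab, field_name, patient_id=""):
    if value not in vocab:
        raise CohortValidationError(
            f"patient {patient_id!r}: field {field_name!r} has value {value!r}, "
            f"expected one of {vocab}"
        )


@dataclass
class PatientInfo:
    """Baseline clinical information for one patient."""

    age: float
    sex: str
    tumor_site: str
    differentiation: str
    lauren: str
    treatment_line: int
    days_to_treatment: float
    pdl1: str
    mmr: str
    ebv: str
    tnm_stage: str

    def validate(self, patient_id: str = "") -> None:
        if not self.age > 0:
            raise CohortValidationError(f"patient {patient_id!r}: age must be > 0")
        _check_enum(self.sex, SEX, "sex", patient_id)
        _check_enum(self.tumor_site, TUMOR_SITE, "tumor_site", patient_id)
        _check_enum(self.differentiation, DIFFERENTIATION, "differentiation", patient_id)
        _check_enum(self.lauren, LAUREN, "lauren", patient_id)
        if not (isinstance(self.treatment_line, int) and self.treatment_line >= 1):
            raise CohortValidationError(
                f"patient {patient_id!r}: treatment_line must be an integer >= 1")
        if self.days_to_treatment < 0:
            raise CohortValidationError(
                f"patient {patient_id!r}: days_to_treatment must be >= 0")
        _check_enum(self.pdl1, TRI_STATE, "pdl1", patient_id)
        _check_enum(self.mmr, MMR, "mmr", patient_id)
        _check_enum(self.ebv, TRI_STATE, "ebv", patient_id)
        _check_enum(self.tnm_stage, TNM, "tnm_stage", patient_id)


@dataclass
class RadReport:
    """Structured radiology report (post-operative status and metastases)."""

    post_gastrectomy: bool
    n_met_lymph_nodes: int
    ln_locations: list[str] = field(default_factory=list)
    liver_met: bool = False
    lung_met: bool = False
    peritoneal_met: bool = False
    ln_type_diversity: int = 0

    def validate(self, patient_id: str = "") -> None:
        if self.n_met_lymph_nodes < 0 or self.ln_type_diversity < 0:
            raise CohortValidationError(
                f"patient {patient_id!r}: lymph-node counts must be non-negative")
        if (len(self.ln_locations) == 0) != (self.n_met_lymph_nodes == 0):
            raise CohortValidationError(
                f"patient {patient_id!r}: ln_locations must be empty iff "
                "n_met_lymph_nodes == 0")
        for loc in self.ln_locations:
            _check_enum(loc, LN_SITES, "ln_locations", patient_id)


@dataclass
class PathReport:
    """Structured pathology report (tumor content, TILs, HER2 heterogeneity)."""

    tumor_proportion: float
    til_level: float
    her2_heterogeneity: list[str] = field(default_factory=lambda: ["3+"])

    def validate(self, patient_id: str = "") -> None:
        for name in ("tumor_proportion", "til_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortValidationError(
                    f"patient {patient_id!r}: {name} must lie in [0, 1]")
        if not self.her2_heterogeneity:
            raise CohortValidationError(
                f"patient {patient_id!r}: her2_heterogeneity must be non-empty")
        for lvl in self.her2_heterogeneity:
            _check_enum(lvl, HER2_LEVELS, "her2_heterogeneity", patient_id)


@dataclass
class Outcome:
    """RECIST response category plus PFS/OS times (months) and event flags."""

    recist: str
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool

    def validate(self, patient_id: str = "") -> None:
        _check_enum(self.recist, RECIST, "recist", patient_id)
        if self.pfs_months < 0 or self.os_months < 0:
            raise CohortValidationError(
                f"patient {patient_id!r}: survival times must be >= 0")


@dataclass
class PatientRecord:
    """One manifest entry.

    ``pathology_assets`` is a list of tile image paths; ``radiology_assets``
    a list of ``(image, mask, organ)`` triples (the organ code drives the
    RECIST per-organ lesion cap). A modality is *present* when both its
    report and at least one asset exist.
    """

    patient_id: str
    cohort: str
    info: PatientInfo
    outcome: Outcome
    rad_report: Optional[RadReport] = None
    path_report: Optional[PathReport] = None
    pathology_assets: Optional[list[str]] = None
    radiology_assets: Optional[list[tuple[str, str, str]]] = None

    @property
    def has_pathology(self) -> bool:
        return self.path_report is not None and bool(self.pathology_assets)

    @property
    def has_radiology(self) -> bool:
        return self.rad_report is not None and bool(self.radiology_assets)

    def validate(self) -> None:
        pid = self.patient_id
        _check_enum(self.cohort, COHORTS, "cohort", pid)
        self.info.validate(pid)
        self.outcome.validate(pid)
        path_partial = (self.path_report is not None) or bool(self.pathology_assets)
        rad_partial = (self.rad_report is not None) or bool(self.radiology_assets)
        if path_partial and not self.has_pathology:
            raise CohortValidationError(
                f"patient {pid!r}: pathology modality must have both a report "
                "and at least one image asset")
        if rad_partial and not self.has_radiology:
            raise CohortValidationError(
                f"patient {pid!r}: radiology modality must have both a report "
                "and at least one (image, mask) asset")
        if not (self.has_pathology or self.has_radiology):
            raise CohortValidationError(
                f"patient {pid!r}: at least one of pathology/radiology must be present")
        if self.path_report is not None:
            self.path_report.validate(pid)
        if self.rad_report is not None:
            self.rad_report.validate(pid)
        if self.radiology_assets:
            if len(self.radiology_assets) > MAX_LESIONS_TOTAL:
                raise CohortValidationError(
                    f"patient {pid!r}: {len(self.radiology_assets)} radiology lesions "
                    f"exceed the RECIST cap of {MAX_LESIONS_TOTAL} target lesions")
            per_organ: dict[str, int] = {}
            for entry in self.radiology_assets:
                if len(entry) != 3:
                    raise CohortValidationError(
                        f"patient {pid!r}: radiology asset must be (image, mask, organ)")
                organ = entry[2]
                _check_enum(organ, LESION_ORGANS, "radiology_assets.organ", pid)
                per_organ[organ] = per_organ.get(organ, 0) + 1
                if per_organ[organ] > MAX_LESIONS_PER_ORGAN:
                    raise CohortValidationError(
                        f"patient {pid!r}: more than {MAX_LESIONS_PER_ORGAN} target "
                        f"lesions in organ {organ!r} violate the RECIST per-organ cap")


# ---------------------------------------------------------------------------
# serialisation

def _record_to_dict(rec: PatientRecord) -> dict:
    d = {
        "patient_id": rec.patient_id,
        "cohort": rec.cohort,
        "info": asdict(rec.info),
        "outcome": asdict(rec.outcome),
        "rad_report": asdict(rec.rad_report) if rec.rad_report else None,
        "path_report": asdict(rec.path_report) if rec.path_report else None,
        "pathology_assets": rec.pathology_assets,
        "radiology_assets": (
            [list(e) for e in rec.radiology_assets] if rec.radiology_assets else None
        ),
    }
    return d


def _record_from_dict(d: dict, row: int) -> PatientRecord:
    try:
        rad = RadReport(**d["rad_report"]) if d.get("rad_report") else None
        path = PathReport(**d["path_report"]) if d.get("path_report") else None
        rad_assets = d.get("radiology_assets")
        if rad_assets is not None:
            rad_assets = [tuple(e) for e in rad_assets]
        return PatientRecord(
            patient_id=d["patient_id"],
            cohort=d["cohort"],
            info=PatientInfo(**d["info"]),
            outcome=Outcome(**d["outcome"]),
            rad_report=rad,
            path_report=path,
            pathology_assets=d.get("pathology_assets"),
            radiology_assets=rad_assets,
        )
    except (KeyError, TypeError) as exc:
        raise ManifestError(f"manifest row {row}: malformed record ({exc})") from exc


def read_manifest(path: str | Path) -> list[PatientRecord]:
    """Read a JSON-lines manifest, validating every record.

    Raises :class:`ManifestError` for malformed rows and
    :class:`CohortValidationError` (naming the patient) for invariant
    violations. Record order is preserved.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ManifestError(f"manifest row {i}: invalid JSON ({exc})") from exc
            rec = _record_from_dict(d, i)
            rec.validate()
            records.append(rec)
    return records


def write_manifest(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as canonical JSON-lines (sorted keys, compact separators)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_dict(rec), sort_keys=True,
                                separators=(",", ":")))
            fh.write("\n")


_CSV_SET_FIELDS = {"ln_locations", "her2_heterogeneity"}


def write_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Flat CSV export: one column per scalar field, dotted names for nested
    blocks, set-valued fields semicolon-joined, asset lists semicolon-joined
    with ``|`` inside each lesion triple."""
    rows = []
    for rec in records:
        d = _record_to_dict(rec)
        row: dict[str, object] = {"patient_id": d["patient_id"], "cohort": d["cohort"]}
        for block in ("info", "outcome", "rad_report", "path_report"):
            sub = d[block] or {}
            for k, v in sub.items():
                if k in _CSV_SET_FIELDS:
                    v = ";".join(v)
                row[f"{block}.{k}"] = v
        row["pathology_assets"] = ";".join(d["pathology_assets"] or [])
        row["radiology_assets"] = ";".join(
            "|".join(e) for e in (d["radiology_assets"] or []))
        rows.append(row)
    cols: list[str] = []
    for row in rows:
        for k in row:
            if k not in cols:
                cols.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        writer.writerows(rows)


def read_csv(path: str | Path) -> list[PatientRecord]:
    """Read the CSV dialect written by :func:`write_csv`."""
    records = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            def block(prefix, row=row):
                out = {}
                for k, v in row.items():
                    if not k.startswith(prefix + ".") or v in ("", None):
                        continue
                    out[k.split(".", 1)[1]] = v
                return out

            def conv(cls, d):
                out = {}
                for f in cls.__dataclass_fields__.values():
                    if f.name not in d:
                        continue
                    raw = d[f.name]
                    if f.name in _CSV_SET_FIELDS:
                        out[f.name] = [s for s in raw.split(";") if s]
                    elif f.type in ("bool", bool):
                        out[f.name] = raw in ("True", "true", "1")
                    elif f.type in ("int", int):
                        out[f.name] = int(raw)
                    elif f.type in ("float", float):
                        out[f.name] = float(raw)
                    else:
                        out[f.name] = raw
                return out

            info_d, out_d = block("info"), block("outcome")
            rad_d, path_d = block("rad_report"), block("path_report")
            if not info_d or not out_d:
                raise ManifestError(f"csv row {i}: missing info/outcome columns")
            path_assets = [s for s in (row.get("pathology_assets") or "").split(";") if s]
            rad_assets = [tuple(s.split("|"))
                          for s in (row.get("radiology_assets") or "").split(";") if s]
            rec = PatientRecord(
                patient_id=row["patient_id"],
                cohort=row["cohort"],
                info=PatientInfo(**conv(PatientInfo, info_d)),
                outcome=Outcome(**conv(Outcome, out_d)),
                rad_report=RadReport(**conv(RadReport, rad_d)) if rad_d else None,
                path_report=PathReport(**conv(PathReport, path_d)) if path_d else None,
                pathology_assets=path_assets or None,
                radiology_assets=rad_assets or None,
            )
            rec.validate()
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# outcome labelling and splitting

def responder_threshold(cohort: str) -> float:
    """PFS threshold (months) separating responders from non-responders."""
    try:
        return PFS_THRESHOLD_MONTHS[cohort]
    except KeyError:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")


def label_responder(outcome: Outcome, cohort: str) -> str:
    """Classify an outcome as ``responder`` / ``non_responder`` / ``excluded``.

    Responders achieved RECIST CR, PR or SD *and* PFS strictly exceeding the
    cohort threshold (8 months for anti-HER2 therapy, 10 for the combined
    immunotherapy cohort). PD is always a non-responder. A CR/PR/SD patient
    whose progression was observed at or before the threshold is a
    non-responder; one censored before exceeding it is excluded from response
    analysis (but kept for survival analysis).
    """
    threshold = responder_threshold(cohort)
    if outcome.recist not in RECIST:
        raise ValueError(f"unknown RECIST code {outcome.recist!r}")
    if outcome.recist == "PD":
        return "non_responder"
    if outcome.pfs_months > threshold:
        return "responder"
    if outcome.pfs_event:
        return "non_responder"
    return "excluded"


def split_cohort(records: Sequence[PatientRecord], val_fraction: float,
                 seed: int) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Random, reproducible train/validation partition.

    The validation set has ``round(n * val_fraction)`` patients; the split is
    disjoint and exhaustive and depends only on ``seed`` and the record order.
    """
    import numpy as np

    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    n_val = int(round(n * val_fraction))
    n_val = min(max(n_val, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [records[i] for i in range(n) if i not in val_idx]
    val = [records[i] for i in range(n) if i in val_idx]
    return train, val
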