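"""Unified plain-text plate-data format: reading, writing, validation.

The dialect is a long-format CSV (one row per well x endpoint) preceded by a
``# key: value`` metadata header block.  It is deliberately strict: decimal
separator is ``.`` only, spreadsheet date artifacts are rejected rather than
coerced, and annotation flags (lab_error, outlier, below_detection) travel
with the data instead of rows being silently dropped.  The validator reports
machine-readable error codes so that curation can be automated.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chem import CompoundRegistry
from .errors import SchemaError

ROLES = frozenset({
    "treatment", "solvent_control", "positive_control",
    "negative_control_compound", "blank",
})
FLAGS = frozenset({"lab_error", "outlier", "below_detection"})

MANDATORY_METADATA = ("test_method_id", "lab_id", "solvent", "exposure_h")
METADATA_KEYS = (
    "test_method_id", "test_method_version", "lab_id", "solvent",
    "solvent_final_percent", "exposure_h", "method_description_ref",
    "compound_batch", "seed_or_run_id",
    "series_start_neglog", "series_end_neglog", "series_step_log",
)

COLUMNS = (
    "plate_id", "well", "role", "compound_id", "conc_neglog_molar",
    "endpoint_id", "raw_value", "replicate", "flags", "timestamp",
)

_WELL_RE = re.compile(r"^[A-P]([1-9]|1[0-9]|2[0-4])$")
_NUMERIC_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
# "Jun-05", "05-Jun", "5-Jun-2005" style spreadsheet date corruptions
_DATE_ARTIFACT_RE = re.compile(
    r"^\d{0,4}-?(Jan|Feb|Mar|Apr|May|Jun|Jul|Aug|Sep|Oct|Nov|Dec)[a-z]*-?\d{0,4}$",
    re.IGNORECASE,
)


@dataclass
class MetadataBlock:
    """Assay-level metadata written as the ``#`` header of a plate file."""

    test_method_id: str
    lab_id: str
    solvent: str
    exposure_h: float
    test_method_version: str = ""
    solvent_final_percent: float | None = None
    method_description_ref: str = ""
    compound_batch: str = ""
    seed_or_run_id: str = ""
    series_start_neglog: float | None = None
    series_end_neglog: float | None = None
    series_step_log: float | None = None

    def content_fields(self) -> tuple:
        """Fields compared when looking for copy-pasted metadata blocks."""
        return (self.test_method_id, self.test_method_version, self.lab_id,
                self.solvent, self.solvent_final_percent, self.exposure_h,
                self.method_description_ref, self.compound_batch)


@dataclass
class WellMeasurement:
    plate_id: str
    well: str
    role: str
    endpoint_id: str
    raw_value: float | None
    compound_id: str = ""
    conc_neglog_molar: float | None = None
    replicate: int = 1
    flags: frozenset[str] = frozenset()
    timestamp: str = ""
    # verbatim text of cells that failed numeric parsing (kept for lossless
    # round trips; surfaced by the validator, never coerced)
    conc_text: str | None = None
    raw_text: str | None = None

    def key(self) -> tuple[str, str, str]:
        return (self.plate_id, self.well, self.endpoint_id)


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning" | "note"
    code: str
    location: str
    message: str

    def to_dict(self) -> dict:
        return {"severity": self.severity, "code": self.code,
                "location": self.location, "message": self.message}


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, severity: str, code: str, location: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, code, location, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def conformant(self) -> bool:
        return not self.errors

    def to_json_obj(self) -> list[dict]:
        return [i.to_dict() for i in self.issues]


@dataclass
class PlateDataset:
    measurements: list[WellMeasurement]
    metadata: MetadataBlock

    def plates(self) -> list[str]:
        return sorted({m.plate_id for m in self.measurements})

    def endpoints(self) -> list[str]:
        return sorted({m.endpoint_id for m in self.measurements})

    def wells(self, plate_id: str | None = None, endpoint_id: str | None = None,
              role: str | None = None) -> list[WellMeasurement]:
        out = self.measurements
        if plate_id is not None:
            out = [m for m in out if m.plate_id == plate_id]
        if endpoint_id is not None:
            out = [m for m in out if m.endpoint_id == endpoint_id]
        if role is not None:
            out = [m for m in out if m.role == role]
        return out


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, ".12g")
    return str(value)


def _parse_numeric_cell(text: str):
    """Return (value, verbatim_text). Non-numeric cells keep their text."""
    t = text.strip()
    if t == "":
        return None, None
    if _NUMERIC_RE.match(t):
        return float(t), None
    return None, t


def read_dataset(path: str | Path) -> PlateDataset:
    """Parse a plate file.  Structural problems (missing columns, missing
    mandatory metadata, bad roles/wells) raise :class:`SchemaError`; cell-level
    numeric anomalies are preserved verbatim for :func:`validate_dataset`."""
    path = Path(path)
    meta_raw: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            kv = line.lstrip("#").strip()
            if ":" in kv:
                k, v = kv.split(":", 1)
                meta_raw[k.strip()] = v.strip()
        else:
            body_start = i
            break
    else:
        body_start = len(lines)

    for key in MANDATORY_METADATA:
        if key not in meta_raw or meta_raw[key] == "":
            raise SchemaError(f"missing mandatory metadata key {key!r}", location=str(path))
    unknown = set(meta_raw) - set(METADATA_KEYS)
    if unknown:
        raise SchemaError(f"unknown metadata keys: {sorted(unknown)}", location=str(path))

    def meta_float(key: str) -> float | None:
        v = meta_raw.get(key, "")
        if v == "":
            return None
        if not _NUMERIC_RE.match(v):
            raise SchemaError(f"metadata {key} is not numeric: {v!r}", location=str(path))
        return float(v)

    metadata = MetadataBlock(
        test_method_id=meta_raw["test_method_id"],
        test_method_version=meta_raw.get("test_method_version", ""),
        lab_id=meta_raw["lab_id"],
        solvent=meta_raw["solvent"],
        solvent_final_percent=meta_float("solvent_final_percent"),
        exposure_h=meta_float("exposure_h"),
        method_description_ref=meta_raw.get("method_description_ref", ""),
        compound_batch=meta_raw.get("compound_batch", ""),
        seed_or_run_id=meta_raw.get("seed_or_run_id", ""),
        series_start_neglog=meta_float("series_start_neglog"),
        series_end_neglog=meta_float("series_end_neglog"),
        series_step_log=meta_float("series_step_log"),
    )

    body = lines[body_start:]
    if not body or body[0].strip() == "":
        return PlateDataset([], metadata)
    parsed = list(csv.reader(body))
    header = parsed[0]
    if tuple(header) != COLUMNS:
        raise SchemaError(f"unexpected columns {header}; expected {list(COLUMNS)}",
                          location=str(path))
    measurements: list[WellMeasurement] = []
    for lineno, cells in enumerate(parsed[1:], start=body_start + 2):
        if not cells:
            continue
        if len(cells) != len(COLUMNS):
            raise SchemaError(f"expected {len(COLUMNS)} cells, got {len(cells)}",
                              location=f"{path}:{lineno}")
        row = dict(zip(COLUMNS, cells))
        if row["role"] not in ROLES:
            raise SchemaError(f"unknown role {row['role']!r}", location=f"{path}:{lineno}")
        if not _WELL_RE.match(row["well"]):
            raise SchemaError(f"bad well coordinate {row['well']!r}",
                              location=f"{path}:{lineno}")
        flags = frozenset(f for f in row["flags"].split(";") if f)
        bad = flags - FLAGS
        if bad:
            raise SchemaError(f"unknown flags {sorted(bad)}", location=f"{path}:{lineno}")
        conc, conc_text = _parse_numeric_cell(row["conc_neglog_molar"])
        raw, raw_text = _parse_numeric_cell(row["raw_value"])
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise SchemaError(f"replicate must be an integer, got {row['replicate']!r}",
                              location=f"{path}:{lineno}") from None
        measurements.append(WellMeasurement(
            plate_id=row["plate_id"], well=row["well"], role=row["role"],
            compound_id=row["compound_id"], conc_neglog_molar=conc,
            endpoint_id=row["endpoint_id"], raw_value=raw, replicate=replicate,
            flags=flags, timestamp=row["timestamp"],
            conc_text=conc_text, raw_text=raw_text,
        ))
    return PlateDataset(measurements, metadata)


def write_dataset(dataset: PlateDataset, path: str | Path) -> None:
    """Serialize with deterministic row and column order; two writes of the
    same dataset are byte-identical.  Flagged rows are written, never dropped."""
    md = dataset.metadata
    meta_pairs = [
        ("test_method_id", md.test_method_id),
        ("test_method_version", md.test_method_version),
        ("lab_id", md.lab_id),
        ("solvent", md.solvent),
        ("solvent_final_percent", md.solvent_final_percent),
        ("exposure_h", md.exposure_h),
        ("method_description_ref", md.method_description_ref),
        ("compound_batch", md.compound_batch),
        ("seed_or_run_id", md.seed_or_run_id),
        ("series_start_neglog", md.series_start_neglog),
        ("series_end_neglog", md.series_end_neglog),
        ("series_step_log", md.series_step_log),
    ]
    buf = io.StringIO()
    for k, v in meta_pairs:
        if _fmt(v) != "":
            buf.write(f"# {k}: {_fmt(v)}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(COLUMNS)
    rows = sorted(dataset.measurements,
                  key=lambda m: (m.plate_id, m.endpoint_id, m.well[0],
                                 int(m.well[1:]), m.replicate))
    for m in rows:
        conc_cell = m.conc_text if m.conc_text is not None else _fmt(m.conc_neglog_molar)
        raw_cell = m.raw_text if m.raw_text is not None else _fmt(m.raw_value)
        writer.writerow([
            m.plate_id, m.well, m.role, m.compound_id, conc_cell,
            m.endpoint_id, raw_cell, str(m.replicate),
            ";".join(sorted(m.flags)), m.timestamp,
        ])
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _declared_series(md: MetadataBlock) -> list[float] | None:
    if None in (md.series_start_neglog, md.series_end_neglog, md.series_step_log):
        return None
    n = int(math.floor((md.series_end_neglog - md.series_start_neglog)
                       / md.series_step_log + 1e-9)) + 1
    return [md.series_start_neglog + i * md.series_step_log for i in range(n)]


def validate_dataset(dataset: PlateDataset,
                     registry: CompoundRegistry | None = None) -> ValidationReport:
    """Run all single-dataset conformance checks.

    Error codes: UNRESOLVED_COMPOUND, MISSING_CONTROL_LINK, DUPLICATE_WELL,
    CONC_OUTSIDE_SERIES, SPREADSHEET_DATE_ARTIFACT, LOCALE_COMMA,
    NON_NUMERIC_CELL, MISSING_TREATMENT_FIELDS.  Notes: DMSO_PERCENT_UNUSUAL.
    A report with any error-severity issue marks the dataset non-conformant.
    """
    report = ValidationReport()
    md = dataset.metadata
    if (md.solvent.upper() == "DMSO" and md.solvent_final_percent is not None
            and md.solvent_final_percent <= 1 and md.solvent_final_percent != 0.1):
        report.add("note", "DMSO_PERCENT_UNUSUAL", "metadata",
                   f"final DMSO {md.solvent_final_percent}% differs from the 0.1% convention")

    series = _declared_series(md)
    seen: dict[tuple, str] = {}
    plates_with_treatment: set[tuple[str, str]] = set()
    plates_with_solvent: set[tuple[str, str]] = set()

    for idx, m in enumerate(dataset.measurements):
        loc = f"{m.plate_id}/{m.well}/{m.endpoint_id}"
        for text, col in ((m.conc_text, "conc_neglog_molar"), (m.raw_text, "raw_value")):
            if text is None:
                continue
            if _DATE_ARTIFACT_RE.match(text):
                report.add("error", "SPREADSHEET_DATE_ARTIFACT", f"{loc}:{col}",
                           f"cell {text!r} looks like a spreadsheet date conversion")
            elif re.match(r"^[+-]?\d+,\d+$", text):
                report.add("error", "LOCALE_COMMA", f"{loc}:{col}",
                           f"cell {text!r} uses a decimal comma")
            else:
                report.add("error", "NON_NUMERIC_CELL", f"{loc}:{col}",
                           f"cell {text!r} is not a number")
        key = m.key()
        if key in seen:
            report.add("error", "DUPLICATE_WELL", loc,
                       "duplicate (plate, well, endpoint) row")
        seen[key] = loc
        if m.role == "treatment":
            plates_with_treatment.add((m.plate_id, m.endpoint_id))
            if not m.compound_id or (m.conc_neglog_molar is None and m.conc_text is None):
                report.add("error", "MISSING_TREATMENT_FIELDS", loc,
                           "treatment wells need compound_id and concentration")
        elif m.role == "solvent_control":
            plates_with_solvent.add((m.plate_id, m.endpoint_id))
        if (registry is not None and m.compound_id
                and m.compound_id not in registry):
            report.add("error", "UNRESOLVED_COMPOUND", loc,
                       f"compound_id {m.compound_id!r} not in registry")
        if (series is not None and m.role == "treatment"
                and m.conc_neglog_molar is not None
                and not any(abs(m.conc_neglog_molar - s) < 1e-6 for s in series)):
            report.add("error", "CONC_OUTSIDE_SERIES", loc,
                       f"concentration {m.conc_neglog_molar} not on the declared series")

    for plate_ep in sorted(plates_with_treatment - plates_with_solvent):
        report.add("error", "MISSING_CONTROL_LINK", "/".join(plate_ep),
                   "plate has treatment wells but no solvent_control wells for this endpoint")
    return report


def validate_datasets(datasets: list[PlateDataset],
                      registry: CompoundRegistry | None = None) -> ValidationReport:
    """Validate several datasets together, adding cross-dataset checks.

    Identical metadata content under distinct run ids is flagged
    (METADATA_COPY_PASTE warning): copy-pasted metadata blocks that were never
    adapted to the actual experiment are a classic curation failure.
    """
    report = ValidationReport()
    for ds in datasets:
        report.issues.extend(validate_dataset(ds, registry).issues)
    by_content: dict[tuple, set[str]] = {}
    for ds in datasets:
        run = ds.metadata.seed_or_run_id
        by_content.setdefault(ds.metadata.content_fields(), set()).add(run)
    for content, runs in by_content.items():
        if len(runs) > 1:
            report.add("warning", "METADATA_COPY_PASTE",
                       f"runs {sorted(runs)}",
                       "identical metadata blocks across distinct run ids")
    return report
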