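"""Study tables, calibrant sets and bundled fixtures.

The package ships the 120-sample method-comparison dataset (20 control and
100 warfarin-therapy subjects measured on a point-of-care coagulometer and
three central-laboratory analyzers) together with the published frequency
distribution of those INR results in five clinical bins.  All tables are
plain CSV with a mandatory header; missing measurements are written as empty
cells and accepted as either empty cells or the literal token ``NA``.

Sample-table layout: ``sample_id, cohort`` followed, per method, by
``<method_id>_pt_sec`` and ``<method_id>_inr`` and an optional
``<method_id>_inr_corrected``.  Calibrant-table layout: ``method_id,
calibrant_id, inr_certified, pt_sec_rep1, pt_sec_rep2, ...``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Measurement",
    "SampleRecord",
    "MethodProfile",
    "Calibrant",
    "CalibrantSet",
    "STUDY_PROFILES",
    "STUDY_METHOD_IDS",
    "read_sample_table",
    "write_sample_table",
    "records_to_frame",
    "frame_to_records",
    "load_study_samples",
    "load_study_frame",
    "load_frequency_table",
    "read_calibrant_table",
    "write_calibrant_table",
    "flag_pt_inr_outliers",
    "write_report",
    "read_report",
]

_MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class Measurement:
    """One analyzer's result for one sample: PT in seconds, the INR the
    instrument reported, and (once harmonized) the line-corrected INR."""

    pt_seconds: float
    inr_reported: float
    inr_corrected: float | None = None

    def __post_init__(self) -> None:
        if not (self.pt_seconds > 0 and self.inr_reported > 0):
            raise ValidationError(
                f"PT and INR must be positive, got PT={self.pt_seconds}, "
                f"INR={self.inr_reported}"
            )
        if self.inr_corrected is not None and not self.inr_corrected > 0:
            raise ValidationError(f"corrected INR must be positive, got {self.inr_corrected}")


@dataclass
class SampleRecord:
    """One subject's measurements across all study methods.

    ``measurements`` maps every method id declared in the manifest to either a
    :class:`Measurement` or ``None`` (explicitly missing).
    """

    sample_id: str
    cohort: str  # "control" | "warfarin"
    measurements: dict[str, Measurement | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in ("control", "warfarin"):
            raise ValidationError(
                f"sample {self.sample_id}: cohort must be 'control' or 'warfarin', "
                f"got {self.cohort!r}"
            )


@dataclass(frozen=True)
class MethodProfile:
    """Identity and measurement model of one analyzer.

    ``isi`` is the International Sensitivity Index of its thromboplastin and
    ``mnpt`` the mean normal PT (s); together they define the conventional
    INR = (PT/MNPT)**ISI.  A whole-blood point-of-care method cannot be
    calibrated against plasma standards, so ``correctable`` must be False
    exactly when ``matrix`` is ``"whole_blood"``.
    """

    method_id: str
    thromboplastin: str  # "rabbit_brain" | "recombinant_human"
    isi: float
    matrix: str = "citrated_plasma"  # | "whole_blood"
    mnpt: float | None = None
    correctable: bool = True

    def __post_init__(self) -> None:
        if self.thromboplastin not in ("rabbit_brain", "recombinant_human"):
            raise ValidationError(f"unknown thromboplastin {self.thromboplastin!r}")
        if self.matrix not in ("whole_blood", "citrated_plasma"):
            raise ValidationError(f"unknown sample matrix {self.matrix!r}")
        if not 0.5 < self.isi < 3.0:
            raise ValidationError(f"ISI {self.isi} outside the plausible (0.5, 3.0) range")
        if self.mnpt is not None and not self.mnpt > 0:
            raise ValidationError(f"MNPT must be positive, got {self.mnpt}")
        if self.correctable == (self.matrix == "whole_blood"):
            raise ValidationError(
                "correctable must be False exactly for whole-blood methods "
                f"({self.method_id}: matrix={self.matrix}, correctable={self.correctable})"
            )

    def with_mnpt(self, mnpt: float) -> "MethodProfile":
        return replace(self, mnpt=mnpt)


@dataclass(frozen=True)
class Calibrant:
    """One certified plasma: assigned INR and replicate PT observations."""

    calibrant_id: str
    inr_certified: float
    pt_observed_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.inr_certified > 0:
            raise ValidationError(f"certified INR must be positive, got {self.inr_certified}")
        if len(self.pt_observed_replicates) < 1:
            raise ValidationError(f"calibrant {self.calibrant_id} has no PT replicates")
        if any(pt <= 0 for pt in self.pt_observed_replicates):
            raise ValidationError(f"calibrant {self.calibrant_id} has a non-positive PT")


@dataclass
class CalibrantSet:
    """The certified calibrant plasmas run on one analyzer."""

    method_id: str
    calibrants: list[Calibrant]

    def __post_init__(self) -> None:
        if len(self.calibrants) < 3:
            raise ValidationError(
                f"calibrant set for {self.method_id} needs >= 3 calibrants, "
                f"got {len(self.calibrants)}"
            )
        certified = [c.inr_certified for c in self.calibrants]
        if len(set(certified)) < 2:
            raise ValidationError("certified INR values are all equal")

    def __len__(self) -> int:
        return len(self.calibrants)


#: The four analyzers of the bundled comparison study.  The point-of-care
#: device reads whole blood and therefore cannot be harmonized against
#: plasma-based calibrants; the three central-laboratory analyzers can.
STUDY_PROFILES: tuple[MethodProfile, ...] = (
    MethodProfile("coaguchek_xs", "recombinant_human", 1.01,
                  matrix="whole_blood", correctable=False),
    MethodProfile("utmb_stago", "rabbit_brain", 1.25),
    MethodProfile("arup_stago", "rabbit_brain", 1.28),
    MethodProfile("bcs_xp", "recombinant_human", 1.02),
)

STUDY_METHOD_IDS: tuple[str, ...] = tuple(p.method_id for p in STUDY_PROFILES)


def _method_ids(manifest: Iterable[str | MethodProfile]) -> list[str]:
    return [m.method_id if isinstance(m, MethodProfile) else str(m) for m in manifest]


def _infer_cohort(sample_id: str) -> str:
    if sample_id.endswith("N"):
        return "control"
    if sample_id.endswith("A"):
        return "warfarin"
    raise ValidationError(
        f"cannot infer cohort for sample {sample_id!r}: id does not end in N or A "
        "and no cohort column is present"
    )


def read_sample_table(
    path: str | Path, manifest: Sequence[str | MethodProfile]
) -> list[SampleRecord]:
    """Read a comma-delimited sample table into records, preserving row order.

    Empty cells and the token ``NA`` become missing entries.  The header must
    contain ``sample_id`` and, for every method in ``manifest``, the
    ``<method_id>_pt_sec`` and ``<method_id>_inr`` columns.
    """
    ids = _method_ids(manifest)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["sample_id"] + [f"{m}_{suf}" for m in ids for suf in ("pt_sec", "inr")]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"sample table is missing required column {col!r}")

    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        cohort = row.get("cohort", "")
        cohort = cohort.strip() if isinstance(cohort, str) else ""
        if not cohort:
            cohort = _infer_cohort(sid)
        meas: dict[str, Measurement | None] = {}
        for m in ids:
            pt = _parse_cell(row[f"{m}_pt_sec"], sid, f"{m}_pt_sec")
            inr = _parse_cell(row[f"{m}_inr"], sid, f"{m}_inr")
            corr_col = f"{m}_inr_corrected"
            corr = (
                _parse_cell(row[corr_col], sid, corr_col) if corr_col in df.columns else None
            )
            if (pt is None) != (inr is None):
                raise ValidationError(
                    f"sample {sid}: method {m} has PT or INR but not both"
                )
            meas[m] = None if pt is None else Measurement(pt, inr, corr)
        records.append(SampleRecord(sid, cohort, meas))
    return records


def _parse_cell(raw: str, sample_id: str, column: str) -> float | None:
    token = raw.strip()
    if token in _MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(
            f"sample {sample_id}: cannot parse {column}={token!r} as a number"
        ) from exc
    if value <= 0:
        raise ValidationError(
            f"sample {sample_id}: {column} must be positive, got {value}"
        )
    return value


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Wide DataFrame view of a record list (one row per sample)."""
    if not records:
        return pd.DataFrame(columns=["sample_id", "cohort"])
    ids = list(records[0].measurements)
    rows = []
    for rec in records:
        row: dict[str, object] = {"sample_id": rec.sample_id, "cohort": rec.cohort}
        for m in ids:
            meas = rec.measurements.get(m)
            row[f"{m}_pt_sec"] = meas.pt_seconds if meas else np.nan
            row[f"{m}_inr"] = meas.inr_reported if meas else np.nan
            row[f"{m}_inr_corrected"] = (
                meas.inr_corrected if meas and meas.inr_corrected is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, manifest: Sequence[str | MethodProfile]) -> list[SampleRecord]:
    """Inverse of :func:`records_to_frame`."""
    ids = _method_ids(manifest)
    records = []
    for _, row in df.iterrows():
        meas: dict[str, Measurement | None] = {}
        for m in ids:
            pt, inr = row.get(f"{m}_pt_sec"), row.get(f"{m}_inr")
            if pd.isna(pt) or pd.isna(inr):
                meas[m] = None
                continue
            corr = row.get(f"{m}_inr_corrected", np.nan)
            meas[m] = Measurement(float(pt), float(inr), None if pd.isna(corr) else float(corr))
        cohort = row.get("cohort")
        if not isinstance(cohort, str) or not cohort:
            cohort = _infer_cohort(str(row["sample_id"]))
        records.append(SampleRecord(str(row["sample_id"]), cohort, meas))
    return records


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records as CSV; missing entries become empty cells."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def load_study_frame() -> pd.DataFrame:
    """The bundled 120-sample comparison dataset as a DataFrame."""
    with resources.as_file(resources.files("ptinrline.data") / "study_samples.csv") as p:
        return pd.read_csv(p)


def load_study_samples() -> list[SampleRecord]:
    """The bundled 120-sample comparison dataset (20 control, 100 warfarin;
    one central-laboratory measurement is missing)."""
    with resources.as_file(resources.files("ptinrline.data") / "study_samples.csv") as p:
        return read_sample_table(p, STUDY_METHOD_IDS)


def load_frequency_table(phase: str):
    """The published methods-by-INR-category frequency table.

    ``phase`` is ``"before"`` or ``"after"`` (harmonization).  Returned as a
    :class:`~ptinrline.stats.ContingencyTable`.  Note the after-phase counts
    are shipped exactly as published; they are not reproducible by re-binning
    the bundled corrected columns (see the methods note).
    """
    from .stats import ContingencyTable  # local import avoids a cycle at import time

    if phase not in ("before", "after"):
        raise ValidationError(f"phase must be 'before' or 'after', got {phase!r}")
    with resources.as_file(resources.files("ptinrline.data") / "frequency_counts.csv") as p:
        df = pd.read_csv(p)
    df = df[df["phase"] == phase].set_index("method_id")
    counts = df.drop(columns="phase").to_numpy(dtype=int)
    return ContingencyTable(
        row_labels=tuple(df.index),
        col_labels=tuple(df.columns[1:]),
        counts=counts,
    )


def read_calibrant_table(path: str | Path) -> dict[str, CalibrantSet]:
    """Read calibrant CSV into one CalibrantSet per method."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("method_id", "calibrant_id", "inr_certified"):
        if col not in df.columns:
            raise FormatError(f"calibrant table is missing required column {col!r}")
    rep_cols = [c for c in df.columns if c.startswith("pt_sec_rep")]
    if not rep_cols:
        raise FormatError("calibrant table has no pt_sec_rep* columns")
    sets: dict[str, list[Calibrant]] = {}
    for _, row in df.iterrows():
        cid = row["calibrant_id"]
        reps = tuple(
            float(row[c]) for c in rep_cols if row[c].strip() not in _MISSING_TOKENS
        )
        cal = Calibrant(cid, float(row["inr_certified"]), reps)
        sets.setdefault(row["method_id"], []).append(cal)
    return {m: CalibrantSet(m, cals) for m, cals in sets.items()}


def write_calibrant_table(sets: Mapping[str, CalibrantSet], path: str | Path) -> None:
    n_rep = max(
        len(c.pt_observed_replicates) for s in sets.values() for c in s.calibrants
    )
    rows = []
    for s in sets.values():
        for c in s.calibrants:
            row = {
                "method_id": s.method_id,
                "calibrant_id": c.calibrant_id,
                "inr_certified": c.inr_certified,
            }
            for i in range(n_rep):
                row[f"pt_sec_rep{i + 1}"] = (
                    c.pt_observed_replicates[i] if i < len(c.pt_observed_replicates) else ""
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def flag_pt_inr_outliers(
    df: pd.DataFrame, method_id: str, max_ln_residual: float = 0.2
) -> list[str]:
    """Flag samples whose reported INR is inconsistent with their PT.

    On one analyzer ln(PT) is, to instrument rounding, an affine function of
    ln(reported INR); reporting granularity (INR to 0.1, PT to 0.1 s)
    perturbs the residual by a few percent at most, so a residual above
    ``max_ln_residual`` (default 0.2, i.e. a PT more than ~20% off the
    analyzer's own PT-INR relationship) marks a transcription error.  The
    bundled dataset contains one: a sample whose PT of 42.9 s sits beside a
    reported INR of 2.70.
    """
    sub = df[[f"{method_id}_pt_sec", f"{method_id}_inr", "sample_id"]].dropna()
    x = np.log(sub[f"{method_id}_inr"].to_numpy(float))
    y = np.log(sub[f"{method_id}_pt_sec"].to_numpy(float))
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    flagged = np.abs(resid - np.median(resid)) > max_ln_residual
    return sub.loc[flagged, "sample_id"].tolist()


def write_report(report, path: str | Path) -> None:
    """Serialize an AgreementReport to JSON, plus one CSV per contingency table."""
    path = Path(path)
    doc = report.to_dict()
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    for phase, block in doc.get("phases", {}).items():
        tab = block.get("contingency")
        if tab is None:
            continue
        out = pd.DataFrame(
            tab["counts"], index=tab["row_labels"], columns=tab["col_labels"]
        )
        out.index.name = "method_id"
        out.to_csv(path.with_name(f"{path.stem}_contingency_{phase}.csv"))


def read_report(path: str | Path):
    """Inverse of :func:`write_report` (JSON part)."""
    from .pipeline import AgreementReport

    return AgreementReport.from_dict(json.loads(Path(path).read_text()))
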