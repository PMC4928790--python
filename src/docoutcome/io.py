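"""Readers and writers for cohort and longitudinal-assessment tables.

Two delimited-text schemas are used throughout:

* the *cohort table* — one row per patient with the demographic summary
  columns (age, initial diagnosis, lesion-localisation string, aetiology,
  assessment delays and counts, rehabilitation duration, discharge outcome
  and the two secondary endpoints);
* the *assessment table* — long format, one row per CRS-R assessment with
  the five subscale scores, optional arousal, and optional MBT item columns.

A verbatim transcription of the study cohort's demographics ships as the
packaged fixture ``table3_cohort.csv``.  One raw aetiology cell contains a
printing typo ("TBI (PO"); the normalised category column corrects it while
the ``aetiology_raw`` column preserves the original text.
"""

from __future__ import annotations

import csv
import io as _stdio
import re
import sys
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .cohort import (
    CRSRAssessment,
    Diagnosis,
    MBTAssessment,
    Outcome,
    PatientRecord,
    SubscaleProfile,
    SUBSCALES,
)

__all__ = [
    "SchemaError",
    "LesionParseError",
    "COHORT_COLUMNS",
    "ASSESSMENT_COLUMNS",
    "read_cohort",
    "read_assessments",
    "load_fixture_cohort",
    "load_aetiology_map",
    "parse_lesions",
    "lesion_regions",
    "patients_from_tables",
    "write_tables",
]


class SchemaError(ValueError):
    """A delimited file does not match the expected schema."""


class LesionParseError(ValueError):
    """A lesion-localisation token is not recognised."""


COHORT_COLUMNS = [
    "patient_no",
    "age",
    "diagnosis",
    "lesions",
    "aetiology",
    "delay_first_crsr",
    "n_crsr",
    "delay_last_crsr",
    "rehab_duration",
    "outcome",
    "return_home",
    "walk",
]

ASSESSMENT_COLUMNS = ["patient_no", "day"] + list(SUBSCALES)
MBT_COLUMNS = [f"mbt_{i}" for i in range(1, 11)]

_VALID_OUTCOMES = {"Non DOC", "MCS", "UWS"}
_VALID_YNA = {"Yes", "No", "NA"}

#: Anatomical tokens of the lesion-localisation shorthand.  F/T/P/O/BG take
#: a laterality prefix (r/l/b); Mes, Pons and DAI appear unprefixed.
_LATERAL_REGIONS = {"F", "T", "P", "O", "BG"}
_UNPREFIXED_REGIONS = {"Mes", "Pons", "DAI"}
_LATERALITY = {"r": "right", "l": "left", "b": "bilateral"}

#: Grouping of tokens into the tally categories used for group descriptives.
#: "Midbrain" covers both mesencephalic and pontine lesions (the cohort
#: table's brainstem tokens).
REGION_GROUPS = {
    "Frontal": {"F"},
    "Temporal": {"T"},
    "Parietal": {"P"},
    "Occipital": {"O"},
    "Basal Ganglia": {"BG"},
    "Midbrain": {"Mes", "Pons"},
    "Diffuse axonal injury": {"DAI"},
}


def _read_delimited(path_or_buf) -> pd.DataFrame:
    """Read a comma- or tab-separated file with a header row (sniffed)."""
    if path_or_buf == "-":
        text = sys.stdin.read()
    elif isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text(encoding="utf-8")
    else:
        text = path_or_buf.read()
    if not text.strip():
        raise SchemaError("empty input: no header row found")
    first_line = text.splitlines()[0]
    sep = "\t" if "\t" in first_line else ","
    return pd.read_csv(_stdio.StringIO(text), sep=sep, dtype=str, keep_default_na=False)


def read_cohort(path_or_buf) -> pd.DataFrame:
    """Read a cohort table; returns a typed :class:`pandas.DataFrame`.

    Accepts a path, an open text buffer, or ``"-"`` for stdin.  Raises
    :class:`SchemaError` when required columns are missing and a row-level
    error (with the offending line) for invalid categorical values.
    """
    df = _read_delimited(path_or_buf)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"cohort table is missing columns {missing}; expected header "
            f"{COHORT_COLUMNS}"
        )
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["diagnosis"] not in {"UWS", "MCS"}:
            raise SchemaError(f"line {line}: diagnosis {row['diagnosis']!r} not in UWS/MCS")
        if row["outcome"] not in _VALID_OUTCOMES:
            raise SchemaError(f"line {line}: outcome {row['outcome']!r} not in {_VALID_OUTCOMES}")
        for col in ("return_home", "walk"):
            if row[col] not in _VALID_YNA:
                raise SchemaError(f"line {line}: {col} {row[col]!r} not in {_VALID_YNA}")
    out = df.copy()
    for col in ("age", "delay_first_crsr", "delay_last_crsr", "rehab_duration"):
        out[col] = pd.to_numeric(out[col])
    out["n_crsr"] = pd.to_numeric(out["n_crsr"]).astype(int)
    out["patient_no"] = out["patient_no"].astype(str)
    return out


def read_assessments(path_or_buf) -> pd.DataFrame:
    """Read a long-format assessment table (one row per CRS-R assessment)."""
    df = _read_delimited(path_or_buf)
    missing = [c for c in ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"assessment table is missing columns {missing}; expected at least "
            f"{ASSESSMENT_COLUMNS}"
        )
    have_mbt = [c for c in MBT_COLUMNS if c in df.columns]
    if have_mbt and len(have_mbt) != 10:
        raise SchemaError("MBT columns must be all present or all absent")
    out = df.copy()
    out["patient_no"] = out["patient_no"].astype(str)
    for col in ["day"] + list(SUBSCALES):
        out[col] = pd.to_numeric(out[col]).astype(int)
    if "arousal" in out.columns:
        out["arousal"] = pd.to_numeric(out["arousal"].replace("", "-1")).astype(int)
    for col in have_mbt:
        # blank cells mean "no MBT administered at this visit"
        out[col] = pd.to_numeric(out[col].replace("", "-1")).astype(int)
    dup = out.duplicated(subset=["patient_no", "day"])
    if dup.any():
        raise SchemaError(f"duplicate (patient, day) rows at index {list(out.index[dup])}")
    return out


def load_fixture_cohort() -> pd.DataFrame:
    """The packaged verbatim transcription of the study's per-patient table."""
    with resources.files("docoutcome.data").joinpath("table3_cohort.csv").open("r") as fh:
        return read_cohort(fh)


def load_aetiology_map() -> dict[str, str]:
    """Editable lookup from raw aetiology strings to tally categories."""
    with resources.files("docoutcome.data").joinpath("aetiology_map.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype=str)
    return dict(zip(df["raw"], df["category"]))


_TOKEN_RE = re.compile(r"^(?:(?P<lat>[rlb])(?P<reg>F|T|P|O|BG)|(?P<plain>Mes|Pons|DAI))$")


def parse_lesions(text: str) -> frozenset[tuple[str, str]]:
    """Parse a lesion-localisation string into (region, laterality) pairs.

    ``"bF, rT"`` maps to ``{("F", "bilateral"), ("T", "right")}``; tokens
    without a laterality prefix (Mes, Pons, DAI) carry laterality ``"none"``.
    Unknown tokens raise :class:`LesionParseError` naming the token.
    """
    sites: set[tuple[str, str]] = set()
    for token in (t.strip() for t in text.split(",")):
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise LesionParseError(f"unrecognised lesion token {token!r} in {text!r}")
        if m.group("plain"):
            sites.add((m.group("plain"), "none"))
        else:
            sites.add((m.group("reg"), _LATERALITY[m.group("lat")]))
    return frozenset(sites)


def lesion_regions(sites: Iterable[tuple[str, str]]) -> set[str]:
    """Collapse (region, laterality) sites onto the tally categories."""
    regions = {r for r, _ in sites}
    return {name for name, tokens in REGION_GROUPS.items() if regions & tokens}


def _yna(value: str) -> Optional[bool]:
    return {"Yes": True, "No": False, "NA": None}[value]


def patients_from_tables(
    cohort: pd.DataFrame,
    assessments: Optional[pd.DataFrame] = None,
) -> list[PatientRecord]:
    """Assemble :class:`PatientRecord` objects from the two table schemas."""
    aet_map = load_aetiology_map()
    by_patient: dict[str, pd.DataFrame] = {}
    if assessments is not None:
        by_patient = {pid: grp.sort_values("day") for pid, grp in assessments.groupby("patient_no")}
    records = []
    for _, row in cohort.iterrows():
        pid = str(row["patient_no"])
        crsr: list[CRSRAssessment] = []
        mbt: list[MBTAssessment] = []
        if pid in by_patient:
            grp = by_patient[pid]

            def _cell(row, col):
                # blank / missing cells encode "not recorded"
                if col not in row:
                    return None
                value = row[col]
                if value == "" or value != value:
                    return None
                value = int(value)
                return value if value >= 0 else None

            for _, arow in grp.iterrows():
                profile = SubscaleProfile(
                    *(int(arow[s]) for s in SUBSCALES),
                    arousal=_cell(arow, "arousal"),
                )
                crsr.append(CRSRAssessment(profile=profile, day=int(arow["day"])))
                if _cell(arow, "mbt_1") is not None:
                    items = tuple(int(arow[c]) for c in MBT_COLUMNS)
                    mbt.append(MBTAssessment(items=items, day=int(arow["day"])))
        raw_aet = str(row.get("aetiology_raw", row["aetiology"]))
        records.append(
            PatientRecord(
                id=pid,
                initial_diagnosis=Diagnosis(row["diagnosis"]),
                discharge_outcome=Outcome(row["outcome"]),
                age=float(row["age"]),
                lesion_sites=parse_lesions(str(row["lesions"])),
                aetiology=aet_map.get(str(row["aetiology"]), str(row["aetiology"])),
                aetiology_raw=raw_aet,
                assessments=tuple(crsr),
                mbt=tuple(mbt),
                delay_first_crsr=float(row["delay_first_crsr"]),
                n_crsr=int(row["n_crsr"]),
                delay_last_crsr=float(row["delay_last_crsr"]),
                rehabilitation_duration=float(row["rehab_duration"]),
                returned_home=_yna(row["return_home"]),
                walks=_yna(row["walk"]),
            )
        )
    return records


def _format_value(value, column: str) -> str:
    if isinstance(value, float):
        if value != value:  # NaN
            return "NA"
        # p-values to 3 dp, everything else to 2 dp; Python's float
        # formatting applies round-half-even.
        digits = 3 if column.startswith("p") or "_p" in column else 2
        return f"{value:.{digits}f}"
    if value is None:
        return "NA"
    return str(value)


def write_tables(tables: dict[str, pd.DataFrame], out_dir, force: bool = False) -> list[Path]:
    """Write result tables as CSV with deterministic column order and
    fixed decimal formatting (2 dp for means/SDs, 3 dp for p-values).

    Re-running on identical input produces byte-identical files.  Existing
    files are only overwritten with ``force=True``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(df.columns)
            for _, row in df.iterrows():
                writer.writerow([_format_value(row[c], c) for c in df.columns])
        written.append(path)
    return written
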