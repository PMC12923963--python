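"""Cohort CSV reader/writer and report rendering.

The cohort dialect is one row per patient: scalar columns named after the
:class:`~nodal_tei.cohort.PatientRecord` fields, plus two boolean columns per
station, ``dissected_<code>`` and ``metastatic_<code>``. Booleans are 0/1,
missing numerics are empty cells, recurrence sites are a semicolon-joined
sorted list. UTF-8, comma-separated, header mandatory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .cohort import PatientRecord, Violation, validate_cohort
from .stations import ALL_STATIONS, STATION_REGIONS, REPORT_REGION_ORDER
from .tei import StationResult

logger = logging.getLogger("nodal_tei")

SCALAR_COLUMNS = (
    "patient_id",
    "histology",
    "siewert",
    "esophageal_involvement_cm",
    "gastric_involvement_cm",
    "cT",
    "cN_upper_middle_mediastinal",
    "neoadjuvant",
    "adjuvant",
    "approach",
    "esophagectomy",
    "gastrectomy",
    "residual",
    "os_time_years",
    "os_event",
    "rfs_time_years",
    "rfs_event",
    "recurrence_sites",
    "recurrence_time_years",
)

BOOL_COLUMNS = (
    "cN_upper_middle_mediastinal",
    "neoadjuvant",
    "adjuvant",
    "os_event",
    "rfs_event",
)


def cohort_columns() -> list[str]:
    cols = list(SCALAR_COLUMNS)
    cols += [f"dissected_{s}" for s in ALL_STATIONS]
    cols += [f"metastatic_{s}" for s in ALL_STATIONS]
    return cols


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id,
            "histology": r.histology,
            "siewert": r.siewert,
            "esophageal_involvement_cm": r.esophageal_involvement_cm,
            "gastric_involvement_cm": r.gastric_involvement_cm,
            "cT": r.cT,
            "cN_upper_middle_mediastinal": int(r.cN_upper_middle_mediastinal),
            "neoadjuvant": int(r.neoadjuvant),
            "adjuvant": int(r.adjuvant),
            "approach": r.approach,
            "esophagectomy": r.esophagectomy,
            "gastrectomy": r.gastrectomy,
            "residual": r.residual,
            "os_time_years": r.os_time_years,
            "os_event": int(r.os_event),
            "rfs_time_years": r.rfs_time_years,
            "rfs_event": int(r.rfs_event),
            "recurrence_sites": ";".join(sorted(r.recurrence_sites)),
            "recurrence_time_years": (
                "" if r.recurrence_time_years is None else r.recurrence_time_years
            ),
        }
        for s in ALL_STATIONS:
            row[f"dissected_{s}"] = int(r.is_dissected(s))
            row[f"metastatic_{s}"] = int(r.is_metastatic(s))
        rows.append(row)
    return pd.DataFrame(rows, columns=cohort_columns())


def write_cohort(records: list[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


class CohortFormatError(ValueError):
    """The CSV does not conform to the cohort dialect."""


class CohortValidationError(ValueError):
    """Strict-mode read found invariant violations."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        first = violations[0]
        super().__init__(
            f"{len(violations)} cohort invariant violation(s); first: "
            f"patient {first.patient_id}, rule {first.rule} ({first.detail})"
        )


def _parse_bool(value, column: str, row: int) -> bool:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise CohortFormatError(
            f"row {row}, column {column}: malformed boolean {value!r}"
        ) from None
    if iv not in (0, 1):
        raise CohortFormatError(f"row {row}, column {column}: boolean must be 0/1")
    return bool(iv)


def _parse_float(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortFormatError(
            f"row {row}, column {column}: malformed number {value!r}"
        ) from None


def read_cohort(path, strict: bool = False) -> list[PatientRecord]:
    """Read a cohort CSV, validate it, and return the records.

    Violations are logged; with ``strict=True`` any violation aborts with
    :class:`CohortValidationError` naming the first offending patient.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=False)
    missing = [c for c in cohort_columns() if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing column(s): {', '.join(missing)}")

    records = []
    for i, row in enumerate(df.to_dict("records")):
        rec_time = row["recurrence_time_years"]
        sites = frozenset(
            s for s in str(row["recurrence_sites"]).split(";") if s
        )
        dissected = {
            s: _parse_bool(row[f"dissected_{s}"], f"dissected_{s}", i)
            for s in ALL_STATIONS
        }
        metastatic = {
            s: _parse_bool(row[f"metastatic_{s}"], f"metastatic_{s}", i)
            for s in ALL_STATIONS
        }
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                histology=str(row["histology"]),
                siewert=str(row["siewert"]),
                esophageal_involvement_cm=_parse_float(
                    row["esophageal_involvement_cm"], "esophageal_involvement_cm", i
                ),
                gastric_involvement_cm=_parse_float(
                    row["gastric_involvement_cm"], "gastric_involvement_cm", i
                ),
                cT=str(row["cT"]),
                cN_upper_middle_mediastinal=_parse_bool(
                    row["cN_upper_middle_mediastinal"],
                    "cN_upper_middle_mediastinal",
                    i,
                ),
                neoadjuvant=_parse_bool(row["neoadjuvant"], "neoadjuvant", i),
                adjuvant=_parse_bool(row["adjuvant"], "adjuvant", i),
                approach=str(row["approach"]),
                esophagectomy=str(row["esophagectomy"]),
                gastrectomy=str(row["gastrectomy"]),
                residual=str(row["residual"]),
                os_time_years=_parse_float(row["os_time_years"], "os_time_years", i),
                os_event=_parse_bool(row["os_event"], "os_event", i),
                rfs_time_years=_parse_float(
                    row["rfs_time_years"], "rfs_time_years", i
                ),
                rfs_event=_parse_bool(row["rfs_event"], "rfs_event", i),
                dissected={s: v for s, v in dissected.items() if v},
                metastatic={s: v for s, v in metastatic.items() if v},
                recurrence_sites=sites,
                recurrence_time_years=(
                    None if rec_time == "" else _parse_float(
                        rec_time, "recurrence_time_years", i
                    )
                ),
            )
        )

    violations = validate_cohort(records)
    for v in violations:
        logger.warning("cohort invariant violation: %s", v.as_line())
    if strict and violations:
        raise CohortValidationError(violations)
    return records


# --- TEI report rendering ---------------------------------------------------

def _fmt_tei(res: StationResult) -> str:
    if not res.evaluable:
        return "-/-"
    return f"{res.tei_os:.1f}/{res.tei_rfs:.1f}"


def _result_rows(tables: dict[str, list[StationResult]]) -> pd.DataFrame:
    """Flatten stratum -> results into one deterministic row order: stations
    grouped by region in report order, strata in insertion order."""
    order = {
        code: i
        for i, code in enumerate(
            c for region in REPORT_REGION_ORDER for c in STATION_REGIONS[region]
        )
    }
    rows = []
    for stratum, results in tables.items():
        for res in results:
            rows.append(
                {
                    "station": res.station,
                    "region": next(
                        reg
                        for reg, codes in STATION_REGIONS.items()
                        if res.station in codes
                    ),
                    "stratum": stratum,
                    "n": res.n_denominator,
                    "n_met": res.n_metastatic,
                    "rate": res.metastasis_rate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "tei_os": res.tei_os,
                    "tei_rfs": res.tei_rfs,
                    "tei": _fmt_tei(res),
                    "class": res.classification or "",
                }
            )
    df = pd.DataFrame(rows)
    df["_order"] = df["station"].map(order)
    df = df.sort_values(["_order", "stratum"], kind="stable").drop(columns="_order")
    return df.reset_index(drop=True)


def render_report(
    tables: dict[str, list[StationResult]] | list[StationResult],
    fmt: str,
    path,
) -> None:
    """Write a stratified (or flat) TEI table as CSV or markdown.

    Output is deterministic: identical inputs give byte-identical files.
    Stations are ordered by region (mediastinum cranio-caudally, then
    abdomen); indices are printed ``os/rfs`` to one decimal and non-evaluable
    strata as ``-/-``; the ``class`` column marks stations exceeding both
    thresholds (``both_exceed``) or one (``single_exceed``).
    """
    if isinstance(tables, list):
        tables = {"all": tables}
    df = _result_rows(tables)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "markdown":
        cols = ["station", "region", "stratum", "n", "n_met", "tei", "class"]
        sub = df[cols].astype(str)
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "|".join(["---"] * len(cols)) + "|"]
        lines += ["| " + " | ".join(row) + " |" for row in sub.itertuples(index=False)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
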