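"""Patient-level cohort model: record type, screening-flow accounting, validation.

One :class:`PatientRecord` holds everything the downstream analysis needs for a
single subject: tumor covariates measured on the resected specimen, the
surgical approach and resection extent, per-station dissection and pathological
metastasis indicators, and the overall-survival (OS) / recurrence-free-survival
(RFS) outcomes with recurrence details. Times are durations in years from
surgery; there are no calendar dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .stations import ALL_STATIONS, is_station

HISTOLOGIES = ("adenocarcinoma", "scc")
SIEWERT_TYPES = ("I", "II", "III", "not_applicable")
CT_STAGES = ("T2", "T3", "T4")
APPROACHES = ("transhiatal", "right_transthoracic", "left_transthoracic", "laparotomy_only")
ESOPHAGECTOMY_TYPES = ("subtotal", "lower", "none")
GASTRECTOMY_TYPES = ("proximal_or_upper", "total", "none")
RESIDUAL_STATUSES = ("R0", "R1", "R2", "no_resection")
RECURRENCE_SITES = (
    "lymph_node_paraaortic",
    "lymph_node_mediastinal",
    "lymph_node_other",
    "liver",
    "peritoneum",
    "lung",
    "other",
)


@dataclass
class PatientRecord:
    """A single subject of the cohort.

    ``dissected`` and ``metastatic`` map station codes to booleans; a station
    absent from ``dissected`` is treated as not dissected (the TEI denominator
    is the set of patients who actually underwent dissection of a station).
    Metastasis is only pathologically observable in a dissected station.
    """

    patient_id: str
    histology: str
    siewert: str
    esophageal_involvement_cm: float
    gastric_involvement_cm: float
    cT: str
    cN_upper_middle_mediastinal: bool
    neoadjuvant: bool
    adjuvant: bool
    approach: str
    esophagectomy: str
    gastrectomy: str
    residual: str
    os_time_years: float
    os_event: bool
    rfs_time_years: float
    rfs_event: bool
    dissected: dict[str, bool] = field(default_factory=dict)
    metastatic: dict[str, bool] = field(default_factory=dict)
    recurrence_sites: frozenset[str] = frozenset()
    recurrence_time_years: float | None = None

    def is_dissected(self, station: str) -> bool:
        return bool(self.dissected.get(station, False))

    def is_metastatic(self, station: str) -> bool:
        return bool(self.metastatic.get(station, False))

    def copy(self, **changes) -> "PatientRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class ScreeningFlow:
    """Counts of the enrollment funnel, from screening to final eligibility."""

    screened: int
    ineligible_at_screening: int
    declined: int
    withdrew_consent: int = 0
    ineligible_post_enrollment: int = 0

    def __post_init__(self) -> None:
        for name in (
            "screened",
            "ineligible_at_screening",
            "declined",
            "withdrew_consent",
            "ineligible_post_enrollment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class InvalidFlowError(ValueError):
    """Screening-flow arithmetic produced a negative count."""


def enrolled_count(flow: ScreeningFlow) -> int:
    """Patients enrolled before surgery: screened minus pre-enrollment exclusions."""
    n = flow.screened - flow.ineligible_at_screening - flow.declined
    if n < 0:
        raise InvalidFlowError(f"enrolled count is negative ({n})")
    return n


def eligible_count(flow: ScreeningFlow) -> int:
    """Patients in the final eligible cohort, after post-enrollment exclusions."""
    n = enrolled_count(flow) - flow.withdrew_consent - flow.ineligible_post_enrollment
    if n < 0:
        raise InvalidFlowError(f"eligible count is negative ({n})")
    return n


@dataclass(frozen=True)
class Violation:
    """One record-level consistency failure found by :func:`validate_cohort`."""

    patient_id: str
    rule: str
    detail: str

    def as_line(self) -> str:
        return f"{self.patient_id}\t{self.rule}\t{self.detail}"


def validate_record(rec: PatientRecord) -> list[Violation]:
    """Check a single record against the cohort invariants."""
    v: list[Violation] = []

    def flag(rule: str, detail: str) -> None:
        v.append(Violation(rec.patient_id, rule, detail))

    if rec.histology not in HISTOLOGIES:
        flag("histology_domain", f"histology={rec.histology!r}")
    if rec.siewert not in SIEWERT_TYPES:
        flag("siewert_domain", f"siewert={rec.siewert!r}")
    if rec.cT not in CT_STAGES:
        flag("cT_domain", f"cT={rec.cT!r}")
    if rec.approach not in APPROACHES:
        flag("approach_domain", f"approach={rec.approach!r}")
    if rec.esophagectomy not in ESOPHAGECTOMY_TYPES:
        flag("esophagectomy_domain", f"esophagectomy={rec.esophagectomy!r}")
    if rec.gastrectomy not in GASTRECTOMY_TYPES:
        flag("gastrectomy_domain", f"gastrectomy={rec.gastrectomy!r}")
    if rec.residual not in RESIDUAL_STATUSES:
        flag("residual_domain", f"residual={rec.residual!r}")

    for name in ("esophageal_involvement_cm", "gastric_involvement_cm",
                 "os_time_years", "rfs_time_years"):
        if getattr(rec, name) < 0:
            flag("negative_value", f"{name}={getattr(rec, name)}")

    for label, mapping in (("dissected", rec.dissected), ("metastatic", rec.metastatic)):
        for code in mapping:
            if not is_station(code):
                flag("unknown_station", f"{label}[{code!r}]")

    for code in ALL_STATIONS:
        if rec.is_metastatic(code) and not rec.is_dissected(code):
            flag("metastasis_without_dissection",
                 f"metastatic[{code}]=1 but dissected[{code}]=0")

    if rec.rfs_time_years > rec.os_time_years + 1e-12:
        flag("rfs_exceeds_os",
             f"rfs_time={rec.rfs_time_years} > os_time={rec.os_time_years}")

    has_recurrence = rec.recurrence_time_years is not None
    if has_recurrence != bool(rec.recurrence_sites):
        flag("recurrence_sites_time_mismatch",
             f"sites={sorted(rec.recurrence_sites)} time={rec.recurrence_time_years}")
    if has_recurrence and not rec.rfs_event:
        flag("recurrence_without_rfs_event",
             f"recurrence at {rec.recurrence_time_years} but rfs_event=0")
    if has_recurrence and rec.recurrence_time_years > rec.os_time_years + 1e-12:
        flag("recurrence_after_os_time",
             f"recurrence_time={rec.recurrence_time_years} > os_time={rec.os_time_years}")
    for site in rec.recurrence_sites:
        if site not in RECURRENCE_SITES:
            flag("recurrence_site_domain", f"site={site!r}")

    if rec.os_event and not has_recurrence and not rec.rfs_event:
        # death without recurrence is itself an RFS event
        flag("death_without_rfs_event", "os_event=1, no recurrence, rfs_event=0")

    if (rec.siewert == "not_applicable") != (rec.histology == "scc"):
        flag("siewert_histology_mismatch",
             f"histology={rec.histology}, siewert={rec.siewert}")

    return v


def validate_cohort(records: list[PatientRecord]) -> list[Violation]:
    """Validate every record; a clean cohort yields an empty list.

    Pure and idempotent: records are never modified.
    """
    out: list[Violation] = []
    for rec in records:
        out.extend(validate_record(rec))
    return out


def render_violations(violations: list[Violation]) -> str:
    """Machine-readable report, one ``patient_id<TAB>rule<TAB>detail`` per line."""
    return "\n".join(v.as_line() for v in violations)
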