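"""Deterministic worked-example cohort builders.

These construct small synthetic cohorts with exact metastasis and survivor
counts at a single station, used to verify the TEI arithmetic end to end
(eligibility -> denominator restriction -> rate x conditional survival). They
are synthetic stand-ins built to stated denominators, not patient data.
"""

from __future__ import annotations

from .cohort import PatientRecord
from .stations import (
    CORE_DISSECTION,
    UPPER_MIDDLE_MEDIASTINAL,
    station_region,
)


def _base_patient(pid: str, **overrides) -> PatientRecord:
    defaults = dict(
        patient_id=pid,
        histology="adenocarcinoma",
        siewert="II",
        esophageal_involvement_cm=2.0,
        gastric_involvement_cm=2.5,
        cT="T3",
        cN_upper_middle_mediastinal=False,
        neoadjuvant=False,
        adjuvant=False,
        approach="transhiatal",
        esophagectomy="lower",
        gastrectomy="proximal_or_upper",
        residual="R0",
        os_time_years=6.0,
        os_event=False,
        rfs_time_years=6.0,
        rfs_event=False,
        dissected={s: True for s in CORE_DISSECTION},
        metastatic={},
    )
    defaults.update(overrides)
    return PatientRecord(**defaults)


def station_fixture_cohort(
    station: str,
    n: int,
    n_metastatic: int,
    n_survivor_os: int,
    n_survivor_rfs: int | None = None,
    *,
    esophageal_involvement_cm: float = 2.0,
    neoadjuvant: bool = False,
) -> list[PatientRecord]:
    """Cohort of ``n`` patients, all with ``station`` dissected and followed at
    least 5 years, of whom ``n_metastatic`` are metastatic at the station and
    ``n_survivor_os`` of those are alive at the 5-year landmark.

    Patients are given whatever surgery the station's denominator rule
    requires (right transthoracic subtotal esophagectomy for upper/middle
    mediastinal stations, total gastrectomy for greater-curvature / distal
    perigastric stations), so the full denominator restriction is exercised.
    """
    if not 0 <= n_survivor_os <= n_metastatic <= n:
        raise ValueError("need 0 <= n_survivor_os <= n_metastatic <= n")
    if n_survivor_rfs is None:
        n_survivor_rfs = n_survivor_os
    region = station_region(station)

    surgery: dict = {}
    dissected = {s: True for s in CORE_DISSECTION}
    if region in ("upper_mediastinal", "middle_mediastinal"):
        surgery = dict(approach="right_transthoracic", esophagectomy="subtotal")
        dissected.update({s: True for s in UPPER_MIDDLE_MEDIASTINAL})
    elif region in ("left_greater_curvature", "distal_perigastric"):
        surgery = dict(gastrectomy="total")
        dissected[station] = True
    dissected[station] = True

    cohort = []
    for i in range(n):
        metastatic = {station: True} if i < n_metastatic else {}
        if i < n_metastatic and i >= n_survivor_os:
            # death before the 5-year landmark, preceded by recurrence
            outcome = dict(
                os_time_years=2.5,
                os_event=True,
                rfs_time_years=1.5,
                rfs_event=True,
                recurrence_sites=frozenset({"lymph_node_other"}),
                recurrence_time_years=1.5,
            )
        elif i < n_metastatic and i >= n_survivor_rfs:
            # alive at 5 years but recurred before it (RFS event, OS survivor)
            outcome = dict(
                os_time_years=6.0,
                os_event=False,
                rfs_time_years=3.0,
                rfs_event=True,
                recurrence_sites=frozenset({"lymph_node_other"}),
                recurrence_time_years=3.0,
            )
        else:
            outcome = dict(
                os_time_years=6.0, os_event=False, rfs_time_years=6.0, rfs_event=False
            )
        cohort.append(
            _base_patient(
                f"{station}-{i:04d}",
                dissected=dict(dissected),
                metastatic=metastatic,
                esophageal_involvement_cm=esophageal_involvement_cm,
                neoadjuvant=neoadjuvant,
                **surgery,
                **outcome,
            )
        )
    return cohort


def screening_fixture_cohort() -> list[PatientRecord]:
    """A 363-patient cohort with the eligibility structure of the study:
    339 R0 + 15 R1 + 9 R2 resections, with 4 of the R0/R1 patients lost to
    follow-up before 5 years without a documented recurrence — leaving 350
    TEI-eligible patients."""
    cohort = []
    i = 0
    for residual, count in (("R0", 339), ("R1", 15), ("R2", 9)):
        for _ in range(count):
            cohort.append(_base_patient(f"S{i:04d}", residual=residual))
            i += 1
    for rec in cohort[:4]:  # R0 patients lost before 5 years, no recurrence
        rec.os_time_years = 3.0
        rec.os_event = False
        rec.rfs_time_years = 3.0
        rec.rfs_event = False
    return cohort
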