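"""Dissection-and-approach recommendation engine.

Encodes the updated surgical algorithm for cT2-T4 EGJ cancer implied by the
TEI analysis: proximal perigastric and suprapancreatic nodes are always
dissected; greater-curvature, distal perigastric and para-aortic nodes are
avoided; mediastinal dissection is tailored to the length of esophageal
involvement (measured after neoadjuvant treatment, when given). Lower
mediastinal nodes are added above 2 cm, middle mediastinal above 3 cm, and
upper mediastinal dissection is conditional — considered only with clinical
nodal positivity in the upper/middle mediastinum or in patients who did not
receive neoadjuvant chemotherapy. The transhiatal approach suffices at 2 cm
or less; the right transthoracic route is required above 3 cm or with
mediastinal cN+; in between, either approach is acceptable. Histology does
not alter the recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .stations import STATION_REGIONS

UPPER_MEDIASTINAL_CONDITION = (
    "cN+ in upper/middle mediastinum OR no neoadjuvant chemotherapy"
)


@dataclass(frozen=True)
class TumorProfile:
    """Inputs of the algorithm: esophageal involvement length (cm; the
    post-treatment measurement when neoadjuvant chemotherapy was given),
    clinical nodal status in the upper/middle mediastinal field, and whether
    neoadjuvant chemotherapy was given."""

    esophageal_involvement_cm: float
    cN_upper_middle_mediastinal: bool = False
    neoadjuvant: bool = False

    def __post_init__(self) -> None:
        if self.esophageal_involvement_cm < 0:
            raise ValueError("esophageal involvement must be non-negative")


@dataclass
class Recommendation:
    approaches: frozenset[str]
    dissect_always: frozenset[str]
    dissect_conditional: dict[str, str] = field(default_factory=dict)
    avoid: frozenset[str] = frozenset()
    gastrectomy: str = "proximal_preferred"

    def __post_init__(self) -> None:
        if not self.approaches:
            raise ValueError("approaches must be non-empty")
        overlap = (self.dissect_always | set(self.dissect_conditional)) & self.avoid
        if overlap:
            raise ValueError(f"stations both dissected and avoided: {sorted(overlap)}")


def recommend(profile: TumorProfile, include_11d: bool = True) -> Recommendation:
    """Map a tumor profile to the recommended approach and dissection extent.

    ``include_11d=False`` drops station 11d from the always-dissect set: the
    suprapancreatic field is recommended as a whole, though 11d individually
    sits below both index thresholds.
    """
    inv = profile.esophageal_involvement_cm
    cn = profile.cN_upper_middle_mediastinal

    always = set(STATION_REGIONS["proximal_perigastric"])
    always |= set(STATION_REGIONS["suprapancreatic"])
    if not include_11d:
        always.discard("11d")
    if inv > 2.0:
        always |= set(STATION_REGIONS["lower_mediastinal"])
    if inv > 3.0:
        always |= set(STATION_REGIONS["middle_mediastinal"])

    conditional: dict[str, str] = {}
    if inv > 3.0 or cn:
        for s in STATION_REGIONS["upper_mediastinal"]:
            conditional[s] = UPPER_MEDIASTINAL_CONDITION

    avoid = (
        set(STATION_REGIONS["distal_perigastric"])
        | set(STATION_REGIONS["left_greater_curvature"])
        | set(STATION_REGIONS["paraaortic"])
    )

    if inv > 3.0 or cn:
        approaches = frozenset({"right_transthoracic"})
    elif inv <= 2.0:
        approaches = frozenset({"transhiatal"})
    else:
        approaches = frozenset({"transhiatal", "right_transthoracic"})

    return Recommendation(
        approaches=approaches,
        dissect_always=frozenset(always),
        dissect_conditional=conditional,
        avoid=frozenset(avoid),
        gastrectomy="proximal_preferred",
    )


def upper_mediastinal_indicated(profile: TumorProfile) -> bool:
    """Resolve the conditional upper-mediastinal recommendation for a concrete
    patient: dissect only with mediastinal cN+ or without neoadjuvant
    chemotherapy (and only when the field is in play at all)."""
    rec = recommend(profile)
    if not rec.dissect_conditional:
        return False
    return profile.cN_upper_middle_mediastinal or not profile.neoadjuvant


def format_recommendation(rec: Recommendation) -> str:
    """Human-readable rendering followed by machine-readable key=value lines."""
    lines = [
        "Recommended approach(es): " + " or ".join(sorted(rec.approaches)),
        "Dissect: " + ", ".join(sorted(rec.dissect_always)),
    ]
    if rec.dissect_conditional:
        cond = next(iter(rec.dissect_conditional.values()))
        lines.append(
            "Dissect conditionally ("
            + cond
            + "): "
            + ", ".join(sorted(rec.dissect_conditional))
        )
    lines.append("Avoid: " + ", ".join(sorted(rec.avoid)))
    lines.append(
        "Gastrectomy: proximal preferred (total only if the distal margin is inadequate)"
    )
    lines.append("")
    lines.append("approaches=" + ",".join(sorted(rec.approaches)))
    lines.append("dissect_always=" + ",".join(sorted(rec.dissect_always)))
    lines.append("dissect_conditional=" + ",".join(sorted(rec.dissect_conditional)))
    lines.append("avoid=" + ",".join(sorted(rec.avoid)))
    lines.append("gastrectomy=" + rec.gastrectomy)
    return "\n".join(lines)
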