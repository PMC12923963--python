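"""Lymph-node station catalog for esophagogastric junction (EGJ) cancer surgery.

The analysis covers the 26 node stations dissected in nationwide Japanese
practice for cT2-T4 EGJ tumors: abdominal stations numbered per the Japanese
Classification of Gastric Carcinoma (1-20 plus the para-aortic sub-station
16a2) and mediastinal stations per the Japanese Classification of Esophageal
Cancer (105-112, with left/right splits for the recurrent-laryngeal-nerve and
main-bronchus stations). Stations are grouped into anatomical regions; the
regions partition the catalog and drive both the denominator-restriction
rules of the TEI analysis and the report ordering.
"""

from __future__ import annotations

#: Region -> station codes. Regions are disjoint and jointly exhaustive.
STATION_REGIONS: dict[str, tuple[str, ...]] = {
    "proximal_perigastric": ("1", "2", "3", "7"),
    "left_greater_curvature": ("4sa", "4sb"),
    "distal_perigastric": ("4d", "5", "6"),
    "suprapancreatic": ("8a", "9", "11p", "11d"),
    "abdominal_hiatal": ("19", "20"),
    "paraaortic": ("16a2",),
    "upper_mediastinal": ("105", "106L", "106R"),
    "middle_mediastinal": ("107", "108", "109L", "109R"),
    "lower_mediastinal": ("110", "111", "112"),
}

#: All 26 station codes, in region order.
ALL_STATIONS: tuple[str, ...] = tuple(
    code for codes in STATION_REGIONS.values() for code in codes
)

_REGION_OF: dict[str, str] = {
    code: region for region, codes in STATION_REGIONS.items() for code in codes
}

#: Regions lying in the mediastinum (chest), reachable only transthoracically
#: in full; the transhiatal route still reaches the lower mediastinum.
MEDIASTINAL_REGIONS = frozenset(
    {"upper_mediastinal", "middle_mediastinal", "lower_mediastinal"}
)

#: Stations whose thorough dissection requires the right transthoracic route.
UPPER_MIDDLE_MEDIASTINAL: tuple[str, ...] = (
    STATION_REGIONS["upper_mediastinal"] + STATION_REGIONS["middle_mediastinal"]
)

#: Stations dissected by every protocol approach (perigastric, suprapancreatic,
#: para-aortic, abdominal hiatal and lower mediastinal fields).
CORE_DISSECTION: tuple[str, ...] = (
    "1", "2", "3", "7",
    "8a", "9", "11p", "11d",
    "16a2",
    "19", "20",
    "110", "111", "112",
)

#: Additional stations dissected with a total gastrectomy (greater-curvature
#: and distal perigastric fields).
TOTAL_GASTRECTOMY_EXTRA: tuple[str, ...] = ("4sa", "4sb", "4d", "5", "6")

#: Region ordering used for all rendered tables: mediastinum cranio-caudally,
#: then abdomen.
REPORT_REGION_ORDER: tuple[str, ...] = (
    "upper_mediastinal",
    "middle_mediastinal",
    "lower_mediastinal",
    "proximal_perigastric",
    "left_greater_curvature",
    "distal_perigastric",
    "suprapancreatic",
    "abdominal_hiatal",
    "paraaortic",
)


class UnknownStationError(ValueError):
    """Raised when a station code outside the 26-station catalog is used."""


def station_region(code: str) -> str:
    """Return the anatomical region of a station code.

    Raises
    ------
    UnknownStationError
        If ``code`` is not one of the 26 catalog stations; the offending
        token is included in the message.
    """
    try:
        return _REGION_OF[code]
    except KeyError:
        raise UnknownStationError(f"unknown lymph-node station code: {code!r}") from None


def is_station(code: str) -> bool:
    """True if ``code`` is one of the 26 catalog stations."""
    return code in _REGION_OF


def stations_in_report_order() -> list[str]:
    """All stations ordered by :data:`REPORT_REGION_ORDER`."""
    return [c for region in REPORT_REGION_ORDER for c in STATION_REGIONS[region]]
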