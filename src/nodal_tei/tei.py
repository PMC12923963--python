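"""Therapeutic efficacy index (TEI) engine.

The TEI of a lymph-node station is the station's metastasis rate multiplied by
the 5-year survival rate among the patients metastatic at that station, on the
percentage scale. It estimates the expected gain in 5-year survival (OS or
RFS), in percentage points, attributable to dissecting that station: a station
metastasizes often *and* whose metastatic patients still survive long-term is
one whose removal plausibly cured somebody.

Denominators are restricted to the patients in whom the station was actually
dissected, and further to the surgical subgroups in which the station is
systematically examined: upper/middle mediastinal stations to right
transthoracic subtotal esophagectomies, greater-curvature and distal
perigastric stations to total gastrectomies. Rates carry Clopper-Pearson exact
95% intervals. Stations with a TEI above 3 for 5-year OS and above 2 for
5-year RFS (strict inequalities) are classified as clearly worth dissecting;
exceeding a single threshold is suggestive; neither indicates minimal benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .cohort import PatientRecord
from .stations import station_region, ALL_STATIONS
from .survival import LOST_BEFORE_5Y, SURVIVOR, five_year_status
from .utils import round_half_up

TEI_OS_THRESHOLD = 3.0
TEI_RFS_THRESHOLD = 2.0

BOTH_EXCEED = "both_exceed"
SINGLE_EXCEED = "single_exceed"
NEITHER = "neither"

#: Regions whose denominator is restricted to right-transthoracic subtotal
#: esophagectomy (thorough mediastinal dissection is protocolized only there).
_RT_RESTRICTED = frozenset({"upper_mediastinal", "middle_mediastinal"})
#: Regions whose denominator is restricted to total gastrectomy.
_TG_RESTRICTED = frozenset({"left_greater_curvature", "distal_perigastric"})


@dataclass
class StationResult:
    """Per-station TEI summary (one row of the reported tables)."""

    station: str
    n_denominator: int
    n_metastatic: int
    metastasis_rate: float | None
    ci_low: float | None
    ci_high: float | None
    n_survivor_5y_os: int
    n_survivor_5y_rfs: int
    tei_os: float | None
    tei_rfs: float | None
    classification: str | None

    @property
    def evaluable(self) -> bool:
        return self.n_denominator > 0


def tei_eligible(cohort: list[PatientRecord]) -> list[PatientRecord]:
    """The TEI analysis population.

    Patients with an R0 or R1 resection, excluding those lost to follow-up
    within 5 years *without confirmation of recurrence*: a patient censored
    for OS before year 5 is retained if a recurrence was documented by then,
    since their disease status is not unknown.
    """
    out = []
    for r in cohort:
        if r.residual not in ("R0", "R1"):
            continue
        if five_year_status(r, "os") == LOST_BEFORE_5Y:
            confirmed = (
                r.recurrence_time_years is not None and r.recurrence_time_years <= 5.0
            )
            if not confirmed:
                continue
        out.append(r)
    return out


def station_denominator(
    eligible: list[PatientRecord], station: str
) -> list[PatientRecord]:
    """Patients contributing to the metastasis-rate denominator of a station."""
    region = station_region(station)
    subset = [r for r in eligible if r.is_dissected(station)]
    if region in _RT_RESTRICTED:
        subset = [
            r
            for r in subset
            if r.approach == "right_transthoracic" and r.esophagectomy == "subtotal"
        ]
    elif region in _TG_RESTRICTED:
        subset = [r for r in subset if r.gastrectomy == "total"]
    return subset


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    Obtained from beta quantiles, the closed form of inverting the binomial
    tail tests. The lower bound is 0 when k = 0 and the upper bound 1 when
    k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def classify(tei_os: float, tei_rfs: float) -> str:
    """Threshold classification of a station's (OS, RFS) index pair.

    Strict inequalities: OS must exceed 3 and RFS must exceed 2; equality
    does not qualify.
    """
    os_hit = tei_os > TEI_OS_THRESHOLD
    rfs_hit = tei_rfs > TEI_RFS_THRESHOLD
    if os_hit and rfs_hit:
        return BOTH_EXCEED
    if os_hit or rfs_hit:
        return SINGLE_EXCEED
    return NEITHER


def station_tei(
    eligible: list[PatientRecord],
    station: str,
    endpoint: str = "both",
    level: float = 0.95,
) -> StationResult:
    """Compute the TEI of one station over an eligible subset.

    The 5-year survival among metastatic cases is a simple proportion of
    survivors at the landmark (the eligibility rule removed patients with
    inadequate follow-up, so the proportion is well defined); with no
    metastatic patient the index is 0, not undefined. Indices are rounded
    half-up to one decimal, matching reported precision; an empty denominator
    yields a not-evaluable result with all rates None.
    """
    if endpoint not in ("os", "rfs", "both"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    denom = station_denominator(eligible, station)
    n = len(denom)
    if n == 0:
        return StationResult(station, 0, 0, None, None, None, 0, 0, None, None, None)

    met = [r for r in denom if r.is_metastatic(station)]
    k = len(met)
    rate = k / n
    ci_low, ci_high = clopper_pearson(k, n, level)

    surv_os = sum(1 for r in met if five_year_status(r, "os") == SURVIVOR)
    surv_rfs = sum(1 for r in met if five_year_status(r, "rfs") == SURVIVOR)
    tei_os = round_half_up(rate * (surv_os / k) * 100.0, 1) if k else 0.0
    tei_rfs = round_half_up(rate * (surv_rfs / k) * 100.0, 1) if k else 0.0

    return StationResult(
        station=station,
        n_denominator=n,
        n_metastatic=k,
        metastasis_rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        n_survivor_5y_os=surv_os,
        n_survivor_5y_rfs=surv_rfs,
        tei_os=tei_os,
        tei_rfs=tei_rfs,
        classification=classify(tei_os, tei_rfs),
    )


def tei_table(
    eligible: list[PatientRecord],
    stations: list[str] | None = None,
    endpoint: str = "both",
) -> list[StationResult]:
    """TEI for every requested station (default: the full 26-station catalog)."""
    if stations is None:
        stations = list(ALL_STATIONS)
    return [station_tei(eligible, s, endpoint) for s in stations]


# --- stratification ---------------------------------------------------------

STRATIFIERS = (
    "esophageal_involvement_bins",
    "histology",
    "neoadjuvant",
    "adjuvant",
    "cN_upper_middle",
)

#: Involvement bins: the mediastinal stations dissected only transthoracically
#: use a coarse <=3 / >3 cm split (small denominators); lower mediastinal and
#: abdominal stations use four bins. Half-open on the left, closed on the
#: right, matching labels like "1.1-2.0" for lengths recorded to one decimal.
COARSE_BINS = (("<=3.0", 0.0, 3.0), (">3.0", 3.0, float("inf")))
FINE_BINS = (
    ("<=1.0", 0.0, 1.0),
    ("1.1-2.0", 1.0, 2.0),
    ("2.1-3.0", 2.0, 3.0),
    (">3.0", 3.0, float("inf")),
)


def involvement_bins_for(station: str):
    region = station_region(station)
    return COARSE_BINS if region in _RT_RESTRICTED else FINE_BINS


def _stratum_value(rec: PatientRecord, stratifier: str) -> str | None:
    if stratifier == "histology":
        return rec.histology
    if stratifier == "neoadjuvant":
        return "yes" if rec.neoadjuvant else "no"
    if stratifier == "adjuvant":
        return "yes" if rec.adjuvant else "no"
    if stratifier == "cN_upper_middle":
        return "cN+" if rec.cN_upper_middle_mediastinal else "cN0"
    raise ValueError(f"unknown stratifier {stratifier!r}")


def stratified_tei(
    eligible: list[PatientRecord],
    stations: list[str] | None = None,
    stratifier: str = "histology",
    endpoint: str = "both",
) -> dict[str, list[StationResult]]:
    """TEI tables split by a stratifier, denominators re-derived per stratum.

    Returns ``{stratum_label: [StationResult, ...]}``. For the involvement
    stratifier the bins depend on the station's region, so a station appears
    only under its applicable bin labels.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    if stations is None:
        stations = list(ALL_STATIONS)

    out: dict[str, list[StationResult]] = {}
    if stratifier == "esophageal_involvement_bins":
        for station in stations:
            for label, lo, hi in involvement_bins_for(station):
                subset = [
                    r for r in eligible if lo < r.esophageal_involvement_cm <= hi
                    or (lo == 0.0 and r.esophageal_involvement_cm == 0.0)
                ]
                out.setdefault(label, []).append(
                    station_tei(subset, station, endpoint)
                )
        return out

    labels = {
        "histology": ("adenocarcinoma", "scc"),
        "neoadjuvant": ("no", "yes"),
        "adjuvant": ("no", "yes"),
        "cN_upper_middle": ("cN0", "cN+"),
    }[stratifier]
    for label in labels:
        subset = [r for r in eligible if _stratum_value(r, stratifier) == label]
        out[label] = [station_tei(subset, s, endpoint) for s in stations]
    return out
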