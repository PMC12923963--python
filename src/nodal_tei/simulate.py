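"""Seeded synthetic cohort generator.

Emulates the structure of a prospective EGJ-cancer surgical cohort: tumor
covariates drawn to published-style marginals, the protocol rule assigning the
surgical approach (right transthoracic for squamous histology, adenocarcinoma
with esophageal involvement over 3 cm, or clinical nodal positivity in the
upper/middle mediastinum; transhiatal otherwise), approach-determined
dissection fields, per-station metastasis indicators with a logistic
involvement effect on mediastinal stations, and OS/RFS outcomes with
administrative censoring at or beyond 5 years plus a small
loss-to-follow-up fraction.

Event times are Weibull, with the scale per patient solved so the 5-year
survivor fraction equals the configured conditional survival: for a patient
with at least one metastatic station, the largest conditional survival among
their metastatic stations; otherwise the node-negative survival. Recurrence,
when it precedes death, is placed an exponential lead time before death, which
guarantees RFS time <= OS time by construction.

Reproducibility: one seed sequence per cohort; each patient draws from a
substream spawned deterministically by patient index, so the same (config,
seed) is byte-identical regardless of iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import PatientRecord, RECURRENCE_SITES
from .stations import (
    ALL_STATIONS,
    CORE_DISSECTION,
    MEDIASTINAL_REGIONS,
    TOTAL_GASTRECTOMY_EXTRA,
    UPPER_MIDDLE_MEDIASTINAL,
    station_region,
)


def _default_station_base_prob() -> dict[str, float]:
    # Illustrative per-station metastasis probabilities: high in the proximal
    # perigastric field, moderate suprapancreatic, low mediastinal/paraaortic,
    # near-zero distal perigastric. Not calibrated to any published table.
    return {
        "1": 0.30, "2": 0.18, "3": 0.28, "7": 0.15,
        "4sa": 0.02, "4sb": 0.005,
        "4d": 0.01, "5": 0.005, "6": 0.01,
        "8a": 0.08, "9": 0.09, "11p": 0.10, "11d": 0.03,
        "19": 0.03, "20": 0.03,
        "16a2": 0.02,
        "105": 0.01, "106L": 0.04, "106R": 0.05,
        "107": 0.01, "108": 0.05, "109L": 0.02, "109R": 0.02,
        "110": 0.08, "111": 0.03, "112": 0.02,
    }


def _default_surv5_given_met() -> dict[str, float]:
    # Conditional 5-year OS given metastasis at the station; illustrative
    # (per-station conditional survival is not published), graded by how
    # regional vs distant the basin is.
    out = {}
    for code in ALL_STATIONS:
        region = station_region(code)
        out[code] = {
            "proximal_perigastric": 0.45,
            "suprapancreatic": 0.35,
            "abdominal_hiatal": 0.30,
            "left_greater_curvature": 0.10,
            "distal_perigastric": 0.10,
            "paraaortic": 0.10,
            "upper_mediastinal": 0.25,
            "middle_mediastinal": 0.25,
            "lower_mediastinal": 0.30,
        }[region]
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the study conditions: cohort size 363; squamous fraction
    0.085; neoadjuvant 0.333; adjuvant 0.534 after R0/R1; esophageal
    involvement log-normal with median 2.0 cm (IQR target 1.0-3.0), gastric
    median 2.5 cm (IQR 1.5-3.7), both truncated at 12 cm; administrative
    censoring uniform on [5.0, 7.4] years (median follow-up about 6.2 years);
    loss to follow-up before 5 years 1.1%; clinical upper/middle mediastinal
    nodal positivity 8.3%; R1 4.1% and R2 2.5%.
    """

    n_patients: int = 363
    seed: int = 0
    prop_scc: float = 0.085
    prop_siewert_I_given_ad: float = 0.093
    prop_neoadjuvant: float = 0.333
    prop_adjuvant_given_r0r1: float = 0.534
    # log-normal parameters on the log scale (location = log median)
    esoph_involvement_location: float = math.log(2.0)
    esoph_involvement_scale: float = 0.8145
    gastric_involvement_location: float = math.log(2.5)
    gastric_involvement_scale: float = 0.669
    involvement_truncation_cm: float = 12.0
    station_base_prob: dict[str, float] = field(
        default_factory=_default_station_base_prob
    )
    mediastinal_slope: float = 0.35  # per-cm log-odds increment
    surv5_given_station_met: dict[str, float] = field(
        default_factory=_default_surv5_given_met
    )
    surv5_node_negative: float = 0.80
    hazard_shape: float = 1.0  # Weibull shape; 1 = exponential
    admin_censor_years_min: float = 5.0
    admin_censor_years_max: float = 7.4
    loss_to_followup_prob: float = 0.011
    prop_cN_upper_middle: float = 0.083
    prop_total_gastrectomy_given_th: float = 0.78
    prop_r1: float = 0.041
    prop_r2: float = 0.025
    prop_recurrence_before_death: float = 0.85
    recurrence_lead_mean_years: float = 1.33
    ct_probs: tuple[float, float, float] = (0.237, 0.444, 0.319)

    def validate(self) -> None:
        probs = {
            "prop_scc": self.prop_scc,
            "prop_siewert_I_given_ad": self.prop_siewert_I_given_ad,
            "prop_neoadjuvant": self.prop_neoadjuvant,
            "prop_adjuvant_given_r0r1": self.prop_adjuvant_given_r0r1,
            "surv5_node_negative": self.surv5_node_negative,
            "loss_to_followup_prob": self.loss_to_followup_prob,
            "prop_cN_upper_middle": self.prop_cN_upper_middle,
            "prop_total_gastrectomy_given_th": self.prop_total_gastrectomy_given_th,
            "prop_r1": self.prop_r1,
            "prop_r2": self.prop_r2,
            "prop_recurrence_before_death": self.prop_recurrence_before_death,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability; got {p}")
        for code, p in {**self.station_base_prob,
                        **self.surv5_given_station_met}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"station probability for {code} out of [0,1]: {p}")
        if self.admin_censor_years_min < 5.0:
            raise ValueError("admin_censor_years_min must be >= 5")
        if self.admin_censor_years_max < self.admin_censor_years_min:
            raise ValueError("admin censoring bounds out of order")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.hazard_shape <= 0:
            raise ValueError("hazard_shape must be positive")


def _approach_rule(histology: str, involvement: float, cn_um: bool) -> str:
    """Protocol rule: right transthoracic iff SCC, adenocarcinoma with
    esophageal involvement over 3 cm, or cN+ in the upper/middle mediastinum;
    transhiatal otherwise."""
    if histology == "scc" or involvement > 3.0 or cn_um:
        return "right_transthoracic"
    return "transhiatal"


def _truncated_lognormal(rng, location, scale, cap) -> float:
    for _ in range(1000):
        x = float(rng.lognormal(mean=location, sigma=scale))
        if x <= cap:
            return round(x, 1)  # lengths recorded to 1 mm
    return cap


def _weibull_time(rng, surv5: float, shape: float) -> float:
    """Draw an event time whose survivor function has S(5) = surv5."""
    if surv5 >= 1.0:
        return float("inf")
    surv5 = max(surv5, 1e-12)
    scale = 5.0 / (-math.log(surv5)) ** (1.0 / shape)
    u = rng.uniform()
    return scale * (-math.log(max(u, 1e-300))) ** (1.0 / shape)


_SITE_WEIGHTS = {
    "lymph_node_paraaortic": 0.275,
    "lymph_node_mediastinal": 0.155,
    "lymph_node_other": 0.15,
    "liver": 0.261,
    "peritoneum": 0.218,
    "lung": 0.211,
    "other": 0.10,
}


def _draw_sites(rng) -> frozenset[str]:
    sites = frozenset(s for s in RECURRENCE_SITES if rng.uniform() < _SITE_WEIGHTS[s])
    if sites:
        return sites
    w = np.array([_SITE_WEIGHTS[s] for s in RECURRENCE_SITES])
    return frozenset({RECURRENCE_SITES[int(rng.choice(len(w), p=w / w.sum()))]})


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate a cohort of :class:`PatientRecord` under ``config``.

    Deterministic in (config, seed): per-patient substreams are spawned from
    one seed sequence by patient index.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records = []
    for i, child in enumerate(children):
        records.append(_simulate_patient(f"P{i:05d}", np.random.default_rng(child), config))
    return records


def _simulate_patient(pid: str, rng, cfg: SimulationConfig) -> PatientRecord:
    scc = rng.uniform() < cfg.prop_scc
    histology = "scc" if scc else "adenocarcinoma"
    siewert = (
        "not_applicable"
        if scc
        else ("I" if rng.uniform() < cfg.prop_siewert_I_given_ad else "II")
    )
    involvement = _truncated_lognormal(
        rng, cfg.esoph_involvement_location, cfg.esoph_involvement_scale,
        cfg.involvement_truncation_cm,
    )
    gastric = _truncated_lognormal(
        rng, cfg.gastric_involvement_location, cfg.gastric_involvement_scale,
        cfg.involvement_truncation_cm,
    )
    cn_um = rng.uniform() < cfg.prop_cN_upper_middle
    neoadjuvant = rng.uniform() < cfg.prop_neoadjuvant
    cT = ("T2", "T3", "T4")[int(rng.choice(3, p=np.array(cfg.ct_probs) / sum(cfg.ct_probs)))]

    approach = _approach_rule(histology, involvement, cn_um)
    if approach == "right_transthoracic":
        esophagectomy, gastrectomy = "subtotal", "proximal_or_upper"
    else:
        esophagectomy = "lower"
        gastrectomy = (
            "total"
            if rng.uniform() < cfg.prop_total_gastrectomy_given_th
            else "proximal_or_upper"
        )

    dissected = {s: True for s in CORE_DISSECTION}
    if approach == "right_transthoracic":
        dissected.update({s: True for s in UPPER_MIDDLE_MEDIASTINAL})
    if gastrectomy == "total":
        dissected.update({s: True for s in TOTAL_GASTRECTOMY_EXTRA})

    metastatic: dict[str, bool] = {}
    for s, yes in dissected.items():
        if not yes:
            continue
        p = cfg.station_base_prob.get(s, 0.0)
        if station_region(s) in MEDIASTINAL_REGIONS and 0.0 < p < 1.0:
            logit = math.log(p / (1.0 - p)) + cfg.mediastinal_slope * involvement
            p = 1.0 / (1.0 + math.exp(-logit))
        if rng.uniform() < p:
            metastatic[s] = True

    u = rng.uniform()
    residual = "R1" if u < cfg.prop_r1 else ("R2" if u < cfg.prop_r1 + cfg.prop_r2 else "R0")
    adjuvant = residual in ("R0", "R1") and rng.uniform() < cfg.prop_adjuvant_given_r0r1

    if metastatic:
        surv5 = max(cfg.surv5_given_station_met[s] for s in metastatic)
    else:
        surv5 = cfg.surv5_node_negative
    death_time = _weibull_time(rng, surv5, cfg.hazard_shape)

    censor = rng.uniform(cfg.admin_censor_years_min, cfg.admin_censor_years_max)
    if rng.uniform() < cfg.loss_to_followup_prob:
        censor = min(censor, rng.uniform(0.0, 5.0))

    recurrence_time = None
    if rng.uniform() < cfg.prop_recurrence_before_death:
        lead = rng.exponential(cfg.recurrence_lead_mean_years)
        recurrence_time = max(death_time - lead, 0.01)

    os_time = min(death_time, censor)
    os_event = death_time <= censor
    if recurrence_time is not None and recurrence_time <= os_time:
        rfs_time, rfs_event = recurrence_time, True
        sites = _draw_sites(rng)
    else:
        recurrence_time, sites = None, frozenset()
        rfs_time, rfs_event = os_time, os_event

    return PatientRecord(
        patient_id=pid,
        histology=histology,
        siewert=siewert,
        esophageal_involvement_cm=involvement,
        gastric_involvement_cm=gastric,
        cT=cT,
        cN_upper_middle_mediastinal=cn_um,
        neoadjuvant=neoadjuvant,
        adjuvant=adjuvant,
        approach=approach,
        esophagectomy=esophagectomy,
        gastrectomy=gastrectomy,
        residual=residual,
        os_time_years=round(os_time, 4),
        os_event=os_event,
        rfs_time_years=round(min(rfs_time, os_time), 4),
        rfs_event=rfs_event,
        dissected=dissected,
        metastatic=metastatic,
        recurrence_sites=sites,
        recurrence_time_years=(
            round(recurrence_time, 4) if recurrence_time is not None else None
        ),
    )


def marginal_report(cohort: list[PatientRecord]) -> dict:
    """Realized marginals of a cohort, for Table-1-style checks."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    esoph = np.array([r.esophageal_involvement_cm for r in cohort])
    gastric = np.array([r.gastric_involvement_cm for r in cohort])
    r0r1 = [r for r in cohort if r.residual in ("R0", "R1")]
    report = {
        "n": n,
        "prop_scc": sum(r.histology == "scc" for r in cohort) / n,
        "prop_neoadjuvant": sum(r.neoadjuvant for r in cohort) / n,
        "prop_adjuvant_given_r0r1": (
            sum(r.adjuvant for r in r0r1) / len(r0r1) if r0r1 else float("nan")
        ),
        "prop_cN_upper_middle": (
            sum(r.cN_upper_middle_mediastinal for r in cohort) / n
        ),
        "prop_rt_approach": sum(r.approach == "right_transthoracic" for r in cohort) / n,
        "prop_total_gastrectomy": sum(r.gastrectomy == "total" for r in cohort) / n,
        "prop_r0": sum(r.residual == "R0" for r in cohort) / n,
        "esoph_involvement_median": float(np.median(esoph)),
        "esoph_involvement_iqr": (
            float(np.percentile(esoph, 25)), float(np.percentile(esoph, 75))
        ),
        "gastric_involvement_median": float(np.median(gastric)),
        "gastric_involvement_iqr": (
            float(np.percentile(gastric, 25)), float(np.percentile(gastric, 75))
        ),
    }
    rates = {}
    for s in ALL_STATIONS:
        dissected = [r for r in cohort if r.is_dissected(s)]
        if dissected:
            rates[s] = sum(r.is_metastatic(s) for r in dissected) / len(dissected)
    report["station_metastasis_rates"] = rates
    return report


# --- flat key-value config files -------------------------------------------

def config_to_text(cfg: SimulationConfig) -> str:
    """Serialize a config as ``key = value`` lines (station maps dotted)."""
    lines = []
    for key, value in asdict(cfg).items():
        if isinstance(value, dict):
            for code, v in value.items():
                lines.append(f"{key}.{code} = {v}")
        elif isinstance(value, tuple):
            lines.append(f"{key} = {','.join(repr(v) for v in value)}")
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SimulationConfig:
    """Parse the flat key-value dialect written by :func:`config_to_text`."""
    cfg = SimulationConfig()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if "." in key:
            base, code = key.split(".", 1)
            mapping = getattr(cfg, base, None)
            if not isinstance(mapping, dict):
                raise ValueError(f"line {lineno}: unknown map parameter {base!r}")
            mapping[code] = float(value)
            continue
        if not hasattr(cfg, key):
            raise ValueError(f"line {lineno}: unknown parameter {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, tuple):
            setattr(cfg, key, tuple(float(v) for v in value.split(",")))
        elif isinstance(current, bool):
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        else:
            setattr(cfg, key, float(value))
    cfg.validate()
    return cfg
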