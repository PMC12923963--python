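# Methods

## The index

For lymph-node station *s*, the therapeutic efficacy index for an endpoint
(5-year OS or 5-year RFS) is

TEI_s = (m_s / n_s) · (a_s / m_s) · 100,

with n_s the station's denominator (eligible patients in whom *s* was
dissected, further restricted as below), m_s the patients with pathological
metastasis at *s*, and a_s the subset of those alive / recurrence-free at the
5-year landmark. With every denominator member adequately followed, the two
fractions telescope to a_s / n_s, which is the identity the unit tests assert
on random fixtures. The 5-year survival among metastatic cases is a simple
proportion, not a Kaplan–Meier estimate: the eligibility rule removes exactly
the patients for whom the landmark status is undefined, and the integer
identity is what makes single-decimal indices like 6.7 = 3/45 recoverable
from printed tables. Indices are rounded half-up to one decimal (internal
computation at full precision); all percentages in the package follow the
same convention.

Thresholds: a station "merits dissection" when TEI exceeds 3 for 5-year OS
and 2 for 5-year RFS — strict inequalities, so (3.0, 2.0) classifies as
`neither`. The thresholds encode a consensus that a ≥3-point OS (or ≥2-point
RFS) gain justifies the morbidity of regional dissection; they are
configurable nowhere because they define the classification being reproduced.

## Eligibility and denominators

The analysis population is patients with R0 or R1 resection. A patient
censored for OS before year 5 is excluded as lost to follow-up *unless* a
recurrence was documented by then: with a confirmed recurrence the patient's
disease status is known, and they count as a non-survivor for the landmark
proportion rather than being dropped. One eligibility set (OS-based, with
recurrence as confirmation) is used for both endpoints; an RFS-specific set
would differ only in pathological edge cases. R1 patients are included by
default; the `--r0-only` switch reproduces the sensitivity analysis limited
to complete resections.

Per-station restrictions reflect which operations systematically examine the
basin: upper and middle mediastinal stations (105–109R) are evaluated only in
right-transthoracic subtotal esophagectomies; left-greater-curvature and
distal perigastric stations (4sa–6) only in total gastrectomies. A station
absent from a record's dissection map is treated as not dissected, so
denominators never silently include unexamined patients.

Stratified tables re-derive denominators inside each stratum. Esophageal
involvement is binned region-dependently: the transthoracic-only
(upper/middle mediastinal) stations use a coarse ≤3 / >3 cm split because
their denominators are small; all other stations use ≤1.0, (1.0, 2.0],
(2.0, 3.0], >3.0 cm. Bins are half-open on the left and closed on the right,
matching labels like "1.1–2.0" for lengths recorded to one decimal; a 0 cm
involvement falls in the first bin. Strata with empty denominators render as
`-/-`.

## Survival machinery

Kaplan–Meier is implemented directly: risk sets count subjects with time ≥ t
(events processed before censorings at ties), survival is the product-limit
estimator, variance is Greenwood's formula, and 95% pointwise bands are
computed on the complementary log-log scale and clipped to [0, 1]
(degenerate at S ∈ {0, 1}). The estimator is property-tested to equal the
empirical survivor function without censoring and cross-checked against
lifelines to 1e-10 on random censored datasets; lifelines is never used in
the analysis path. The two-group log-rank test uses the standard
observed-minus-expected statistic with hypergeometric variance referred to
chi-square with 1 df, upper-tail p, no continuity correction; its type-I
error is verified by simulation (2000 replicates of identical exponential
groups with uniform censoring, n = 50 per arm) to lie in [0.035, 0.065] at
α = 0.05.

The 5-year landmark is closed: an event at exactly t = 5.0 counts as an event
before 5 years, while censoring at exactly 5.0 counts as adequate follow-up.
Medians of even-sized sets use the midpoint convention; a KM median is the
smallest time with S(t) ≤ 0.5 and is reported as not reached when the curve
stays above 0.5. Median follow-up is the plain median over OS-censored
patients; a reverse-KM estimate is a known alternative and is deliberately
not substituted for it. First-recurrence sites are counted with multiplicity
per patient (percentages may sum past 100), with the denominator restricted
to recurrences after R0/R1 resection.

Clopper–Pearson intervals come from the beta-quantile closed form of
inverting the two binomial tail tests; the test suite checks them against a
brute-force bisection oracle on the tail probabilities for all k ≤ n ≤ 40
and verifies ≥ 93.5% empirical coverage at p = 0.15, n = 100 over 2000
simulated draws. At the design's assumed 15% mediastinal metastasis rate and
n = 100, the interval width is ≤ 15 percentage points, the bound that sized
the transthoracic arm.

## Synthetic cohort generator

The generator emulates the protocol and data structure the analysis assumes,
at the study's conditions by default: 363 patients; squamous-cell fraction
0.085 (squamous patients have no Siewert type); neoadjuvant chemotherapy
0.333; adjuvant 0.534 after R0/R1; esophageal involvement log-normal with
median 2.0 cm and σ_log = 0.8145 (IQR target 1.0–3.0 cm), gastric median
2.5 cm and σ_log = 0.669 (IQR 1.5–3.7 cm), both truncated at 12 cm by
resampling and recorded to 1 mm; clinical upper/middle-mediastinal nodal
positivity 8.3%; R1 4.1% and R2 2.5%; total gastrectomy in 78% of
transhiatal patients.

The surgical approach follows the protocol rule deterministically: right
transthoracic for squamous histology, adenocarcinoma with involvement
> 3 cm, or mediastinal cN+; transhiatal otherwise. Every approach dissects
the perigastric (1, 2, 3, 7), suprapancreatic (8a, 9, 11p, 11d), para-aortic
(16a2), abdominal hiatal (19, 20) and lower mediastinal (110–112) fields;
the transthoracic route adds the upper and middle mediastinum (105–109R);
total gastrectomy adds the greater-curvature and distal perigastric stations.

Metastasis indicators are drawn independently per dissected station from
per-station base probabilities, with a logistic adjustment for mediastinal
stations: logit p_s(x) = logit p_s + β·x, where x is esophageal involvement
in cm and β defaults to 0.35 per cm. The default base probabilities and the
per-station conditional 5-year survivals are illustrative — per-station
conditional survival is not published anywhere to calibrate to — and are
graded by anatomy (high perigastric, moderate suprapancreatic, low
mediastinal/para-aortic, near-zero distal perigastric).

Death times are Weibull (shape 1 by default, i.e. exponential) with the
scale solved per patient so that S(5) equals the patient's conditional
5-year survival: the maximum of the per-station values over their metastatic
stations, or 0.80 for node-negative patients. Administrative censoring is
uniform on [5.0, 7.4] years — its lower bound at exactly 5 years guarantees
that inadequate follow-up arises only through the explicit
loss-to-follow-up mechanism (probability 0.011 of an additional uniform
censoring time below 5 years). Recurrence precedes death in 85% of
trajectories, placed an exponential lead time (mean 1.33 years) before the
death time and floored at 0.01; RFS ≤ OS holds by construction. Recurrence
sites are drawn per site with weights shaped like observed first-recurrence
patterns (para-aortic and mediastinal nodal recurrences prominent,
multi-site common).

Reproducibility: one `SeedSequence` per cohort; each patient's variates come
from a substream spawned by patient index, so identical (config, seed) give
byte-identical cohorts independent of iteration order.

What the generator does **not** emulate — and therefore what passing tests do
not show about real data: cross-station dependence of metastasis (stations
are independent given covariates, adequate because the TEI is computed
marginally per station), confounding between approach selection and
prognosis beyond the involvement pathway, stage-specific survival structure,
non-proportional hazards, or any attempt to fit the real cohort's joint
distribution. Parameter-recovery tests (metastasis probability 0.15 and
conditional survival 0.30 at n = 5000 recovering TEI ≈ 4.5 within three
binomial standard errors) validate the pipeline's arithmetic under the
generative model, not the model's realism.

## Recommendation engine

The rule engine encodes the dissection algorithm implied by the index
analysis. Always dissect the proximal perigastric {1, 2, 3, 7} and
suprapancreatic {8a, 9, 11p, 11d} fields; always avoid the distal perigastric
{4d, 5, 6}, left greater curvature {4sa, 4sb} and para-aortic {16a2} fields;
add the lower mediastinum {110, 111, 112} when esophageal involvement
exceeds 2 cm and the middle mediastinum {107, 108, 109L, 109R} when it
exceeds 3 cm; the upper mediastinum {105, 106L, 106R} becomes a conditional
field above 3 cm or with mediastinal cN+, dissected only for cN+ patients or
those without neoadjuvant chemotherapy. Approach: transhiatal suffices at
≤ 2 cm without mediastinal cN+; the right transthoracic route is required
above 3 cm or with cN+; either is acceptable in between. Involvement is the
post-treatment measurement when neoadjuvant therapy was given. Thresholds
are strict ("exceeding"): exactly 2.0 cm takes the transhiatal-sufficient
branch and exactly 3.0 cm the either-approach branch. Histology does not
enter the rule.

Station 11d is kept in the always-dissect set because the suprapancreatic
field is recommended as a whole even though 11d individually sits below both
thresholds; `include_11d=False` exposes the tension by dropping it. The
engine is monotone by construction: enlarging involvement never removes a
station or relaxes the transthoracic requirement, a property the tests sweep.

## Numerical and interface conventions

Times are years from surgery (no calendar dates). The cohort CSV dialect is
UTF-8, comma-separated, header mandatory, booleans 0/1, missing numerics
empty, recurrence sites a semicolon-joined sorted list, plus
`dissected_<code>` / `metastatic_<code>` column pairs for all 26 stations.
Reading validates every record (metastasis requires dissection, RFS ≤ OS,
death without recurrence is an RFS event, recurrence fields consistent,
squamous histology ↔ Siewert not-applicable) and either logs or, in strict
mode, aborts on the first violation. Rendered tables order stations by
region, mediastinum cranio-caudally then abdomen, and are byte-deterministic.

Problem sizes in the test suite — 500–10 000-patient simulated cohorts, 2000
replicates for the log-rank and coverage simulations, 100 datasets for the
KM cross-check — were chosen as the smallest sizes at which the binomial and
Monte-Carlo tolerances quoted above are meaningful.

## Known limitations

- The TEI is a descriptive index, not a causal estimate of dissection
  benefit; no multiplicity adjustment is applied across the 26 stations.
- One OS-based eligibility set serves both endpoints (flagged above).
- Mediastinal-station denominators are structurally entangled with approach
  selection, which itself depends on involvement length; the generator
  reproduces this constraint rather than removing it.
- The gastric-involvement analogue of the involvement stratifier is not
  built in; bin edges for it would be configurable with no claimed default.
- Generator survival parameters are illustrative; absolute TEI magnitudes
  from simulated cohorts should not be compared with published values.
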