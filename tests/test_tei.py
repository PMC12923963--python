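import numpy as np
import pytest
from scipy import stats

from nodal_tei.fixtures import (
    screening_fixture_cohort,
    station_fixture_cohort,
)
from nodal_tei.simulate import SimulationConfig, simulate_cohort
from nodal_tei.stations import ALL_STATIONS
from nodal_tei.tei import (
    BOTH_EXCEED,
    NEITHER,
    SINGLE_EXCEED,
    classify,
    clopper_pearson,
    station_denominator,
    station_tei,
    stratified_tei,
    tei_eligible,
    tei_table,
)
from nodal_tei.utils import round_half_up


class TestEligibility:
    def test_study_sized_fixture_retains_350(self):
        cohort = screening_fixture_cohort()  # 339 R0 + 15 R1 + 9 R2, 4 lost
        assert len(tei_eligible(cohort)) == 350

    def test_all_r2_gives_empty_subset(self):
        cohort = [p.copy(residual="R2") for p in station_fixture_cohort("1", 5, 0, 0)]
        assert tei_eligible(cohort) == []

    def test_censored_with_confirmed_recurrence_is_retained(self):
        rec = station_fixture_cohort("1", 1, 0, 0)[0]
        rec.os_time_years, rec.os_event = 3.0, False
        rec.rfs_time_years, rec.rfs_event = 2.0, True
        rec.recurrence_time_years = 2.0
        rec.recurrence_sites = frozenset({"liver"})
        assert tei_eligible([rec]) == [rec]


class TestDenominators:
    def test_upper_middle_mediastinal_restricted_to_rt_subtotal(self):
        rt = station_fixture_cohort("108", 117, 0, 0)
        th = station_fixture_cohort("1", 100, 0, 0)
        for p in th:  # transhiatal patients with 108 nonetheless dissected
            p.dissected["108"] = True
        denom = station_denominator(tei_eligible(rt + th), "108")
        assert len(denom) == 117
        assert all(p.approach == "right_transthoracic" for p in denom)

    def test_greater_curvature_restricted_to_total_gastrectomy(self):
        tg = station_fixture_cohort("4d", 174, 0, 0)
        pg = station_fixture_cohort("1", 50, 0, 0)
        for p in pg:  # proximal gastrectomy, 4d dissected anyway
            p.dissected["4d"] = True
        denom = station_denominator(tei_eligible(tg + pg), "4d")
        assert len(denom) == 174

    def test_nobody_dissected_gives_empty_denominator(self):
        cohort = station_fixture_cohort("1", 10, 0, 0)
        assert station_denominator(tei_eligible(cohort), "5") == []


class TestClopperPearson:
    def test_closed_form_bounds_at_zero_and_full_counts(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)
        low, high = clopper_pearson(10, 10)
        assert low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)  # ~0.6915
        assert high == 1.0

    def test_interval_width_at_assumed_mediastinal_rate(self):
        # the design's sample-size rationale: width <= 15 points at 15/100
        low, high = clopper_pearson(15, 100)
        assert high - low <= 0.15

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)

    def test_bounds_satisfy_defining_tail_equalities(self):
        """The interval endpoints solve the binomial tail equations:
        P(X >= k | p = low) = alpha/2 and P(X <= k | p = high) = alpha/2."""
        for n in range(1, 16):
            for k in range(n + 1):
                low, high = clopper_pearson(k, n)
                if k > 0:
                    assert stats.binom.sf(k - 1, n, low) == pytest.approx(
                        0.025, abs=1e-9
                    )
                if k < n:
                    assert stats.binom.cdf(k, n, high) == pytest.approx(
                        0.025, abs=1e-9
                    )


class TestStationTEI:
    @pytest.mark.parametrize(
        "station,n,k,surv,involvement,expected",
        [
            ("108", 45, 5, 3, 3.5, 6.7),
            ("110", 81, 8, 4, 2.5, 4.9),
            ("106L", 39, 2, 2, 2.0, 5.1),
        ],
    )
    def test_worked_examples_at_reported_denominators(
        self, station, n, k, surv, involvement, expected
    ):
        cohort = station_fixture_cohort(
            station, n, k, surv, esophageal_involvement_cm=involvement
        )
        res = station_tei(tei_eligible(cohort), station)
        assert res.n_denominator == n
        assert res.tei_os == expected

    def test_zero_metastasis_gives_zero_index(self):
        cohort = station_fixture_cohort("9", 40, 0, 0)
        res = station_tei(tei_eligible(cohort), "9")
        assert res.tei_os == 0.0 and res.tei_rfs == 0.0
        assert res.ci_low == 0.0

    def test_lost_patient_removed_before_the_rate(self):
        # 10 dissected, 1 lost upstream -> 9; 3 metastatic, 1 survivor:
        # (3/9) * (1/3) * 100 = 11.1
        cohort = station_fixture_cohort("9", 10, 3, 1)
        lost = next(p for p in cohort if not p.metastatic)
        lost.os_time_years, lost.os_event = 2.0, False
        lost.rfs_time_years, lost.rfs_event = 2.0, False
        res = station_tei(tei_eligible(cohort), "9")
        assert res.n_denominator == 9
        assert res.tei_os == 11.1

    def test_empty_denominator_flagged_not_evaluable(self):
        cohort = station_fixture_cohort("1", 5, 0, 0)
        res = station_tei(tei_eligible(cohort), "5")
        assert not res.evaluable
        assert res.tei_os is None and res.metastasis_rate is None

    def test_decomposition_identity_on_random_fixtures(self):
        """With every denominator member adequately followed, TEI/100 is
        exactly (5-year survivors with station metastasis) / denominator."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(0, n + 1))
            s = int(rng.integers(0, k + 1))
            cohort = station_fixture_cohort("9", n, k, s)
            res = station_tei(tei_eligible(cohort), "9")
            assert res.tei_os == round_half_up(100.0 * s / n, 1)

    def test_invariant_to_ordering_and_duplication(self):
        cohort = station_fixture_cohort("9", 30, 6, 2)
        base = station_tei(tei_eligible(cohort), "9")
        shuffled = list(cohort)
        np.random.default_rng(4).shuffle(shuffled)
        doubled = cohort + [p.copy(patient_id=p.patient_id + "b") for p in cohort]
        assert station_tei(tei_eligible(shuffled), "9").tei_os == base.tei_os
        dup = station_tei(tei_eligible(doubled), "9")
        assert dup.metastasis_rate == pytest.approx(base.metastasis_rate)
        assert dup.tei_os == base.tei_os


class TestClassification:
    @pytest.mark.parametrize(
        "tei_os,tei_rfs,expected",
        [
            (17.6, 13.8, BOTH_EXCEED),
            (3.1, 1.5, SINGLE_EXCEED),
            (2.0, 2.5, SINGLE_EXCEED),
            (3.0, 2.0, NEITHER),  # thresholds are strict
            (0.0, 0.0, NEITHER),
        ],
    )
    def test_threshold_rules(self, tei_os, tei_rfs, expected):
        assert classify(tei_os, tei_rfs) == expected


class TestStratification:
    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError):
            stratified_tei([], stratifier="age")

    def test_two_stratum_denominators_partition_the_total(self, default_cohort):
        eligible = tei_eligible(default_cohort)
        tables = stratified_tei(eligible, stations=["110"], stratifier="neoadjuvant")
        total = station_tei(eligible, "110").n_denominator
        assert (
            tables["no"][0].n_denominator + tables["yes"][0].n_denominator == total
        )

    def test_missing_stratum_rendered_not_evaluable(self):
        cohort = station_fixture_cohort("4sa", 20, 1, 1)  # all adenocarcinoma
        tables = stratified_tei(
            tei_eligible(cohort), stations=["4sa"], stratifier="histology"
        )
        assert not tables["scc"][0].evaluable
        assert tables["adenocarcinoma"][0].evaluable

    def test_involvement_bins_use_region_specific_edges(self):
        cohort = station_fixture_cohort("110", 10, 0, 0, esophageal_involvement_cm=1.0)
        tables = stratified_tei(
            tei_eligible(cohort), stations=["110"], stratifier="esophageal_involvement_bins"
        )
        assert set(tables) == {"<=1.0", "1.1-2.0", "2.1-3.0", ">3.0"}
        # boundary 1.0 cm falls in the closed-right first bin
        assert tables["<=1.0"][0].n_denominator == 10
        upper = station_fixture_cohort("108", 10, 0, 0, esophageal_involvement_cm=3.0)
        coarse = stratified_tei(
            tei_eligible(upper), stations=["108"], stratifier="esophageal_involvement_bins"
        )
        assert set(coarse) == {"<=3.0", ">3.0"}
        assert coarse["<=3.0"][0].n_denominator == 10

    def test_mediastinal_tei_rises_with_involvement_in_simulation(self):
        """With a positive involvement effect on mediastinal metastasis odds,
        the station-110 index in the top involvement bin clearly exceeds the
        bottom bin at large n."""
        cfg = SimulationConfig(n_patients=20000, seed=31, mediastinal_slope=0.8)
        eligible = tei_eligible(simulate_cohort(cfg))
        tables = stratified_tei(
            eligible, stations=["110"], stratifier="esophageal_involvement_bins"
        )
        lo = tables["<=1.0"][0].tei_os
        hi = tables[">3.0"][0].tei_os
        assert hi > lo

    def test_full_table_covers_catalog(self, default_cohort):
        results = tei_table(tei_eligible(default_cohort))
        assert [r.station for r in results] == list(ALL_STATIONS)
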