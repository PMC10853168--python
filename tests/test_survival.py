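"""Cox/KM contracts, cutoff scan behavior, LOH classification, strata."""

import math

import numpy as np
import pandas as pd
import pytest

from hapscore import (
    DataError,
    SurvivalRecord,
    classify_loh,
    cox_hr,
    km_logrank,
    scan_cutoff,
    stratify_haps_loh,
)
from hapscore.survival import km_median


def make_records(times, events, prefix="p"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestCox:
    def test_mirrored_groups_hr_one(self):
        times = [3.0, 5.0, 8.0, 13.0, 21.0]
        recs = make_records(times + times, [1] * 10)
        res = cox_hr(recs, [0] * 5 + [1] * 5)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_recovers_twofold_hazard(self):
        rng = np.random.default_rng(11)
        n = 2000
        g = np.repeat([0, 1], n // 2)
        lam = np.where(g == 1, 2.0, 1.0)
        t = rng.exponential(1 / lam)
        res = cox_hr(make_records(t, np.ones(n, int)), g)
        assert 1.85 <= res.hr <= 2.15
        assert res.ci_low < res.hr < res.ci_high

    def test_all_censored_rejected(self):
        recs = make_records([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(DataError, match="censored"):
            cox_hr(recs, [0, 0, 1, 1])

    def test_single_member_group_rejected(self):
        recs = make_records([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(DataError, match="2 patients"):
            cox_hr(recs, [0, 1, 1, 1])

    def test_label_complement_reciprocity(self):
        rng = np.random.default_rng(5)
        n = 120
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 0.6, 1.0))
        e = (rng.random(n) < 0.85).astype(int)
        recs = make_records(t, e)
        r1 = cox_hr(recs, g)
        r2 = cox_hr(recs, 1 - g)
        assert r1.hr * r2.hr == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_lifelines(self):
        # lifelines' own Newton stops earlier; agreement at its precision
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        n = 80
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 0.5, 1.0))
        e = (rng.random(n) < 0.9).astype(int)
        res = cox_hr(make_records(t, e), g)
        df = pd.DataFrame({"t": t, "e": e, "g": g})
        cph = CoxPHFitter().fit(df, "t", "e",
                                fit_options={"precision": 1e-10})
        assert res.hr == pytest.approx(
            float(np.exp(cph.summary.loc["g", "coef"])), abs=1e-4
        )

    def test_adjusted_fit_includes_covariates(self):
        rng = np.random.default_rng(31)
        n = 150
        g = rng.integers(0, 2, n)
        age = rng.normal(60, 8, n)
        lam = np.exp(0.7 * g + 0.02 * (age - 60))
        t = rng.exponential(1 / lam)
        recs = [
            SurvivalRecord(f"p{i}", float(t[i]), 1, covariates={"age": age[i]})
            for i in range(n)
        ]
        unadj = cox_hr(recs, g)
        adj = cox_hr(recs, g, adjust=["age"])
        assert adj.hr > 1  # harmful group effect survives adjustment
        assert adj.hr != pytest.approx(unadj.hr, abs=1e-9)


class TestKM:
    def test_median_from_hand_km_table(self):
        # S(2)=0.75, S(4)=0.50 -> first time with S <= 0.5 is 4
        assert km_median(np.array([2.0, 4, 6, 8]), np.ones(4, int)) == 4.0

    def test_median_not_reached(self):
        assert km_median(np.array([2.0, 4, 6, 8]),
                         np.array([1, 0, 0, 0])) == math.inf

    def test_identical_groups_logrank_p_one(self):
        times = [2.0, 4, 6, 8, 11]
        recs = make_records(times + times, [1] * 10)
        res = km_logrank(recs, [0] * 5 + [1] * 5)
        assert res.logrank_p == pytest.approx(1.0)
        assert res.medians["high"] == res.medians["low"]

    def test_shifted_group_preserves_median_order(self):
        t_low = [2.0, 4, 6, 8]
        t_high = [12.0, 14, 16, 18]
        recs = make_records(t_low + t_high, [1] * 8)
        res = km_logrank(recs, [0] * 4 + [1] * 4)
        assert res.medians["high"] > res.medians["low"]

    def test_km_curve_non_increasing_starts_at_one(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        e = (rng.random(40) < 0.8).astype(int)
        order = np.argsort(t)
        ts, es = t[order], e[order]
        s, curve = 1.0, [1.0]
        for tau in np.unique(ts[es == 1]):
            at_risk = np.sum(ts >= tau)
            d = np.sum((ts == tau) & (es == 1))
            s *= 1 - d / at_risk
            curve.append(s)
        assert curve[0] == 1.0
        assert all(a >= b for a, b in zip(curve, curve[1:]))

    def test_logrank_agrees_with_scikit_survival(self):
        from sksurv.compare import compare_survival

        rng = np.random.default_rng(17)
        n = 100
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 0.7, 1.0)) + 0.01
        e = (rng.random(n) < 0.85).astype(int)
        res = km_logrank(make_records(t, e), g)
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)],
                     dtype=[("event", "?"), ("time", "<f8")])
        _, p = compare_survival(y, g)
        assert res.logrank_p == pytest.approx(p, abs=1e-10)


class TestScan:
    @staticmethod
    def threshold_cohort(seed, n=500, theta=10.0, hr=0.4, censor_to=88.0):
        rng = np.random.default_rng(seed)
        scores = rng.normal(10, 3, n)
        lam0 = math.log(2) / 12
        lam = np.where(scores >= theta, hr * lam0, lam0)
        t_ev = rng.exponential(1 / lam)
        c = rng.uniform(0, censor_to, n)
        e = (t_ev <= c).astype(int)
        recs = make_records(np.minimum(t_ev, c), e)
        return pd.Series(scores, index=[r.patient_id for r in recs]), recs

    def test_chosen_hr_is_grid_minimum_up_to_tiebreak(self):
        scores, recs = self.threshold_cohort(1)
        res = scan_cutoff(scores, recs)
        assert res.chosen_hr <= res.table["hr"].min() * 1.01 + 1e-12

    def test_grid_respects_group_size_constraint(self):
        scores, recs = self.threshold_cohort(2)
        res = scan_cutoff(scores, recs)
        assert (res.table["n_high"] >= res.min_group_size).all()
        assert (res.table["n_low"] >= res.min_group_size).all()

    def test_recovery_near_generative_threshold(self):
        # the estimator's real resolution: within 0.25 score units most runs
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            scores, recs = self.threshold_cohort(10_000 + rep)
            res = scan_cutoff(scores, recs)
            hits += abs(res.chosen_cutoff - 10.0) <= 0.25
        assert hits >= 0.75 * n_rep

    def test_null_scan_optimism_is_reported(self):
        # with no true effect the minimized HR is biased below 1:
        # the scan's multiplicity optimism, surfaced not corrected
        chosen = []
        for rep in range(8):
            scores, recs = self.threshold_cohort(60_000 + rep, n=250, hr=1.0)
            res = scan_cutoff(scores, recs)
            chosen.append(res.chosen_hr)
            assert res.rationale in ("lowest_hr", "no significant cutpoint")
        assert np.mean(np.array(chosen) < 1.0) >= 0.75

    def test_two_point_score_forces_single_cutoff(self):
        rng = np.random.default_rng(9)
        n = 60
        scores = pd.Series(np.repeat([0.0, 1.0], n // 2),
                           index=[f"p{i}" for i in range(n)])
        t = rng.exponential(10, n)
        recs = make_records(t, np.ones(n, int))
        res = scan_cutoff(scores, recs)
        assert len(res.table) == 1
        assert res.chosen_cutoff == 1.0

    def test_constant_scores_rejected(self):
        recs = make_records(np.arange(1, 26), np.ones(25, int))
        scores = pd.Series(5.0, index=[r.patient_id for r in recs])
        with pytest.raises(DataError, match="constant"):
            scan_cutoff(scores, recs)

    def test_too_few_patients_rejected(self):
        recs = make_records(np.arange(1, 11), np.ones(10, int))
        scores = pd.Series(np.arange(10.0), index=[r.patient_id for r in recs])
        with pytest.raises(DataError, match="20"):
            scan_cutoff(scores, recs)


class TestLOH:
    def test_loss_requires_cn_and_significance(self):
        intact = {"A": 1.0, "B": 1.0}
        ps = {"A": 0.5, "B": 0.5}
        st = classify_loh("PT1", {**intact, "C": 0.4}, {**ps, "C": 0.005})
        assert st.per_locus["C"] == "LOH"
        assert st.status == "LOH"

    def test_nonsignificant_imbalance_stays_intact(self):
        st = classify_loh("PT1", {"A": 0.4, "B": 1.0, "C": 1.0},
                          {"A": 0.02, "B": 0.5, "C": 0.5})
        assert st.per_locus["A"] == "intact"
        assert st.status == "intact"

    def test_normal_copy_number_intact(self):
        st = classify_loh("PT1", {"A": 1.0, "B": 1.1, "C": 0.9},
                          {"A": 0.5, "B": 0.9, "C": 0.7})
        assert st.status == "intact"

    def test_cn_only_rule(self):
        st = classify_loh("PT1", {"A": 0.4, "B": 1.0, "C": 1.0},
                          {"A": 0.02, "B": 0.5, "C": 0.5}, rule="cn_only")
        assert st.per_locus["A"] == "LOH"

    def test_missing_locus_rejected(self):
        with pytest.raises(DataError, match="locus C"):
            classify_loh("PT1", {"A": 1.0, "B": 1.0}, {"A": 0.5, "B": 0.5})


class TestStrata:
    def test_four_mode_covers_all_combinations(self):
        haps = {"p1": "high", "p2": "high", "p3": "low", "p4": "low"}
        loh = {"p1": "intact", "p2": "LOH", "p3": "intact", "p4": "LOH"}
        out = stratify_haps_loh(haps, loh, collapse="four")
        assert set(out.values()) == {
            "HAPShigh/HLAintact", "HAPShigh/HLALOH",
            "HAPSlow/HLAintact", "HAPSlow/HLALOH",
        }

    def test_two_mode_pools_non_reference(self):
        haps = {"p1": "high", "p2": "high", "p3": "low"}
        loh = {"p1": "intact", "p2": "LOH", "p3": "intact"}
        out = stratify_haps_loh(haps, loh, collapse="two")
        assert out == {"p1": "HAPShigh/HLAintact", "p2": "other",
                       "p3": "other"}

    def test_missing_label_rejected(self):
        with pytest.raises(DataError, match="p2"):
            stratify_haps_loh({"p1": "high", "p2": "low"}, {"p1": "intact"})
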