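import itertools

import numpy as np
import pandas as pd
import pytest

from treatmark.validate import (MarkerCandidate, PlotResult, base_plot,
                                best_dmr_positions, evaluate_candidate,
                                rank_and_aggregate, table1_filter,
                                validation_plots, vp_product)

from conftest import make_patient


def _cohort(n, seed=0, hazard=lambda high, treated: 0.2, treated_frac=0.5,
            high_frac=0.5, censor_rate=0.1):
    """Small custom cohort with an explicit per-patient hazard law; the
    feature value is bimodal around the high indicator."""
    rng = np.random.default_rng(seed)
    patients, values, treated_ids, high = {}, {}, [], {}
    for i in range(n):
        cid = f"p{i}"
        is_treated = rng.random() < treated_frac
        is_high = rng.random() < high_frac
        h = hazard(is_high, is_treated)
        t_death = rng.exponential(1.0 / h)
        t_cens = rng.exponential(1.0 / censor_rate)
        dead = t_death <= t_cens
        patients[cid] = make_patient(cid, vital_status="dead" if dead else "alive",
                                     time_years=float(min(t_death, t_cens)) + 1e-9)
        values[cid] = float(rng.normal(4.0 if is_high else 1.0, 0.4))
        high[cid] = is_high
        if is_treated:
            treated_ids.append(cid)
    outcome = {cid: "positive" if p.vital_status == "alive" else "negative"
               for cid, p in patients.items()}
    return patients, pd.Series(values), tuple(treated_ids), outcome, high


class TestTable1Filter:
    def test_exhaustive_truth_table(self):
        passing = [(b, u, d)
                   for b, u, d in itertools.product(["UP", "DOWN"], repeat=3)
                   if table1_filter(b, u, d)]
        assert sorted(passing) == sorted([
            ("UP", "UP", "UP"), ("UP", "UP", "DOWN"),
            ("DOWN", "UP", "DOWN"), ("DOWN", "DOWN", "DOWN")])

    @pytest.mark.parametrize("labels,expected", [
        (("UP", "UP", "DOWN"), True),
        (("UP", "DOWN", "UP"), False),
        (("DOWN", "UP", "DOWN"), True),
    ])
    def test_published_compositions(self, labels, expected):
        assert table1_filter(*labels) is expected


class TestVpProduct:
    def test_boundary_is_strict(self):
        product, ok = vp_product(0.05, 0.05)
        assert product == pytest.approx(0.0025)
        assert not ok

    def test_low_p_offsets_nonsignificant_partner(self):
        product, ok = vp_product(0.001, 0.9)
        assert product == pytest.approx(9e-4)
        assert ok

    def test_two_moderate_ps_fail(self):
        assert vp_product(0.2, 0.2) == (pytest.approx(0.04), False)

    def test_symmetric_monotone_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b = rng.uniform(0, 1, 2)
            pab, _ = vp_product(a, b)
            pba, _ = vp_product(b, a)
            assert pab == pba <= min(a, b)
            bigger, _ = vp_product(min(a * 1.5, 1.0), b)
            assert bigger >= pab


class TestBasePlot:
    def test_single_threshold_equals_direct_computation(self):
        from treatmark.stratify import mean_of_medians, stratify
        from treatmark.survival import cox_group_p, make_observations
        patients, values, treated, outcome, _ = _cohort(120, seed=3)
        tv = values.loc[list(treated)]
        res = base_plot(tv, outcome, patients, [0.0], feature_id="f")
        vp = tv[[c for c in tv.index if outcome[c] == "positive"]]
        vn = tv[[c for c in tv.index if outcome[c] == "negative"]]
        strat = stratify(tv, mean_of_medians(vp, vn), 0.0)
        group_of = {c: 1 for c in strat.up_ids} | {c: 0 for c in strat.down_ids}
        direct = cox_group_p(make_observations(
            patients, strat.up_ids + strat.down_ids, group_of))
        assert res.p_value == pytest.approx(direct.p_value)
        assert res.threshold_pct == 0.0

    def test_more_thresholds_never_worsen_best_p(self):
        patients, values, treated, outcome, _ = _cohort(150, seed=5)
        tv = values.loc[list(treated)]
        p0 = base_plot(tv, outcome, patients, [0.0]).p_value
        p_all = base_plot(tv, outcome, patients, [0.0, 5.0, 10.0]).p_value
        assert p_all <= p0

    def test_protective_high_stratum_labeled_up(self):
        hits = 0
        for seed in range(20):
            patients, values, treated, outcome, _ = _cohort(
                300, seed=seed, treated_frac=1.0,
                hazard=lambda high, tr: 0.08 if high else 0.8)
            res = base_plot(values.loc[list(treated)], outcome, patients, [0.0])
            if res is not None and res.label == "UP" and res.p_value < 0.05:
                hits += 1
        assert hits >= 18

    def test_null_feature_p_is_calibrated(self):
        ps = []
        patients, values, treated, outcome, _ = _cohort(200, seed=77)
        rng = np.random.default_rng(78)
        tv_index = [c for c in values.index if c in set(treated)]
        for _ in range(400):
            null_values = pd.Series(rng.normal(0, 1, len(tv_index)) + 5,
                                    index=tv_index)
            res = base_plot(null_values, outcome, patients, [0.0])
            ps.append(res.p_value)
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.02 <= frac <= 0.08


class TestValidationPlots:
    def test_universal_marker_shows_no_arm_difference(self):
        """A stratum effect applied regardless of treatment leaves treated
        and untreated indistinguishable inside each stratum."""
        ps = []
        for seed in range(20):
            patients, values, treated, outcome, _ = _cohort(
                300, seed=seed,
                hazard=lambda high, tr: 0.5 if high else 0.1)
            up_val, down_val = validation_plots(values, outcome, treated,
                                                patients, [0.0])
            for v in (up_val, down_val):
                if v is not None:
                    ps.append(v.p_value)
        assert np.median(ps) > 0.2

    def test_treatment_specific_marker_detected_in_up_stratum(self):
        labels, ps = [], []
        for seed in range(20):
            patients, values, treated, outcome, _ = _cohort(
                400, seed=seed,
                hazard=lambda high, tr: 0.05 if (high and tr) else 0.5)
            up_val, _ = validation_plots(values, outcome, treated,
                                         patients, [0.0])
            labels.append(up_val.label)
            ps.append(up_val.p_value)
        assert labels.count("UP") >= 18
        assert np.median(ps) < 0.01

    def test_identical_arms_rarely_significant(self):
        n_ok = 0
        for seed in range(20):
            patients, values, treated, outcome, _ = _cohort(250, seed=100 + seed)
            up_val, down_val = validation_plots(values, outcome, treated,
                                                patients, [0.0])
            if all(v.p_value > 0.05 for v in (up_val, down_val) if v):
                n_ok += 1
        assert n_ok >= 15


class TestEvaluateCandidate:
    def test_no_untreated_patients_drops_candidate(self):
        patients, values, treated, outcome, _ = _cohort(80, seed=1,
                                                        treated_frac=1.0)
        cand = evaluate_candidate("f", "gene", 1.0, values, treated, outcome,
                                  patients, [0.0])
        assert cand is None

    def test_treatment_specific_marker_passes_pipeline_filter(self):
        n_pass = 0
        for seed in range(10):
            patients, values, treated, outcome, _ = _cohort(
                400, seed=seed,
                hazard=lambda high, tr: 0.04 if (high and tr) else 0.5)
            cand = evaluate_candidate("f", "gene", 1.0, values, treated,
                                      outcome, patients, [0.0])
            if cand is not None and cand.passed_filter:
                n_pass += 1
        assert n_pass >= 8


class TestDmrPositions:
    def _dmr(self):
        from treatmark.diffexp import FeatureResult
        return FeatureResult("chrX:100-161", "dmr", 0.2, 1e-4, 1e-3, "up",
                             chrom="chrX", start=100, end=161,
                             positions=(100, 120, 140, 160))

    def test_single_position_selected_for_every_threshold(self):
        from treatmark.diffexp import FeatureResult
        dmr = FeatureResult("chrX:100-101", "dmr", 0.2, 1e-4, 1e-3, "up",
                            chrom="chrX", start=100, end=101, positions=(100,))
        patients, values, treated, outcome, _ = _cohort(100, seed=2)
        betas = pd.DataFrame([np.clip(values / 8, 0, 1)],
                             index=pd.MultiIndex.from_tuples(
                                 [("chrX", 100)], names=["chrom", "pos"]))
        mapping = best_dmr_positions(dmr, betas, treated, outcome, patients,
                                     [0.0, 5.0, 10.0])
        assert mapping == {0.0: 100, 5.0: 100, 10.0: 100}

    def test_signal_bearing_position_wins(self):
        rng = np.random.default_rng(12)
        hits = 0
        for seed in range(10):
            patients, values, treated, outcome, high = _cohort(
                300, seed=seed,
                hazard=lambda h, tr: 0.05 if (h and tr) else 0.5)
            rows = []
            for pos in (100, 120, 140, 160):
                if pos == 140:  # only this CpG tracks the survival stratum
                    row = np.clip(values / 8.0, 0.01, 0.99)
                else:
                    row = pd.Series(rng.beta(5, 5, len(values)),
                                    index=values.index)
                rows.append(row)
            betas = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
                [("chrX", p) for p in (100, 120, 140, 160)],
                names=["chrom", "pos"]))
            mapping = best_dmr_positions(self._dmr(), betas, treated, outcome,
                                         patients, [0.0])
            if mapping.get(0.0) == 140:
                hits += 1
        assert hits >= 9


class TestRankAndAggregate:
    def _candidate(self, fid, set_id, vp):
        plot = PlotResult(fid, "base", 0.0, vp ** 0.5, "UP", 50, -1.0)
        val = PlotResult(fid, "up_validation", 0.0, vp ** 0.5, "UP", 80, -1.0)
        return MarkerCandidate(feature_id=fid, set_id=set_id, kind="gene",
                               base=plot, up_val=val, down_val=None,
                               vp_product=vp, passed_filter=True, effect=1.0)

    def test_geometric_mean_of_two_products(self):
        cands = [self._candidate("a", "s1", 1e-4),
                 self._candidate("b", "s1", 1e-6)]
        _, summary = rank_and_aggregate(cands)
        assert summary.loc[0, "geometric_mean_vp"] == pytest.approx(1e-5)

    def test_single_candidate_mean_is_itself(self):
        _, summary = rank_and_aggregate([self._candidate("a", "s1", 3e-4)])
        assert summary.loc[0, "geometric_mean_vp"] == pytest.approx(3e-4)

    def test_ranking_matches_plain_sort(self):
        rng = np.random.default_rng(14)
        vps = rng.uniform(1e-8, 2e-3, 30)
        cands = [self._candidate(f"f{i}", f"s{i % 3}", float(v))
                 for i, v in enumerate(vps)]
        ranked, summary = rank_and_aggregate(cands)
        assert list(ranked["vp_product"]) == sorted(vps)
        # summary ordered by member count, descending
        assert list(summary["n_candidates"]) == \
            sorted(summary["n_candidates"], reverse=True)

    def test_empty_input_yields_empty_tables(self):
        ranked, summary = rank_and_aggregate([])
        assert ranked.empty and summary.empty
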