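"""Coupling-table assembly filters, change categorization, amplitude
residualization and the normality screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import songgaps as sg
from songgaps import stats
from songgaps.stats import (
    NormalityScreen,
    build_change_table,
    categorize_changes,
    change_coupling_analysis,
    compare_transition_types,
    residualize_amplitude,
    screen_normality,
)

from conftest import events_from_sequences


class TestCategorize:
    def test_identical_distributions_unchanged(self):
        cats = categorize_changes({"x": 50, "y": 50}, {"x": 50, "y": 50})
        assert {c.category for c in cats.values()} == {"unchanged"}

    def test_large_shift_detected(self):
        # 2x2 chi-square without continuity correction for {90,10} vs {50,50}:
        # 200*(90*50-10*50)^2/(100*100*140*60) = 38.095
        cats = categorize_changes({"x": 90, "y": 10}, {"x": 50, "y": 50})
        assert cats["x"].statistic == pytest.approx(38.0952380952, rel=1e-9)
        assert cats["x"].category == "decreased"
        assert cats["y"].category == "increased"
        # cross-check against scipy's implementation
        ref = chi2_contingency([[90, 10], [50, 50]], correction=False)
        assert cats["x"].statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert cats["x"].pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_lrt_variant_agrees_in_direction(self):
        chi = categorize_changes({"x": 90, "y": 10}, {"x": 50, "y": 50})
        lrt = categorize_changes({"x": 90, "y": 10}, {"x": 50, "y": 50},
                                 method="lrt")
        assert lrt["x"].category == chi["x"].category == "decreased"
        ref = chi2_contingency([[90, 10], [50, 50]], correction=False,
                               lambda_="log-likelihood")
        assert lrt["x"].statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            categorize_changes({"x": 0, "y": 0}, {"x": 5, "y": 5})

    def test_type_one_error_near_nominal(self):
        # both conditions drawn from the same distribution: each target is
        # flagged at ~alpha
        rng = np.random.default_rng(2)
        reps, hits = 800, 0
        for _ in range(reps):
            a = rng.multinomial(60, [0.6, 0.4])
            b = rng.multinomial(60, [0.6, 0.4])
            cats = categorize_changes({"x": int(a[0]), "y": int(a[1])},
                                      {"x": int(b[0]), "y": int(b[1])})
            hits += cats["x"].category != "unchanged"
        assert 0.02 <= hits / reps <= 0.08


class TestNormalityScreen:
    def test_log10_values_returned(self):
        scr = screen_normality(np.array([1.0, 10.0, 100.0, 5.0, 2.0]))
        assert isinstance(scr, NormalityScreen)
        assert set(np.round(scr.log10_values, 6)) >= {0.0, 1.0, 2.0}

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            screen_normality(np.array([1.0, 0.0, 2.0]))
        with pytest.raises(ValueError):
            screen_normality(np.array([1.0, 2.0]))

    def test_lognormal_sample_normalized_by_transform(self):
        rng = np.random.default_rng(3)
        vals = 10 ** rng.normal(2.0, 0.3, size=200)
        scr = screen_normality(vals)
        assert scr.pvalue < 0.05  # raw values rejected
        assert scr.log_pvalue >= 0.05
        assert scr.normalized


def synthetic_rows(seed=0, n_birds=10, amp_coupling=0.0, amp_effect=0.0,
                   slope=-0.24, noise=0.08):
    """Coupling-table-shaped rows with controllable amplitude structure."""
    rng = np.random.default_rng(seed)
    psets = [[0.8, 0.2], [0.6, 0.4], [0.5, 0.3, 0.2]]
    rows = []
    for b in range(n_birds):
        ub = rng.normal(0, 0.05)
        for s, ps in enumerate(psets):
            vs = rng.normal(0, 0.05)
            for p in ps:
                la = rng.normal(-0.4, 0.15) + amp_coupling * p
                y = 2.0 + slope * p + amp_effect * la + ub + vs + rng.normal(0, noise)
                rows.append({
                    "bird_id": f"b{b}", "sequence_id": f"b{b}s{s}", "p": p,
                    "log10_gap": y, "median_gap_ms": 10 ** y, "log10_amp": la,
                    "rms_amp": 10 ** la, "transition_type": "branch",
                })
    return pd.DataFrame(rows)


class TestResidualize:
    def test_step1_residuals_sum_to_zero(self):
        rows, fit1, _fit2 = residualize_amplitude(synthetic_rows(seed=1))
        assert abs(np.sum(fit1.resid)) < 1e-6 * len(rows)

    def test_amplitude_unrelated_leaves_coupling_intact(self):
        rows = synthetic_rows(seed=2, amp_coupling=0.0, amp_effect=0.0)
        raw = sg.fit_coupling_model(rows).coef("p")
        _r, _f1, fit2 = residualize_amplitude(rows)
        res = fit2.coef("p")
        assert abs(res["estimate"] - raw["estimate"]) < 1.5 * raw["se"]
        assert res["p"] < 0.05 and res["estimate"] < 0

    def test_amplitude_driven_gaps_lose_coupling_after_residualization(self):
        # gap fully determined by amplitude; p independent of both
        rng_rows = synthetic_rows(seed=3, amp_coupling=0.0, amp_effect=-0.6,
                                  slope=0.0, noise=0.01)
        _r, _f1, fit2 = residualize_amplitude(rng_rows)
        res = fit2.coef("p")
        assert abs(res["estimate"]) < 2 * res["se"]

    def test_missing_amplitude_raises(self):
        rows = synthetic_rows(seed=4)
        rows.loc[3, "log10_amp"] = np.nan
        with pytest.raises(ValueError, match="rows"):
            residualize_amplitude(rows)


class TestModelGuards:
    def test_transition_types_must_both_be_present(self):
        rows = synthetic_rows(seed=5)
        with pytest.raises(ValueError, match="types"):
            compare_transition_types(rows)

    def test_change_analysis_needs_records_and_variation(self):
        with pytest.raises(ValueError, match=">= 3"):
            change_coupling_analysis(pd.DataFrame({"delta_p": [0.1]}))
        df = pd.DataFrame({
            "bird_id": ["a", "a", "b", "b"], "sequence_id": list("wxyz"),
            "delta_p": [0.1, 0.1, 0.1, 0.1],
            "delta_log10_gap": [0.0, 0.1, -0.1, 0.2],
            "pct_gap_change": [0.0, 1.0, -1.0, 2.0],
        })
        with pytest.raises(ValueError, match="constant"):
            change_coupling_analysis(df)

    def test_single_bird_rejected(self):
        rows = synthetic_rows(seed=6, n_birds=1)
        with pytest.raises(ValueError, match="birds"):
            sg.fit_coupling_model(rows)


class TestExactFilters:
    """Hand-built fixture with known counts; every filter must match the
    hand tally exactly."""

    def condition_a(self):
        rends = (["bcaf"] * 7 + ["bcak"] * 4 + ["bc"] * 1
                 + ["pq"] * 9 + ["mn"] * 19 + ["mo"] * 1)
        return events_from_sequences({"birdA": rends, "birdB": rends})

    def condition_b(self):
        rends = (["bcaf"] * 6 + ["bcak"] * 5
                 + ["pq"] * 9 + ["mn"] * 19 + ["mo"] * 1)
        return events_from_sequences({"birdA": rends, "birdB": rends})

    def test_coupling_filters(self):
        an = sg.analyze_corpus(self.condition_a())
        rows = an.coupling[an.coupling.bird_id == "birdA"]
        # 'a' occurs 11 times -> branch {f: 7/11, k: 4/11}; k has 4 < 5
        # instances; 'b'->'c' 12x and 'c'->'a' 11x are stereotyped; 'p'
        # occurs 9 < 10 times; 'm' is a branch with p_max = 0.95 and its
        # 'n' arm has 19 instances while 'o' has 1
        assert set(zip(rows.context, rows.target)) == {
            ("a", "f"), ("b", "c"), ("c", "a"), ("m", "n"),
        }
        by = rows.set_index(["context", "target"])
        assert by.loc[("a", "f"), "p"] == pytest.approx(7 / 11)
        assert by.loc[("a", "f"), "n_instances"] == 7
        assert by.loc[("m", "n"), "transition_type"] == "branch"
        assert by.loc[("b", "c"), "transition_type"] == "stereotyped"
        bps = {bp.context: bp for bp in an.branch_points["birdA"]}
        assert "p" not in bps
        assert bps["a"].n_occurrences == 11

    def test_change_filters(self):
        an_a = sg.analyze_corpus(self.condition_a())
        an_b = sg.analyze_corpus(self.condition_b())
        change, stereo = build_change_table(an_a, an_b)
        cha = change[change.bird_id == "birdA"]
        # only (a, f) passes the >= 5-instances-in-both rule: k has 4 in A;
        # the 'm' branch (0.95) contributes its 'n' arm as well
        assert set(zip(cha.context, cha.target)) == {("a", "f"), ("m", "n")}
        assert set(cha.category) == {"unchanged"}
        sta = stereo[stereo.bird_id == "birdA"]
        # 'b' and 'c' are stereotyped in both conditions with >= 5 instances
        assert set(sta.context) == {"b", "c"}
        assert set(sta.category) == {"stereotyped"}


class TestCategoryContrast:
    def test_singleton_category_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        rows = []
        for b in range(6):
            for s in range(3):
                for cat in ("increased", "decreased", "unchanged"):
                    rows.append({"bird_id": f"b{b}", "sequence_id": f"b{b}s{s}{cat}",
                                 "pct_gap_change": rng.normal(-5, 3),
                                 "category": cat})
        change = pd.DataFrame(rows)
        stereo = pd.DataFrame([{"bird_id": "b0", "sequence_id": "b0st",
                                "pct_gap_change": -5.0, "category": "stereotyped"}])
        with pytest.warns(UserWarning, match="single observation"):
            con = stats.category_contrast(change, stereo)
        assert "stereotyped" not in con.levels
        assert con.omnibus["df_num"] == 2.0
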