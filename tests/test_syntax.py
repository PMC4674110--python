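"""Transition counting, termination exclusion, the context-dependence G
test, branch-point resolution and the variable-repeat exclusion rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songgaps.syntax import (
    count_transitions,
    exclude_repeats,
    lrt_context_dependence,
    resolve_contexts,
)


class TestCounting:
    def test_branch_counts_and_probabilities(self):
        table = count_transitions(["eaf"] * 18 + ["eak"] * 2)
        assert table.counts[2]["ea"] == {"f": 18, "k": 2}
        assert table.probabilities("ea") == {"f": 0.9, "k": 0.1}

    def test_probabilities_from_three_targets(self):
        table = count_transitions(["def"] * 82 + ["dec"] * 13 + ["deq"] * 5)
        assert table.probabilities("de") == {"c": 0.13, "f": 0.82, "q": 0.05}

    def test_final_syllable_counts_as_termination_only(self):
        table = count_transitions(["ab"])
        assert table.counts[1]["a"] == {"b": 1}
        assert "b" not in table.counts[1]
        assert table.terminations[1]["b"] == 1

    def test_empty_rendition_contributes_nothing(self):
        table = count_transitions(["", "ab"])
        assert sum(table.counts[1]["a"].values()) == 1

    def test_termination_excluded_from_probabilities(self):
        # 'a' is followed by 'b' 3 times and ends the song twice: p(b|a) = 1
        table = count_transitions(["ab"] * 3 + ["a"] * 2)
        assert table.probabilities("a") == {"b": 1.0}
        assert table.terminations[1]["a"] == 2


class TestLRT:
    def test_identical_contexts_give_zero(self):
        res = lrt_context_dependence({"a": {"x": 10, "y": 10}, "b": {"x": 10, "y": 10}})
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_contexts_give_large_g(self):
        # G = 2*(20 ln 2 + 20 ln 2) = 80 ln 2
        res = lrt_context_dependence({"a": {"x": 20, "y": 0}, "b": {"x": 0, "y": 20}})
        assert res.g == pytest.approx(80 * np.log(2), rel=1e-12)
        assert res.df == 1
        assert res.pvalue < 1e-12

    def test_single_context_raises(self):
        with pytest.raises(ValueError):
            lrt_context_dependence({"a": {"x": 5, "y": 5}})

    def test_null_rejection_rate_is_nominal(self):
        # both contexts share p = {0.7, 0.3}: rejections at alpha=0.05 should
        # occur at ~5% (quick 600-replicate version of the calibration)
        rng = np.random.default_rng(123)
        rej = 0
        reps = 600
        for _ in range(reps):
            a = rng.multinomial(100, [0.7, 0.3])
            b = rng.multinomial(100, [0.7, 0.3])
            res = lrt_context_dependence(
                {"a": {"x": int(a[0]), "y": int(a[1])},
                 "b": {"x": int(b[0]), "y": int(b[1])}}
            )
            rej += res.pvalue < 0.05
        assert 0.025 <= rej / reps <= 0.075

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)),
            min_size=2,
            max_size=5,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_g_statistic_is_valid(self, rows):
        counts = {
            f"c{i}": {"x": r[0], "y": r[1], "z": r[2]} for i, r in enumerate(rows)
        }
        res = lrt_context_dependence(counts)
        assert res.g >= 0
        assert 0 <= res.pvalue <= 1


class TestResolve:
    def test_context_independent_predecessors_pool(self):
        rends = (["acx"] * 30 + ["acy"] * 10 + ["bcx"] * 30 + ["bcy"] * 10)
        bps = resolve_contexts(count_transitions(rends))
        c = [bp for bp in bps if bp.context == "c"]
        assert len(c) == 1 and not c[0].split
        assert c[0].probability("x") == pytest.approx(0.75)

    def test_context_dependent_predecessors_split(self):
        rends = (["acx"] * 45 + ["acy"] * 5 + ["bcx"] * 5 + ["bcy"] * 45)
        bps = resolve_contexts(count_transitions(rends))
        by_ctx = {bp.context: bp for bp in bps}
        assert "ac" in by_ctx and "bc" in by_ctx
        assert by_ctx["ac"].probability("x") == pytest.approx(0.9)
        assert by_ctx["bc"].probability("x") == pytest.approx(0.1)
        assert by_ctx["ac"].lrt.pvalue < 0.05

    def test_occurrence_filter(self):
        bps = resolve_contexts(count_transitions(["zw"] * 9))
        assert all(bp.context != "z" for bp in bps)
        bps = resolve_contexts(count_transitions(["zw"] * 10))
        assert any(bp.context == "z" for bp in bps)

    def test_stereotyped_threshold_is_strict(self):
        # p_max exactly 0.95 stays a branch point
        bps = resolve_contexts(count_transitions(["mn"] * 19 + ["mo"] * 1))
        m = next(bp for bp in bps if bp.context == "m")
        assert m.p_max == pytest.approx(0.95)
        assert m.classification == "branch"
        bps = resolve_contexts(count_transitions(["mn"] * 20 + ["mo"] * 1))
        m = next(bp for bp in bps if bp.context == "m")
        assert m.classification == "stereotyped"

    def test_probabilities_sum_to_one(self, small_corpus):
        corpus, _ = small_corpus
        for bird in corpus.birds:
            table = count_transitions(["".join(r.labels) for r in bird.renditions])
            for bp in resolve_contexts(table):
                assert sum(p for _t, _c, p in bp.targets) == pytest.approx(
                    1.0, abs=1e-12
                )
                assert bp.n_occurrences == bp.n_transitions + bp.n_terminations

    def test_estimates_converge_to_generator_truth(self, small_corpus):
        # 4-sigma bands: ~80 (bird, target) pairs are checked jointly, so a
        # per-target 3-sigma band would reject a correct generator too often
        corpus, truth = small_corpus
        tt = truth.transitions.set_index(["bird_id", "from_label", "to_label"])
        n_checked = 0
        for bird in corpus.birds:
            table = count_transitions(["".join(r.labels) for r in bird.renditions])
            for bp in resolve_contexts(table):
                if bp.split:
                    continue
                for t, _c, p_hat in bp.targets:
                    p = tt.loc[(bird.bird_id, bp.context[-1], t), "p_true"]
                    band = 4 * np.sqrt(p * (1 - p) / bp.n_transitions) + 1e-9
                    assert abs(p_hat - p) <= band
                    n_checked += 1
        assert n_checked > 40


class TestExcludeRepeats:
    def test_variable_runs_flagged_and_cut(self):
        frags, flagged = exclude_repeats(["abbc", "abbbc", "abc"])
        assert flagged == {"b"}
        assert frags[0] == [["a"], ["c"]]
        table = count_transitions(frags)
        assert "b" not in table.counts[1]
        assert "a" not in table.counts[1] or "b" not in table.counts[1].get("a", {})

    def test_fixed_runs_kept(self):
        frags, flagged = exclude_repeats(["abbc", "abbc", "abbc"])
        assert flagged == set()
        assert frags[0] == [["a", "b", "b", "c"]]

    def test_no_repeats_is_identity(self):
        frags, flagged = exclude_repeats(["abc", "acb"])
        assert flagged == set()
        assert [list("".join(sum(f, []))) for f in frags] == [list("abc"), list("acb")]

    def test_fragment_ends_are_not_terminations(self):
        frags, _ = exclude_repeats(["abbc", "abbbc"])
        table = count_transitions(frags)
        # 'a' precedes an excluded run: it must not register a termination
        assert table.terminations[1].get("a", 0) == 0
        assert table.terminations[1]["c"] == 2
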