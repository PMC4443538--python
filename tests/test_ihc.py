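import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capsuledyn import (
    InputFormatError,
    generate_ihc_dataset,
    kruskal_statistic,
    kruskal_wallis_by_week,
    permutation_p_value,
    score_fields,
)
from helpers import naive_kruskal_h, naive_permutation_p


def ihc_rows(e1, e2, rat="r1", group="immobilized", week=2):
    rows = []
    for fld, (a, b) in enumerate(zip(e1, e2), start=1):
        rows.append({"rat": rat, "group": group, "week": week,
                     "field": fld, "examiner": 1, "percent": a})
        rows.append({"rat": rat, "group": group, "week": week,
                     "field": fld, "examiner": 2, "percent": b})
    return pd.DataFrame(rows)


class TestFieldScoring:
    def test_worst_field_removed_means_retained(self):
        table = ihc_rows([50, 60, 70, 80], [55, 60, 90, 80])
        scores = score_fields(table)
        assert list(scores["field"]) == [1, 2, 4]
        assert list(scores["mean"]) == [52.5, 60.0, 80.0]

    def test_tie_removes_lowest_field_index(self):
        table = ihc_rows([50, 60, 70, 80], [50, 60, 70, 80])
        scores = score_fields(table)
        assert list(scores["field"]) == [2, 3, 4]

    def test_two_field_rat_keeps_one(self):
        table = ihc_rows([40, 50], [45, 50])
        scores = score_fields(table)
        assert len(scores) == 1 and scores["field"].iloc[0] == 2

    def test_wrong_examiner_count_rejected(self):
        table = ihc_rows([50, 60], [55, 60])
        with pytest.raises(InputFormatError, match="2 examiner rows"):
            score_fields(table.iloc[:-1])

    def test_removal_never_increases_max_interrater_diff(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e1 = rng.uniform(0, 100, 4)
            e2 = np.clip(e1 + rng.normal(0, 10, 4), 0, 100)
            table = ihc_rows(e1, e2)
            before = np.abs(e1 - e2).max()
            after = score_fields(table)["inter_rater_diff"].max()
            assert after <= before + 1e-12


class TestKruskalWallis:
    def test_h_and_permutation_p_match_naive_enumeration(self):
        values = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = ["sham"] * 3 + ["imm"] * 3
        assert kruskal_statistic(values, labels) == pytest.approx(
            naive_kruskal_h(values, labels)
        )
        assert kruskal_statistic(values, labels) == pytest.approx(12 * 13.5 / 42)
        # both extreme splits reach the maximal H, so the exact p over the
        # 20 equally likely assignments is 2/20
        assert permutation_p_value(values, labels) == pytest.approx(0.1)
        assert naive_permutation_p(values, labels) == pytest.approx(0.1)

    def test_tie_correction_matches_naive_oracle(self):
        values = [1.0, 2.0, 2.0, 5.0, 2.0, 7.0, 8.0, 8.0]
        labels = ["a"] * 4 + ["b"] * 4
        assert kruskal_statistic(values, labels) == pytest.approx(
            naive_kruskal_h(values, labels)
        )

    def test_all_tied_values_give_h_zero_p_one(self):
        scores = pd.DataFrame(
            {
                "week": 2, "group": ["sham"] * 3 + ["immobilized"] * 3,
                "mean": [50.0] * 6, "rat": list("abcdef"), "field": 1,
            }
        )
        res = kruskal_wallis_by_week(scores)
        assert res[0].H == 0.0 and res[0].p_value == 1.0

    @given(
        st.lists(st.floats(min_value=0.1, max_value=99.0), min_size=6, max_size=10),
        st.sampled_from(["exp", "affine", "cube"]),
    )
    def test_h_invariant_under_strictly_monotone_transforms(self, values, kind):
        labels = ["a" if i % 2 else "b" for i in range(len(values))]
        h0 = kruskal_statistic(values, labels)
        v = np.asarray(values)
        t = {"exp": np.exp(v / 50), "affine": 3 * v + 7, "cube": v**3}[kind]
        assert kruskal_statistic(t, labels) == pytest.approx(h0, abs=1e-9)

    def test_single_group_week_skipped_with_warning(self, caplog):
        scores = pd.DataFrame(
            {"week": [2, 2], "group": ["sham", "sham"], "mean": [1.0, 2.0]}
        )
        with caplog.at_level("WARNING"):
            res = kruskal_wallis_by_week(scores)
        assert res == [] and "skipped" in caplog.text


class TestGenerator:
    def test_zero_examiner_sd_gives_identical_counts(self):
        table = generate_ihc_dataset(
            2, {("sham", 2): 40.0, ("immobilized", 2): 20.0},
            examiner_sd=0.0, seed=1,
        )
        wide = table.pivot_table(
            index=["rat", "field"], columns="examiner", values="percent"
        )
        assert (wide[1] == wide[2]).all()

    def test_reproducible_under_seed_and_bounded(self):
        kw = dict(n_rats_per_cell=3, group_effects={("sham", 4): 95.0},
                  examiner_sd=10.0, seed=9)
        t1, t2 = generate_ihc_dataset(**kw), generate_ihc_dataset(**kw)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["percent"].between(0, 100).all()

    def test_negative_sd_rejected(self):
        from capsuledyn import ConfigurationError

        with pytest.raises(ConfigurationError):
            generate_ihc_dataset(2, {("sham", 2): 10.0}, examiner_sd=-1.0)

    def test_strong_separation_detected(self):
        hits = 0
        for seed in range(40):
            table = generate_ihc_dataset(
                4, {("sham", 2): 60.0, ("immobilized", 2): 10.0},
                examiner_sd=5.0, seed=seed,
            )
            res = kruskal_wallis_by_week(score_fields(table))
            hits += res[0].significant
        assert hits >= 36  # >= 90% power at this separation
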