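import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuevote import (
    Call,
    Category,
    TissueScore,
    ValidationError,
    dataset_call,
    final_call,
    generate_worked_example,
    inner_score,
    support_category,
    total_score,
)
from tissuevote.scoring import (
    SUPPORT_BELOW,
    SUPPORT_HIGH,
    SUPPORT_MEDIUM,
    SUPPORT_MEDIUM_HIGH,
    SUPPORT_STRONG,
)

S, P, U = Call.specific, Call.two_selective, Call.ubiquitous


class TestInnerScore:
    def test_majority_pair_scores_half_each(self):
        # two 2-selective probe sets + one non-informative ubiquitous
        calls = [P("Liver", "Lymph"), P("Liver", "Lymph"), U()]
        scores = inner_score(calls).scores
        assert scores == {"Liver": 0.5, "Lymph": 0.5}

    def test_unanimous_specific_scores_one(self):
        scores = inner_score([S("Liver")] * 3).scores
        assert scores == {"Liver": 1.0}

    def test_split_evidence_falls_back_to_averaging(self):
        # specific(Liver) and 2-selective(Liver, Kidney) tie at the 50% bar:
        # neither wins outright, so contributions are averaged
        calls = [S("Liver"), P("Liver", "Kidney"), U()]
        scores = inner_score(calls).scores
        assert scores == {"Liver": 0.75, "Kidney": 0.25}

    def test_all_ubiquitous_empty_map(self):
        assert inner_score([U(), U()]).scores == {}

    def test_one_of_two_triggers_rule1(self):
        # 1 of 2 counts as "at least 50%": the ubiquitous call is dropped
        scores = inner_score([P("Liver", "Kidney"), U()]).scores
        assert scores == {"Liver": 0.5, "Kidney": 0.5}

    def test_minority_informative_keeps_ubiquitous_calls(self):
        # 1 informative of 3: rule 1 does not fire, averaging dilutes
        scores = inner_score([S("Liver"), U(), U()]).scores
        assert scores == {"Liver": pytest.approx(1 / 3)}

    def test_mention_frequency_mode(self):
        calls = [S("Liver"), P("Liver", "Kidney"), U()]
        scores = inner_score(calls, rule2_frequency="mention").scores
        assert scores == {"Liver": 1.0, "Kidney": 0.5}

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            inner_score([])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                [S("Liver"), S("Kidney"), P("Liver", "Kidney"), P("Liver", "Heart"), U()]
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_scores_sum_at_most_one(self, calls):
        assert sum(inner_score(calls).scores.values()) <= 1.0 + 1e-9


class TestTotalScore:
    def _inner(self, gene, ds, **scores):
        return TissueScore(gene=gene, scope=f"inner:{ds}", scores=scores)

    def test_worked_average(self):
        inner = {
            "GNF1H": self._inner("GRHPR", "GNF1H", Liver=0.5, Lymph=0.5),
            "GeAZr": self._inner("GRHPR", "GeAZr", Liver=1.0),
            "GSE7307": self._inner("GRHPR", "GSE7307", Liver=0.75, Kidney=0.25),
            "GDS3113": self._inner("GRHPR", "GDS3113"),
        }
        presence = {ds: True for ds in inner}
        total, coverage = total_score(inner, presence, "GRHPR")
        assert total.scores["Liver"] == pytest.approx(0.5625)
        assert coverage == (4, 4)

    def test_single_dataset_full_score(self):
        inner = {"A": self._inner("g", "A", Liver=1.0)}
        presence = {"A": True, "B": False, "C": False, "D": False}
        total, coverage = total_score(inner, presence, "g")
        assert total.scores["Liver"] == 1.0
        assert coverage == (1, 4)

    def test_present_but_ubiquitous_contributes_zero(self):
        inner = {"A": self._inner("g", "A", Liver=1.0), "B": self._inner("g", "B")}
        presence = {"A": True, "B": True}
        total, coverage = total_score(inner, presence, "g")
        assert total.scores["Liver"] == 0.5
        assert coverage == (2, 2)

    def test_absent_everywhere_rejected(self):
        with pytest.raises(ValidationError):
            total_score({}, {"A": False, "B": False}, "g")

    def test_absent_dataset_changes_coverage_only(self):
        inner = {"A": self._inner("g", "A", Liver=0.8)}
        t1, c1 = total_score(inner, {"A": True}, "g")
        t2, c2 = total_score(inner, {"A": True, "B": False}, "g")
        assert t1.scores == t2.scores
        assert c1 == (1, 1) and c2 == (1, 2)

    @settings(deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["A", "B", "C", "D"]),
            st.dictionaries(
                st.sampled_from(["Liver", "Kidney"]),
                st.floats(min_value=0, max_value=1),
                max_size=2,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_matches_brute_force_mean(self, inner_maps):
        inner = {
            ds: TissueScore(gene="g", scope=f"inner:{ds}", scores=sc)
            for ds, sc in inner_maps.items()
        }
        presence = {ds: True for ds in inner}
        total, _ = total_score(inner, presence, "g")
        for tissue, value in total.scores.items():
            expected = sum(
                inner[ds].scores.get(tissue, 0.0) for ds in inner
            ) / len(inner)
            assert value == pytest.approx(expected)
            assert value <= max(
                inner[ds].scores.get(tissue, 0.0) for ds in inner
            ) + 1e-12


class TestSupportBands:
    @pytest.mark.parametrize(
        "category,score,expected",
        [
            (Category.SPECIFIC, 1.0, SUPPORT_STRONG),
            (Category.SPECIFIC, 0.9, SUPPORT_HIGH),
            (Category.SPECIFIC, 0.75, SUPPORT_HIGH),
            (Category.SPECIFIC, 0.6, SUPPORT_MEDIUM_HIGH),
            (Category.SPECIFIC, 0.5, SUPPORT_MEDIUM),
            (Category.SPECIFIC, 0.49, SUPPORT_BELOW),
            (Category.TWO_SELECTIVE, 0.5, SUPPORT_STRONG),
            (Category.TWO_SELECTIVE, 0.4, SUPPORT_MEDIUM_HIGH),
            (Category.TWO_SELECTIVE, 0.3, SUPPORT_MEDIUM_HIGH),
            (Category.TWO_SELECTIVE, 0.29, SUPPORT_BELOW),
            (Category.UBIQUITOUS, 0.9, SUPPORT_BELOW),
        ],
    )
    def test_band_lookup(self, category, score, expected):
        assert support_category(category, score) == expected

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            support_category(Category.SPECIFIC, 1.2)
        with pytest.raises(ValidationError):
            support_category(Category.SPECIFIC, -0.1)

    def test_bands_are_disjoint_and_ordered(self):
        grid = np.linspace(0, 1, 201)
        labels = [support_category(Category.SPECIFIC, s) for s in grid]
        order = [SUPPORT_BELOW, SUPPORT_MEDIUM, SUPPORT_MEDIUM_HIGH, SUPPORT_HIGH, SUPPORT_STRONG]
        ranks = [order.index(l) for l in labels]
        assert ranks == sorted(ranks)


class TestFinalCall:
    def test_grhpr_verdict(self):
        calls, n = generate_worked_example("GRHPR")
        inner = {ds: inner_score(c, "GRHPR", ds) for ds, c in calls.items()}
        presence = {ds: True for ds in calls}
        total, coverage = total_score(inner, presence, "GRHPR")
        ds_calls = {ds: dataset_call(c) for ds, c in calls.items()}
        result = final_call("GRHPR", ds_calls, total, coverage)
        assert result.category is Category.SPECIFIC
        assert result.tissues == ("Liver",)
        assert result.support == SUPPORT_MEDIUM_HIGH
        assert result.coverage == (4, 4)

    def test_ass1_verdict(self):
        calls, n = generate_worked_example("ASS1")
        inner = {ds: inner_score(c, "ASS1", ds) for ds, c in calls.items()}
        presence = {ds: True for ds in calls}
        presence["GDS3113"] = False
        total, coverage = total_score(inner, presence, "ASS1")
        ds_calls = {ds: dataset_call(c) for ds, c in calls.items()}
        result = final_call("ASS1", ds_calls, total, coverage)
        assert result.category is Category.TWO_SELECTIVE
        assert set(result.tissues) == {"Liver", "Kidney"}
        assert result.coverage == (3, 4)

    def test_all_ubiquitous_gene(self):
        ds_calls = {"A": U(), "B": U()}
        total = TissueScore(gene="g", scope="total", scores={})
        result = final_call("g", ds_calls, total, (2, 2))
        assert result.category is Category.UBIQUITOUS
        assert result.tissues == ()
        assert result.support == SUPPORT_BELOW

    def test_low_score_reported_below_threshold(self):
        ds_calls = {"A": S("Liver"), "B": U(), "C": U(), "D": U()}
        total = TissueScore(gene="g", scope="total", scores={"Liver": 0.25})
        result = final_call("g", ds_calls, total, (4, 4))
        assert result.support == SUPPORT_BELOW
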