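"""Scale scoring, banding, and group aggregation against the published
per-participant study outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindmotion.psychometrics import (
    SWLS_BANDS,
    ScaleResponse,
    classify_mmse,
    longitudinal_report,
    round_half_away,
    score_maas,
    score_swls,
    summarize_group,
)
from mindmotion.reference_data import STUDY_OUTCOMES
from mindmotion.synthetic import generate_scale_items


class TestSWLS:
    @pytest.mark.parametrize(
        "total, category",
        [
            (16, "slightly dissatisfied"),
            (21, "slightly satisfied"),
            (35, "extremely satisfied"),
            (20, "neutral"),
            (5, "extremely dissatisfied"),
        ],
    )
    def test_banding(self, total, category):
        items = generate_scale_items("SWLS", total, seed=1)
        score = score_swls(items)
        assert score.value == total
        assert score.category == category

    def test_bands_partition_range(self):
        for total in range(5, 36):
            hits = [lo <= total <= hi for lo, hi, _ in SWLS_BANDS]
            assert sum(hits) == 1

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError, match="5 item"):
            score_swls([4, 4, 4, 4])

    def test_out_of_range_item_named(self):
        with pytest.raises(ValueError, match="item 3"):
            score_swls([4, 4, 8, 4, 4])


class TestMAAS:
    @pytest.mark.parametrize("fill, expected", [(6, 6.0), (1, 1.0)])
    def test_extremes(self, fill, expected):
        assert score_maas([fill] * 15).value == expected

    def test_mean_rounding_to_one_decimal(self):
        # (8·2 + 7·3)/15 = 37/15 ≈ 2.467 → 2.5 at one decimal
        assert score_maas([2] * 8 + [3] * 7).value == 2.5

    def test_permutation_invariance(self):
        items = [1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6, 1, 2, 3]
        assert score_maas(items).value == score_maas(items[::-1]).value


class TestMMSE:
    @pytest.mark.parametrize(
        "total, band",
        [(19, "moderate"), (30, "normal"), (9, "severe"), (24, "mild"), (21, "mild"),
         (25, "normal"), (20, "moderate"), (10, "moderate"), (0, "severe")],
    )
    def test_banding(self, total, band):
        assert classify_mmse(total) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0–30"):
            classify_mmse(31)


class TestRounding:
    @pytest.mark.parametrize(
        "x, decimals, expected",
        [(27.25, 1, 27.3), (18.25, 1, 18.3), (-2.35, 1, -2.4), (25.25, 0, 25.0),
         (3.425, 1, 3.4), (1.0267, 1, 1.0)],
    )
    def test_half_away_from_zero(self, x, decimals, expected):
        assert round_half_away(x, decimals) == expected


class TestGroupSummary:
    def test_patients_swls_before(self):
        s = summarize_group([16, 16, 17, 24])
        assert (s.mean_rounded, s.sd_rounded) == (18.3, 3.9)

    def test_patients_swls_after(self):
        s = summarize_group([21, 24, 22, 25])
        assert (s.mean_rounded, s.sd_rounded) == (23.0, 1.8)

    def test_singleton_has_no_sd(self):
        s = summarize_group([4.2])
        assert s.mean == 4.2 and s.sd is None and s.sd_rounded is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_group([])

    def test_sample_sd_not_population(self):
        vals = [3.3, 4.2, 4.5, 5.2]
        s = summarize_group(vals)
        assert s.sd == pytest.approx(np.std(vals, ddof=1))
        assert s.sd != pytest.approx(np.std(vals))


def _reference_responses(seed=11):
    out = []
    for row in STUDY_OUTCOMES.itertuples():
        items = generate_scale_items(row.scale, row.score, seed + row.Index)
        out.append(
            ScaleResponse(
                participant=row.participant,
                group=row.group,
                timepoint=row.timepoint,
                scale=row.scale,
                items=tuple(items),
            )
        )
    return out


class TestLongitudinalReport:
    def test_reproduces_published_group_statistics(self):
        rep = longitudinal_report(_reference_responses()).set_index(
            ["group", "scale", "timepoint"]
        )

        def cell(group, scale, tp):
            r = rep.loc[(group, scale, tp)]
            return r["mean_rounded"], r["sd_rounded"]

        assert cell("patient", "SWLS", "before") == (18.3, 3.9)
        assert cell("patient", "SWLS", "after") == (23.0, 1.8)
        assert cell("patient", "MAAS", "after")[0] == 3.4
        assert cell("employee", "MAAS", "before") == (4.3, 0.8)
        assert cell("employee", "MAAS", "midterm") == (3.8, 1.0)
        assert cell("employee", "MAAS", "after") == (4.3, 0.7)
        assert cell("employee", "SWLS", "before")[0] == 27.3
        # printed as an integer in the study table
        assert round_half_away(rep.loc[("employee", "SWLS", "midterm"), "mean"], 0) == 25

    def test_deterministic_ordering(self):
        rep = longitudinal_report(_reference_responses())
        groups = rep["group"].tolist()
        assert groups == sorted(groups, key=["patient", "employee"].index)
        first_patient = rep[rep.group == "patient"]["scale"].tolist()
        assert first_patient == sorted(
            first_patient, key=["SWLS", "MAAS", "MMSE"].index
        )

    def test_empty_input_empty_table(self):
        assert len(longitudinal_report([])) == 0

    def test_single_participant_rows_lack_sd(self):
        resp = [
            ScaleResponse("p", "patient", tp, "SWLS", tuple(generate_scale_items("SWLS", 20, 3)))
            for tp in ("before", "midterm", "after")
        ]
        rep = longitudinal_report(resp)
        assert len(rep) == 3
        assert rep["sd"].isna().all()


@settings(max_examples=100, deadline=None)
@given(
    scale=st.sampled_from(["SWLS", "MAAS"]),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_generated_items_score_to_target(scale, seed):
    """Item generation is exact for SWLS sums and one-decimal MAAS means."""
    rng = np.random.default_rng(seed)
    if scale == "SWLS":
        target = int(rng.integers(5, 36))
        items = generate_scale_items(scale, target, seed)
        assert score_swls(items).value == target
    else:
        target = round(rng.uniform(1, 6), 1)
        items = generate_scale_items(scale, target, seed)
        assert score_maas(items).value == pytest.approx(target)


def test_unachievable_targets_rejected():
    with pytest.raises(ValueError, match="unachievable"):
        generate_scale_items("SWLS", 36, 0)
    with pytest.raises(ValueError, match="unachievable"):
        generate_scale_items("MAAS", 6.5, 0)
    items = generate_scale_items("SWLS", 35, 0)
    assert items == [7, 7, 7, 7, 7]
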