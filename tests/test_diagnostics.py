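"""Accuracy statistics: printed-table replays and enumeration oracles."""

import itertools

import numpy as np
import pytest

from ctsfna.data import fig5_category_pairs, load_table2_outcomes
from ctsfna.diagnostics import (
    ConfusionSummary,
    SlideOutcome,
    confusion,
    intensity_contrast,
    mann_whitney,
    mcnemar_exact,
    outcomes_from_frame,
    per_category_accuracy,
    round_half_up,
)
from ctsfna.images import InputError


def make_outcomes(tp=0, fp=0, fn=0, tn=0, inad=0):
    out = []
    for n, call, ref in (
        (tp, "positive", "malignant"),
        (fp, "positive", "benign_normal"),
        (fn, "negative", "malignant"),
        (tn, "negative", "benign_normal"),
        (inad, "inadequate", "benign_normal"),
    ):
        for _ in range(n):
            out.append(SlideOutcome(f"X{len(out)}", call, ref))
    return out


class TestConfusion:
    def test_published_index_cross_tab(self):
        s = confusion(make_outcomes(tp=58, fp=2, fn=5, tn=61))
        assert s.rounded()["sensitivity"] == 92.1
        assert s.rounded()["specificity"] == 96.8
        assert s.rounded()["accuracy"] == 94.4
        assert s.total == 126

    def test_published_comparator_cross_tab_with_atypical_negative(self):
        s = confusion(
            outcomes_from_frame(load_table2_outcomes()), use_comparator=True
        )
        assert (s.tp, s.fp, s.fn, s.tn, s.n_inadequate) == (61, 6, 1, 53, 5)
        r = s.rounded()
        assert r["sensitivity"] == 98.4
        assert r["specificity"] == 89.8
        assert r["accuracy"] == 94.2
        assert r["insufficiency_rate"] == 4.0

    def test_all_correct_toy_set(self):
        r = confusion(make_outcomes(tp=5, tn=5)).rounded()
        assert all(
            r[k] == 100.0
            for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
        )
        assert r["insufficiency_rate"] == 0.0

    def test_count_conservation(self):
        s = confusion(make_outcomes(tp=3, fp=4, fn=5, tn=6, inad=2))
        assert s.tp + s.fp + s.fn + s.tn + s.n_inadequate == 20

    def test_label_swap_duality(self):
        s = ConfusionSummary(tp=7, fp=3, fn=2, tn=11)
        swapped = ConfusionSummary(tp=s.tn, fp=s.fn, fn=s.fp, tn=s.tp)
        assert swapped.sensitivity == pytest.approx(s.specificity)
        assert swapped.specificity == pytest.approx(s.sensitivity)
        assert swapped.ppv == pytest.approx(s.npv)
        assert swapped.npv == pytest.approx(s.ppv)

    def test_unknown_comparator_level_rejected(self):
        o = [SlideOutcome("a", "negative", "malignant", comparator_call="weird")]
        with pytest.raises(InputError):
            confusion(o, use_comparator=True)


class TestPerCategoryAccuracy:
    def test_published_category_counts(self):
        cats, refs = fig5_category_pairs()
        table = per_category_accuracy(cats, refs).set_index("category")
        assert table.loc[4, "accuracy_pct"] == 96.7
        assert table.loc[3, "accuracy_pct"] == 88.9
        assert table.loc[2, "accuracy_pct"] == 84.6
        assert table.loc[1, "accuracy_pct"] == 100.0

    def test_single_benign_category_1_slide(self):
        t = per_category_accuracy([1], ["benign_normal"])
        assert t.accuracy_pct.iloc[0] == 100.0

    def test_category4_accuracy_equals_ppv_identity(self):
        # on any cohort: category-4 concordance is exactly the PPV of the
        # induced binary test
        cats = [4] * 10 + [3] * 5 + [1] * 5
        refs = ["malignant"] * 8 + ["benign_normal"] * 12
        t = per_category_accuracy(cats, refs).set_index("category")
        calls = make_outcomes(tp=8, fp=2, fn=0, tn=10)
        s = confusion(calls)
        assert t.loc[4, "accuracy_pct"] == round_half_up(s.ppv)


def mcnemar_oracle(b, c):
    """Enumerate all 2^(b+c) discordant-pair outcomes under H0."""
    n = b + c
    if n == 0:
        return 1.0
    obs = abs(b - c)
    hits = 0
    for bits in itertools.product([0, 1], repeat=n):
        k = sum(bits)
        if abs(k - (n - k)) >= obs:
            hits += 1
    return hits / 2**n


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        pairs = [(True, False)] * 3 + [(False, True)] * 3
        b, c, p, degenerate = mcnemar_exact(pairs)
        assert (b, c, p) == (3, 3, 1.0)
        assert not degenerate

    def test_no_discordance_is_degenerate(self):
        b, c, p, degenerate = mcnemar_exact([(True, True)] * 4)
        assert (b, c, p) == (0, 0, 1.0)
        assert degenerate

    def test_hand_enumerated_binomial_tail(self):
        pairs = [(True, False)] * 1 + [(False, True)] * 7
        _, _, p, _ = mcnemar_exact(pairs)
        assert p == pytest.approx(2 * (1 + 8) / 2**8)  # 0.0703125

    def test_matches_enumeration_for_all_small_tables(self):
        for b in range(0, 13):
            for c in range(0, 13 - b):
                pairs = [(True, False)] * b + [(False, True)] * c
                _, _, p, _ = mcnemar_exact(pairs)
                assert p == pytest.approx(mcnemar_oracle(b, c), abs=1e-12)

    def test_agrees_with_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(1, 7), (2, 9), (5, 5), (0, 6)]:
            table = [[10, b], [c, 10]]
            expected = sm_mcnemar(table, exact=True).pvalue
            pairs = [(True, False)] * b + [(False, True)] * c
            assert mcnemar_exact(pairs).p_value == pytest.approx(expected)


def mw_permutation_oracle(a, b):
    """Full enumeration of group assignments (tie-free data)."""
    pooled = list(a) + list(b)
    na = len(a)

    def ustat(group_a_vals, rest):
        return sum(
            sum(1.0 if x > y else 0.5 if x == y else 0.0 for y in rest)
            for x in group_a_vals
        )

    u_obs = ustat(a, b)
    mu = na * len(b) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(ustat(ga, gb) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestMannWhitney:
    def test_total_tie_single_elements(self):
        u, p, _ = mann_whitney([5.0], [5.0])
        assert u == 0.5
        assert p >= 0.99

    def test_fully_separated_small_groups(self):
        u, p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_matches_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        for na, nb in [(3, 3), (4, 4), (5, 5), (4, 6), (2, 7)]:
            vals = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = vals[:na], vals[na:]
            _, p, _ = mann_whitney(a, b)
            assert p == pytest.approx(mw_permutation_oracle(a, b), abs=1e-12)

    def test_configured_intensity_separation_is_significant(self):
        # malignant vs benign median-red draws at the generator's default
        # contrast (1500 +/- 300 vs 350 +/- 120), n = 60 per group
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            mal = rng.normal(1500, 300, 60)
            ben = rng.normal(350, 120, 60)
            _, p, _ = mann_whitney(mal, ben)
            hits += p < 1e-4
        assert hits >= 95

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])


class TestIntensityContrast:
    def test_identical_intensities_give_p_near_one(self):
        out = [
            SlideOutcome(f"m{i}", "positive", "malignant", red_intensity=5.0)
            for i in range(4)
        ] + [
            SlideOutcome(f"b{i}", "negative", "benign_normal", red_intensity=5.0)
            for i in range(4)
        ]
        res = intensity_contrast(out)
        assert res["groups"]["malignant"]["median"] == res["groups"]["benign_normal"]["median"]
        assert res["mann_whitney"]["p_value"] > 0.9

    def test_single_slide_per_class_medians(self):
        out = [
            SlideOutcome("m", "positive", "malignant", red_intensity=7.0),
            SlideOutcome("b", "negative", "benign_normal", red_intensity=3.0),
        ]
        res = intensity_contrast(out)
        assert res["groups"]["malignant"]["median"] == 7.0
        assert res["groups"]["benign_normal"]["median"] == 3.0

    def test_misclassified_slides_flagged(self):
        out = [
            SlideOutcome("fp", "positive", "benign_normal", red_intensity=9.0),
            SlideOutcome("tn", "negative", "benign_normal", red_intensity=1.0),
            SlideOutcome("tp", "positive", "malignant", red_intensity=9.0),
        ]
        assert intensity_contrast(out)["misclassified"] == ["fp"]


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,printed",
        [
            (58, 63, 92.1),
            (61, 63, 96.8),
            (119, 126, 94.4),
            (61, 62, 98.4),
            (53, 59, 89.8),
            (114, 121, 94.2),
            (5, 126, 4.0),
        ],
    )
    def test_printed_percentages_from_printed_counts(self, num, den, printed):
        assert round_half_up(100.0 * num / den) == printed

    def test_half_rounds_up(self):
        assert round_half_up(92.05) == 92.1
        assert round_half_up(92.04) == 92.0
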