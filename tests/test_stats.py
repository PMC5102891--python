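"""Log-rank vs hand/permutation oracles, Holm–Šidák, factorial ANOVA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from lamsync import (factorial_anova, holm_sidak, kaplan_meier_logrank,
                     pearson, ttest)
from lamsync.bursts import IncidenceRecord
from lamsync.stats import logrank_by_hand


def _rec(i, group, onset, event=True):
    return IncidenceRecord(f"{group}{i}", group, onset, event)


def test_identical_groups_give_null_logrank():
    recs = [_rec(i, "control", 2.0) for i in range(4)] \
        + [_rec(i, "FL", 2.0) for i in range(4)]
    r = kaplan_meier_logrank(recs)
    assert r.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
    assert r.logrank_p == pytest.approx(1.0, abs=1e-6)


def test_separated_groups_match_hand_worked_table():
    """4 events at step 1 vs 4 at step 4: chi2 from the O−E table."""
    recs = [_rec(i, "control", 3.0) for i in range(4)] \
        + [_rec(i, "FL", 0.5) for i in range(4)]
    r = kaplan_meier_logrank(recs)
    hand = logrank_by_hand(recs)
    assert r.logrank_chi2 == pytest.approx(hand, rel=1e-9)
    assert hand == pytest.approx(7.0)    # worked by hand: (4−8/2)²/…
    assert r.logrank_p < 0.05
    assert r.median_onset_level == {"FL": 0.5, "control": 3.0}


def test_logrank_agrees_with_hand_form_over_all_label_assignments():
    """Exhaustive n = 8: the packaged statistic equals the O−E form for
    every possible 4/4 group labelling of a fixed onset pattern."""
    onsets = [3.0, 2.0, 2.0, 1.0, 1.0, 0.5, 0.5, 0.5]
    for chosen in combinations(range(8), 4):
        recs = [_rec(i, "control" if i in chosen else "FL", onsets[i])
                for i in range(8)]
        r = kaplan_meier_logrank(recs)
        assert r.logrank_chi2 == pytest.approx(logrank_by_hand(recs),
                                               abs=1e-9)


def test_logrank_invariant_to_record_order():
    recs = [_rec(0, "control", 3.0), _rec(1, "control", 0.5, False),
            _rec(2, "FL", 2.0), _rec(3, "FL", 1.0), _rec(4, "FL", 0.5),
            _rec(5, "control", 1.0)]
    a = kaplan_meier_logrank(recs)
    b = kaplan_meier_logrank(list(reversed(recs)))
    assert a.logrank_chi2 == pytest.approx(b.logrank_chi2)
    for g in a.step_functions:
        np.testing.assert_allclose(a.step_functions[g][1],
                                   b.step_functions[g][1])


def test_all_censored_is_flagged_not_tested():
    recs = [_rec(i, "control", None, False) for i in range(3)] \
        + [_rec(i, "FL", None, False) for i in range(3)]
    r = kaplan_meier_logrank(recs)
    assert r.flagged is not None
    assert r.logrank_chi2 is None
    for g, (steps, surv) in r.step_functions.items():
        np.testing.assert_allclose(surv, 1.0)


def test_km_step_functions_non_increasing():
    recs = [_rec(0, "control", 3.0), _rec(1, "control", 1.0),
            _rec(2, "control", 0.5, False), _rec(3, "FL", 2.0),
            _rec(4, "FL", 2.0), _rec(5, "FL", 0.5)]
    r = kaplan_meier_logrank(recs)
    for steps, surv in r.step_functions.values():
        assert np.all(np.diff(surv) <= 1e-12)


def test_holm_sidak_hand_thresholds():
    """Stepwise Šidák: α_i = 1 − 0.95^{1/(m−i+1)} → for
    p = [0.001, 0.02, 0.04] the thresholds are 0.01695/0.02532/0.05,
    so all three are rejected."""
    res = holm_sidak([0.001, 0.02, 0.04])
    assert list(res["reject"]) == [True, True, True]
    np.testing.assert_allclose(
        res["p_adjusted"],
        [1 - 0.999 ** 3, max(1 - 0.98 ** 2, 1 - 0.999 ** 3), 0.04],
        atol=1e-12)
    # stopping: a large p blocks everything after it in rank order
    res2 = holm_sidak([0.001, 0.9, 0.04])
    assert list(res2["reject"]) == [True, False, False]


def test_holm_sidak_trivial_cases():
    assert not any(holm_sidak([1.0, 1.0])["reject"])
    single = holm_sidak([0.04])
    assert single["reject"][0]
    assert single["p_adjusted"][0] == pytest.approx(0.04)
    with pytest.raises(ValueError):
        holm_sidak([0.5, 1.2])


def test_holm_sidak_never_fewer_rejections_than_bonferroni(rng):
    for _ in range(50):
        p = rng.uniform(0, 0.2, size=6)
        hs = holm_sidak(p)["reject"].sum()
        bonf = (p < 0.05 / len(p)).sum()
        assert hs >= bonf


def test_anova_all_equal_gives_zero_f():
    df = pd.DataFrame({"g": ["a", "b"] * 10, "s": ["x"] * 10 + ["y"] * 10,
                       "v": 3.14})
    res = factorial_anova(df, "v", ["g", "s"])
    assert (res.table["F"] == 0).all()


def test_anova_balanced_2x2_matches_textbook_formula(rng):
    """Cell means (0, 2, 1, 3): main effects from the marginal-mean
    contrasts, computed against the closed-form two-way ANOVA."""
    n = 25
    cells = {("a", "x"): 0.0, ("a", "y"): 2.0,
             ("b", "x"): 1.0, ("b", "y"): 3.0}
    rows = []
    for (g, s), mu in cells.items():
        for v in mu + rng.standard_normal(n):
            rows.append({"g": g, "s": s, "v": v})
    df = pd.DataFrame(rows)
    res = factorial_anova(df, "v", ["g", "s"])

    # textbook sums of squares for a balanced 2×2
    grand = df["v"].mean()
    ss_g = sum(2 * n * (df[df.g == lv]["v"].mean() - grand) ** 2
               for lv in ("a", "b"))
    ss_s = sum(2 * n * (df[df.s == lv]["v"].mean() - grand) ** 2
               for lv in ("x", "y"))
    cell_means = df.groupby(["g", "s"])["v"].mean()
    ss_cells = sum(n * (cell_means[k] - grand) ** 2 for k in cell_means.index)
    ss_int = ss_cells - ss_g - ss_s
    ss_err = sum((df["v"] - df.groupby(["g", "s"])["v"]
                  .transform("mean")) ** 2)
    ms_err = ss_err / (4 * n - 4)
    assert res.f("g") == pytest.approx(ss_g / ms_err, rel=1e-6)
    assert res.f("s") == pytest.approx(ss_s / ms_err, rel=1e-6)
    assert res.f("g:s") == pytest.approx(ss_int / ms_err, rel=1e-6)


def test_anova_empty_cell_named():
    df = pd.DataFrame({"g": ["a", "a", "b"], "s": ["x", "y", "x"],
                       "v": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="empty design cell"):
        factorial_anova(df, "v", ["g", "s"])
    with pytest.raises(ValueError, match="levels"):
        factorial_anova(pd.DataFrame({"g": ["a"] * 4, "v": [1.0] * 4}),
                        "v", ["g"])


def test_pearson_hand_values():
    assert pearson([1, 2, 3, 4], [1, 2, 3, 4])["r"] == pytest.approx(1.0)
    assert pearson([1, 2, 3, 4], [-1, -2, -3, -4])["r"] \
        == pytest.approx(-1.0)
    res = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res["r"] == pytest.approx(0.8)
    with pytest.raises(ValueError):
        pearson([1, 1, 1], [1, 2, 3])


def test_ttest_sanity(rng):
    a = rng.standard_normal(30)
    b = rng.standard_normal(30) + 2.0
    assert ttest(a, b)["p"] < 0.001
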