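"""Split-plot ANOVA, post-hoc contrasts, regression and table assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from mipac.containers import SsPacMap
from mipac.group import (
    EFFECTS,
    behavior_regression,
    build_cohort_table,
    default_posthoc_contrasts,
    posthoc_ttests,
    split_plot_anova,
)

LANGS = ("L1", "L2")
HEMIS = ("left", "right")


def make_table(y, grades):
    """Long table from a subjects x 4 matrix, cells (L1,l),(L1,r),(L2,l),(L2,r)."""
    rows = []
    for i, (vals, g) in enumerate(zip(y, grades)):
        for k, (lang, hemi) in enumerate([(l, h) for l in LANGS for h in HEMIS]):
            rows.append(
                {
                    "subject_id": f"s{i:02d}",
                    "grade": int(g),
                    "language": lang,
                    "hemisphere": hemi,
                    "sspac": float(vals[k]),
                }
            )
    return pd.DataFrame(rows)


def oracle_split_plot(y, grades):
    """Independent oracle: split-plot sums of squares from cell means.

    Computed directly from weighted marginal means of the
    Grade x Language x Hemisphere x Subject layout (every subject seen at
    all four within cells).
    """
    y = np.asarray(y, dtype=float)
    grades = np.asarray(grades)
    n = y.shape[0]
    glev = np.unique(grades)
    grand = y.mean()
    cell = y.reshape(n, 2, 2)  # subject x language x hemisphere

    m_subj = cell.mean(axis=(1, 2))
    m_grade = np.array([m_subj[grades == g].mean() for g in glev])
    m_lang = cell.mean(axis=(0, 2))
    m_hemi = cell.mean(axis=(0, 1))
    m_lh = cell.mean(axis=0)
    m_gl = np.array([cell[grades == g].mean(axis=(0, 2)) for g in glev])
    m_gh = np.array([cell[grades == g].mean(axis=(0, 1)) for g in glev])
    m_glh = np.array([cell[grades == g].mean(axis=0) for g in glev])
    ng = np.array([(grades == g).sum() for g in glev])

    ss = {}
    ss["Grade"] = 4 * np.sum(ng * (m_grade - grand) ** 2)
    ss["Subject(Grade)"] = 4 * sum(
        ((m_subj[grades == g] - m_grade[k]) ** 2).sum() for k, g in enumerate(glev)
    )
    ss["Language"] = 2 * n * np.sum((m_lang - grand) ** 2)
    ss["Hemisphere"] = 2 * n * np.sum((m_hemi - grand) ** 2)
    ss["Grade x Language"] = 2 * np.sum(
        ng[:, None] * (m_gl - m_grade[:, None] - m_lang[None, :] + grand) ** 2
    )
    ss["Grade x Hemisphere"] = 2 * np.sum(
        ng[:, None] * (m_gh - m_grade[:, None] - m_hemi[None, :] + grand) ** 2
    )
    ss["Language x Hemisphere"] = n * np.sum(
        (m_lh - m_lang[:, None] - m_hemi[None, :] + grand) ** 2
    )
    ss["Grade x Language x Hemisphere"] = np.sum(
        ng[:, None, None]
        * (
            m_glh
            - m_gl[:, :, None]
            - m_gh[:, None, :]
            - m_lh[None, :, :]
            + m_grade[:, None, None]
            + m_lang[None, :, None]
            + m_hemi[None, None, :]
            - grand
        )
        ** 2
    )
    # error strata from subject-level interactions with the within factors
    m_sl = cell.mean(axis=2)  # subject x language
    m_sh = cell.mean(axis=1)
    gi = np.searchsorted(glev, grades)
    ss["Language x Subject(Grade)"] = 2 * np.sum(
        (m_sl - m_subj[:, None] - m_gl[gi] + m_grade[gi][:, None]) ** 2
    )
    ss["Hemisphere x Subject(Grade)"] = 2 * np.sum(
        (m_sh - m_subj[:, None] - m_gh[gi] + m_grade[gi][:, None]) ** 2
    )
    total = ((y - grand) ** 2).sum()
    ss["Language x Hemisphere x Subject(Grade)"] = total - sum(
        ss[k]
        for k in (
            "Grade",
            "Subject(Grade)",
            "Language",
            "Hemisphere",
            "Grade x Language",
            "Grade x Hemisphere",
            "Language x Hemisphere",
            "Grade x Language x Hemisphere",
            "Language x Subject(Grade)",
            "Hemisphere x Subject(Grade)",
        )
    )
    ss["total"] = total
    return ss


ERROR_OF = {
    "Grade": "Subject(Grade)",
    "Language": "Language x Subject(Grade)",
    "Grade x Language": "Language x Subject(Grade)",
    "Hemisphere": "Hemisphere x Subject(Grade)",
    "Grade x Hemisphere": "Hemisphere x Subject(Grade)",
    "Language x Hemisphere": "Language x Hemisphere x Subject(Grade)",
    "Grade x Language x Hemisphere": "Language x Hemisphere x Subject(Grade)",
}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_anova_matches_cell_mean_oracle(seed):
    rng = np.random.default_rng(seed)
    grades = np.repeat([1, 2, 3], 4)
    y = rng.standard_normal((12, 4)) + rng.standard_normal((12, 1))
    res = split_plot_anova(make_table(y, grades))
    oracle = oracle_split_plot(y, grades)
    for effect in EFFECTS:
        row = res.effect(effect)
        assert row["ss"] == pytest.approx(oracle[effect], abs=1e-9), effect
        assert row["ss_error"] == pytest.approx(oracle[ERROR_OF[effect]], abs=1e-9), effect
        assert 0.0 <= row["pes"] <= 1.0


@pytest.mark.parametrize("seed", [3, 4])
def test_anova_total_ss_conservation(seed):
    rng = np.random.default_rng(seed)
    grades = np.repeat([1, 2, 3], [5, 4, 4])  # unbalanced groups
    y = rng.standard_normal((13, 4))
    res = split_plot_anova(make_table(y, grades))
    tab = res.table
    strata_err = (
        tab.loc["Grade", "ss_error"]
        + tab.loc["Language", "ss_error"]
        + tab.loc["Hemisphere", "ss_error"]
        + tab.loc["Language x Hemisphere", "ss_error"]
    )
    total = ((y - y.mean()) ** 2).sum()
    assert tab["ss"].sum() + strata_err == pytest.approx(total, rel=1e-9)


def test_anova_dfs_match_design():
    rng = np.random.default_rng(9)
    grades = np.repeat([1, 2, 3], [13, 13, 12])
    res = split_plot_anova(make_table(rng.standard_normal((38, 4)), grades))
    tab = res.table
    assert tab.loc["Grade", "df"] == 2 and tab.loc["Grade", "df_error"] == 35
    assert tab.loc["Language", "df"] == 1 and tab.loc["Language", "df_error"] == 35
    assert tab.loc["Grade x Language x Hemisphere", "df"] == 2


def test_grade_f_equals_t_squared_two_groups(rng):
    """Collapsing the within factors, F(Grade) is the squared pooled t."""
    subj_vals = rng.standard_normal(10) + np.repeat([0.0, 1.0], 5)
    y = np.tile(subj_vals[:, None], (1, 4))  # constant across within cells
    grades = np.repeat([1, 2], 5)
    with pytest.warns(RuntimeWarning):  # within strata are degenerate
        res = split_plot_anova(make_table(y, grades))
    t = sst.ttest_ind(subj_vals[:5], subj_vals[5:]).statistic
    assert res.effect("Grade")["F"] == pytest.approx(t**2, rel=1e-10)


def test_anova_constant_dv_degenerate():
    y = np.full((6, 4), 2.5)
    with pytest.warns(RuntimeWarning):
        res = split_plot_anova(make_table(y, np.repeat([1, 2, 3], 2)))
    assert (res.table["F"] == 0.0).all()


def test_anova_missing_cell_is_design_error():
    rng = np.random.default_rng(0)
    table = make_table(rng.standard_normal((6, 4)), np.repeat([1, 2, 3], 2))
    broken = table.drop(table[(table.subject_id == "s00") & (table.hemisphere == "right")
                              & (table.language == "L2")].index)
    with pytest.raises(ValueError):
        split_plot_anova(broken)


# ---------------------------------------------------------------- post hocs


def test_posthoc_identical_paired_cells():
    rng = np.random.default_rng(1)
    y = rng.standard_normal((6, 4))
    y[:, 2:] = y[:, :2]  # L2 == L1
    table = make_table(y, np.repeat([1, 2, 3], 2))
    (res,) = posthoc_ttests(
        table, [("L1 vs L2", {"language": "L1"}, {"language": "L2"})]
    )
    assert res.paired and res.t == 0.0 and res.cohen_d == 0.0 and res.p_bonferroni == 1.0


def test_posthoc_bonferroni_cap_at_one(rng):
    y = rng.standard_normal((12, 4))
    table = make_table(y, np.repeat([1, 2, 3], 4))
    results = posthoc_ttests(table, default_posthoc_contrasts())
    assert len(results) == 9
    weak = [r for r in results if r.p_raw > 0.2]
    assert weak and all(r.p_bonferroni == 1.0 for r in weak)
    assert all(r.p_bonferroni == min(1.0, r.p_raw * 9) for r in results)


def test_posthoc_hand_worked_paired_example():
    """n=5 paired differences 1..5: t = 3/(sqrt(2.5)/sqrt(5)), d = 3/sqrt(2.5)."""
    base = np.zeros((5, 4))
    base[:, 0] = base[:, 1] = np.arange(1.0, 6.0)  # L1 cells
    table = make_table(base, [1, 1, 1, 2, 2])
    (res,) = posthoc_ttests(table, [("L1 vs L2", {"language": "L1"}, {"language": "L2"})])
    assert res.paired and res.df == 4
    assert res.t == pytest.approx(3.0 / (np.sqrt(2.5) / np.sqrt(5)))
    assert res.cohen_d == pytest.approx(3.0 / np.sqrt(2.5))
    assert res.p_raw == pytest.approx(2 * sst.t.sf(res.t, 4))


def test_posthoc_independent_matches_scipy(rng):
    y = rng.standard_normal((10, 4))
    y[5:] += 1.0
    table = make_table(y, np.repeat([1, 2], 5))
    (res,) = posthoc_ttests(
        table, [("G2 vs G1", {"grade": 2}, {"grade": 1})]
    )
    assert not res.paired and res.df == 8
    a = y[5:].mean(axis=1)
    b = y[:5].mean(axis=1)
    ref = sst.ttest_ind(a, b)
    assert res.t == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-10)


def test_posthoc_empty_cell_error(rng):
    table = make_table(rng.standard_normal((4, 4)), [1, 1, 2, 2])
    with pytest.raises(ValueError):
        posthoc_ttests(table, [("bad", {"grade": 3}, {"grade": 1})])


# ---------------------------------------------------------------- regression


def _reg_table(rng, n=38, slope=0.0, noise=1.0):
    rows = []
    for i in range(n):
        x_left, x_right = rng.standard_normal(2)
        score = 50 + slope * x_left + noise * rng.standard_normal()
        for lang in LANGS:
            for hemi, x in zip(HEMIS, (x_left, x_right)):
                rows.append(
                    {"subject_id": f"s{i}", "grade": 1 + i % 3, "language": lang,
                     "hemisphere": hemi, "sspac": x, "picture_naming_pct": score}
                )
    return pd.DataFrame(rows)


def test_regression_collinear_perfect_fit(rng):
    table = _reg_table(rng, slope=2.0, noise=0.0)
    results = behavior_regression(table, ["picture_naming_pct"])
    left = next(r for r in results if r.hemisphere == "left")
    assert left.r == pytest.approx(1.0)
    assert left.slope == pytest.approx(2.0)
    assert left.significant


def test_regression_zero_variance_predictor(rng):
    table = _reg_table(rng)
    table["sspac"] = 1.0
    with pytest.raises(ValueError):
        behavior_regression(table, ["picture_naming_pct"])


def test_regression_type_one_rate_controlled():
    """With no true link, the 0.005 flag fires at ~its nominal rate."""
    rng = np.random.default_rng(12)
    flags = n_tests = 0
    for _ in range(300):
        results = behavior_regression(_reg_table(rng, slope=0.0), ["picture_naming_pct"])
        flags += sum(r.significant for r in results)
        n_tests += len(results)
    # exact binomial: P(X >= 9) < 0.1% at p = 0.005, n = 600
    assert flags / n_tests <= 9 / 600


# ---------------------------------------------------------------- cohort table


def _sspac_map(subject, grade, language, hemisphere, value=0.0):
    return SsPacMap(
        phase_freqs=np.array([3.0, 5.0, 7.0]),
        amp_freqs=np.array([25.0, 30.0, 35.0]),
        values=np.full((3, 3), value),
        meta={"subject_id": subject, "grade": grade, "language": language,
              "hemisphere": hemisphere},
    )


def test_build_cohort_table_counts_and_join():
    maps, sspow = [], {}
    for i in range(38):
        sid = f"s{i:02d}"
        for lang in LANGS:
            for hemi in HEMIS:
                maps.append(_sspac_map(sid, 1 + i % 3, lang, hemi, value=0.1 * i))
                sspow[(sid, lang, hemi)] = float(i)
    behavior = pd.DataFrame(
        [{"subject_id": f"s{i:02d}", "language": lang, "picture_naming_pct": 50.0}
         for i in range(38) for lang in LANGS]
    )
    table = build_cohort_table(maps, sspow, behavior)
    assert len(table) == 152
    assert table.loc[0, "sspac"] == pytest.approx(0.0)
    assert {"sspow", "picture_naming_pct"} <= set(table.columns)


def test_build_cohort_table_missing_hemisphere_names_subject():
    maps = [_sspac_map("s00", 1, lang, "left") for lang in LANGS]
    maps += [
        _sspac_map("s01", 1, lang, hemi) for lang in LANGS for hemi in HEMIS
    ]
    with pytest.raises(ValueError, match="s00"):
        build_cohort_table(maps)


def test_build_cohort_table_without_behavior():
    maps = [_sspac_map("s00", 1, lang, hemi) for lang in LANGS for hemi in HEMIS]
    table = build_cohort_table(maps, behavior=pd.DataFrame())
    assert not any(c.endswith("_pct") for c in table.columns)
    with pytest.raises(ValueError):
        behavior_regression(table)
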