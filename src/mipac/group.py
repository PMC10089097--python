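"""Band-averaged group-level inference: split-plot ANOVA, post-hoc
contrasts, and brain-behavior regression.

The design has one between-subject factor (Grade: three proficiency
groups) and two two-level within-subject factors (Language: L1/L2;
Hemisphere: left/right).  The split-plot decomposition is computed from
orthonormal within-subject contrasts: the between stratum is a one-way
ANOVA on subject means, and each within-subject effect reduces to a
one-way Grade ANOVA on the corresponding subject-level contrast, whose
residual forms that stratum's error term.  With two-level within factors
no sphericity correction is required.  Group means are weighted by
subject counts (the groups may be mildly unbalanced, e.g. 13/13/12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .containers import HEMISPHERES, LANGUAGES, SsPacMap
from .pac import GAMMA_AMP_BAND, THETA_PHASE_BAND, band_average

EFFECTS = (
    "Grade",
    "Language",
    "Hemisphere",
    "Grade x Language",
    "Grade x Hemisphere",
    "Language x Hemisphere",
    "Grade x Language x Hemisphere",
)

# Cell order (language, hemisphere): (L1,left), (L1,right), (L2,left), (L2,right)
_C_MEAN = np.array([0.5, 0.5, 0.5, 0.5])
_C_LANG = np.array([-0.5, -0.5, 0.5, 0.5])
_C_HEMI = np.array([-0.5, 0.5, -0.5, 0.5])
_C_INTER = np.array([0.5, -0.5, -0.5, 0.5])


@dataclass
class AnovaResult:
    """Split-plot ANOVA table: one row per effect.

    Columns: ss, df, ss_error, df_error, F, p, pes (partial eta squared,
    SS_effect / (SS_effect + SS_error_stratum)).
    """

    table: pd.DataFrame
    dv: str

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _one_way_parts(z: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """(SS_mean, SS_group, SS_resid) of a subject-level variable.

    SS_mean is the projection onto the grand mean (N * zbar^2); SS_group
    the weighted between-group SS; SS_resid the within-group SS.
    """
    n = z.size
    zbar = z.mean()
    ss_mean = n * zbar**2
    ss_group = 0.0
    ss_resid = 0.0
    for g in np.unique(groups):
        zg = z[groups == g]
        ss_group += zg.size * (zg.mean() - zbar) ** 2
        ss_resid += float(np.sum((zg - zg.mean()) ** 2))
    return float(ss_mean), float(ss_group), float(ss_resid)


def _wide_design(table: pd.DataFrame, dv: str) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x 4 cell matrix in fixed (language, hemisphere) order."""
    required = {"subject_id", "grade", "language", "hemisphere", dv}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns {sorted(missing)}")
    wide = table.pivot_table(
        index=["subject_id", "grade"], columns=["language", "hemisphere"], values=dv
    )
    cells = [(lang, hemi) for lang in LANGUAGES for hemi in HEMISPHERES]
    for cell in cells:
        if cell not in wide.columns:
            raise ValueError(f"design cell {cell} missing from table")
    wide = wide[cells]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.get_level_values(0).tolist()
        raise ValueError(f"incomplete within-subject design for subjects {bad}")
    grades = wide.index.get_level_values("grade").to_numpy()
    if np.unique(grades).size < 2:
        raise ValueError("need at least two grade groups")
    counts = pd.Series(grades).value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per grade")
    return wide.to_numpy(dtype=float), grades


def split_plot_anova(table: pd.DataFrame, dv: str = "sspac") -> AnovaResult:
    """Three-way split-plot ANOVA of a long cohort table.

    Between factor Grade; within factors Language and Hemisphere.  Error
    terms: Grade is tested against Subject-within-Grade; each within
    effect (and its Grade interaction) against the corresponding
    contrast-by-Subject-within-Grade stratum.
    """
    y, grades = _wide_design(table, dv)
    n = y.shape[0]
    n_groups = np.unique(grades).size
    df_subj = n - n_groups

    rows = {}
    # Between stratum: orthonormal mean contrast.
    _, ss_grade, ss_subj = _one_way_parts(y @ _C_MEAN, grades)
    rows["Grade"] = (ss_grade, n_groups - 1, ss_subj, df_subj)
    # Within strata.
    for name, c in (("Language", _C_LANG), ("Hemisphere", _C_HEMI), ("Language x Hemisphere", _C_INTER)):
        ss_main, ss_int, ss_err = _one_way_parts(y @ c, grades)
        rows[name] = (ss_main, 1, ss_err, df_subj)
        rows[f"Grade x {name}"] = (ss_int, n_groups - 1, ss_err, df_subj)

    records = []
    for effect in EFFECTS:
        ss, df1, ss_err, df2 = rows[effect]
        ms = ss / df1
        ms_err = ss_err / df2 if df2 > 0 else 0.0
        if ms_err == 0.0:
            if ss != 0.0:
                f = np.inf
            else:
                warnings.warn(f"degenerate ANOVA ({effect}): zero error SS", RuntimeWarning)
                f = 0.0
        else:
            f = ms / ms_err
        p = float(sst.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        records.append(
            {"effect": effect, "ss": ss, "df": df1, "ss_error": ss_err, "df_error": df2,
             "F": float(f), "p": p, "pes": float(pes)}
        )
    out = pd.DataFrame(records).set_index("effect")
    return AnovaResult(table=out, dv=dv)


@dataclass
class ContrastResult:
    name: str
    paired: bool
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohen_d: float
    cohen_d_pooled: float
    n: int


def _cell_means(table: pd.DataFrame, filt: dict, dv: str) -> pd.Series:
    sub = table
    for key, val in filt.items():
        sub = sub[sub[key] == val]
    if sub.empty:
        raise ValueError(f"contrast selects no rows: {filt}")
    return sub.groupby("subject_id")[dv].mean()


def posthoc_ttests(
    table: pd.DataFrame,
    contrasts: list[tuple[str, dict, dict]],
    dv: str = "sspac",
) -> list[ContrastResult]:
    """Post-hoc t tests with Bonferroni correction over the contrast family.

    Each contrast is (name, cell_filter_a, cell_filter_b); cell filters
    are column -> value dicts, averaged over remaining within factors per
    subject.  If both cells cover the same subjects the test is paired
    (d = mean difference / sd of differences); otherwise an
    independent-samples pooled-variance t (d = mean difference / pooled
    sd).  Bonferroni multiplies p by the number of contrasts, capped at 1.
    """
    k = len(contrasts)
    results = []
    for name, filt_a, filt_b in contrasts:
        a = _cell_means(table, filt_a, dv)
        b = _cell_means(table, filt_b, dv)
        paired = set(a.index) == set(b.index)
        if paired:
            d = (a - b.reindex(a.index)).to_numpy()
            n = d.size
            sd = d.std(ddof=1)
            t = 0.0 if sd == 0 else d.mean() / (sd / np.sqrt(n))
            df = n - 1
            cohen = 0.0 if sd == 0 else d.mean() / sd
            pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            cohen_pooled = 0.0 if pooled_sd == 0 else (a.mean() - b.mean()) / pooled_sd
            n_used = n
        else:
            xa, xb = a.to_numpy(), b.to_numpy()
            na, nb = xa.size, xb.size
            sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
            se = np.sqrt(sp2 * (1 / na + 1 / nb))
            t = 0.0 if se == 0 else (xa.mean() - xb.mean()) / se
            df = na + nb - 2
            cohen = cohen_pooled = 0.0 if sp2 == 0 else (xa.mean() - xb.mean()) / np.sqrt(sp2)
            n_used = na + nb
        p_raw = float(2 * sst.t.sf(abs(t), df)) if df > 0 else 1.0
        results.append(
            ContrastResult(
                name=name, paired=paired, t=float(t), df=int(df), p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * k), cohen_d=float(cohen),
                cohen_d_pooled=float(cohen_pooled), n=n_used,
            )
        )
    return results


@dataclass
class RegressionResult:
    score: str
    hemisphere: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    significant: bool


def behavior_regression(
    table: pd.DataFrame,
    scores: list[str] | None = None,
    dv: str = "sspac",
    language: str = "L2",
    alpha_threshold: float = 0.005,
) -> list[RegressionResult]:
    """OLS of each behavioral score on band-averaged ssPAC, per hemisphere.

    The significance flag applies a Bonferroni-style fixed p threshold
    (default 0.005) across the family of (score, hemisphere) tests.
    """
    if scores is None:
        scores = [c for c in table.columns if c.endswith("_pct")]
    if not scores:
        raise ValueError("no behavioral score columns found")
    out = []
    for score in scores:
        for hemi in HEMISPHERES:
            sub = table[(table["language"] == language) & (table["hemisphere"] == hemi)]
            sub = sub.dropna(subset=[score, dv])
            if len(sub) < 4:
                raise ValueError(f"need >=4 subjects for regression ({score}, {hemi})")
            x = sub[dv].to_numpy(dtype=float)
            y = sub[score].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"zero-variance predictor for ({score}, {hemi})")
            fit = sst.linregress(x, y)
            out.append(
                RegressionResult(
                    score=score, hemisphere=hemi, slope=float(fit.slope),
                    intercept=float(fit.intercept), r=float(fit.rvalue),
                    p=float(fit.pvalue), n=len(sub),
                    significant=bool(fit.pvalue < alpha_threshold),
                )
            )
    return out


def build_cohort_table(
    sspac_maps: list[SsPacMap],
    sspow: dict[tuple[str, str, str], float] | None = None,
    behavior: pd.DataFrame | None = None,
    phase_band: tuple[float, float] = THETA_PHASE_BAND,
    amp_band: tuple[float, float] = GAMMA_AMP_BAND,
) -> pd.DataFrame:
    """Long cohort table of band-averaged ssPAC (and optional ssPow, scores).

    One row per subject x language x hemisphere; every subject must
    contribute all four neural rows.  ``sspow`` maps (subject_id,
    language, hemisphere) to the speech-specific gamma power; behavior
    rows are joined on (subject_id, language).
    """
    rows = []
    for m in sspac_maps:
        meta = m.meta
        for key in ("subject_id", "grade", "language", "hemisphere"):
            if key not in meta:
                raise ValueError(f"ssPAC map meta lacks {key!r}")
        row = {
            "subject_id": meta["subject_id"],
            "grade": int(meta["grade"]),
            "language": meta["language"],
            "hemisphere": meta["hemisphere"],
            "sspac": band_average(m, phase_band, amp_band),
        }
        if sspow is not None:
            key = (meta["subject_id"], meta["language"], meta["hemisphere"])
            if key not in sspow:
                raise ValueError(f"missing ssPow value for {key}")
            row["sspow"] = float(sspow[key])
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = table.groupby("subject_id").size()
    bad = counts[counts != 4]
    if not bad.empty:
        raise ValueError(
            f"each subject needs 2 languages x 2 hemispheres; offending subjects: "
            f"{bad.index.tolist()}"
        )
    grade_n = table.groupby("subject_id")["grade"].nunique()
    if (grade_n != 1).any():
        raise ValueError("grade must be constant within subject")
    if behavior is not None and not behavior.empty:
        table = table.merge(behavior, on=["subject_id", "language"], how="left")
    return table


def default_posthoc_contrasts() -> list[tuple[str, dict, dict]]:
    """The standard contrast family: L1 vs L2 within each grade, and
    pairwise grade comparisons within each language."""
    contrasts: list[tuple[str, dict, dict]] = []
    for g in (1, 2, 3):
        contrasts.append(
            (f"L1 vs L2, Grade {g}", {"grade": g, "language": "L1"}, {"grade": g, "language": "L2"})
        )
    for lang in LANGUAGES:
        for ga, gb in ((2, 1), (3, 1), (3, 2)):
            contrasts.append(
                (
                    f"{lang}: Grade {ga} vs {gb}",
                    {"grade": ga, "language": lang},
                    {"grade": gb, "language": lang},
                )
            )
    return contrasts
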