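"""Scoring and statistics, checked against brute-force sums-of-squares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from carilow.rating_analysis import (
    StatResult,
    UndefinedRelativeEffectivenessError,
    WorkbookSchemaError,
    analyze_ratings,
    condition_means,
    load_ratings_workbook,
    paired_t,
    re_per_resolution,
    relative_effectiveness,
    reproduce_published,
    rm_anova,
    rm_anova_2way,
    sex_check_anova,
    within_subject_sem,
)

# ---------------------------------------------------------------------------
# independent oracles: explicit sums-of-squares decompositions
# ---------------------------------------------------------------------------


def oneway_rm_oracle(x):
    """x: participants x levels.  Returns (F, df, MSE) by explicit SS sums."""
    n, a = x.shape
    grand = x.mean()
    ss_subj = a * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_cond
    mse = ss_err / ((a - 1) * (n - 1))
    return ss_cond / (a - 1) / mse, (a - 1, (a - 1) * (n - 1)), mse


def twoway_rm_oracle(x):
    """x: participants x A x B.  Returns dict of (F, df) for A, B, AB."""
    n, a, b = x.shape
    grand = x.mean()
    s_m = x.mean(axis=(1, 2))
    a_m = x.mean(axis=(0, 2))
    b_m = x.mean(axis=(0, 1))
    sa_m = x.mean(axis=2)
    sb_m = x.mean(axis=1)
    ab_m = x.mean(axis=0)

    ss_a = n * b * ((a_m - grand) ** 2).sum()
    ss_b = n * a * ((b_m - grand) ** 2).sum()
    ss_ab = n * ((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    ss_sa = b * ((sa_m - s_m[:, None] - a_m[None, :] + grand) ** 2).sum()
    ss_sb = a * ((sb_m - s_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    resid = (
        x
        - sa_m[:, :, None]
        - sb_m[:, None, :]
        - ab_m[None, :, :]
        + s_m[:, None, None]
        + a_m[None, :, None]
        + b_m[None, None, :]
        - grand
    )
    ss_sab = (resid**2).sum()

    out = {}
    out["A"] = (ss_a / (a - 1) / (ss_sa / ((a - 1) * (n - 1))), (a - 1, (a - 1) * (n - 1)))
    out["B"] = (ss_b / (b - 1) / (ss_sb / ((b - 1) * (n - 1))), (b - 1, (b - 1) * (n - 1)))
    df_ab = (a - 1) * (b - 1)
    out["AB"] = (ss_ab / df_ab / (ss_sab / (df_ab * (n - 1))), (df_ab, df_ab * (n - 1)))
    return out


def _long_2way(x, res_labels=("R1", "R2", "R3"), car_labels=("V", "C-68p", "C-147p")):
    n, a, b = x.shape
    rows = [
        {"participant": p, "resolution": res_labels[i], "caricature": car_labels[j],
         "mean_rating": x[p, i, j]}
        for p in range(n) for i in range(a) for j in range(b)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _toy_ratings():
    rows = []
    # two participants, 3x3 grid, two trials per cell with known means
    for p, base in ((0, 3.0), (1, 5.0)):
        for ri, res in enumerate(["R1", "R2", "R3"]):
            for ci, car in enumerate(["V", "C-68p", "C-147p"]):
                for k, sex in enumerate(["M", "F"]):
                    rows.append(
                        {"participant": p, "resolution": res, "caricature": car,
                         "sex": sex, "rating": base + ri + 0.5 * ci + k}
                    )
    return pd.DataFrame(rows)


def test_condition_means_constant_table():
    df = _toy_ratings().assign(rating=5.0)
    cm = condition_means(df)
    assert (cm["mean_rating"] == 5.0).all()
    assert len(cm) == 2 * 9


def test_condition_means_match_manual_computation():
    cm = condition_means(_toy_ratings())
    # participant 0, R2, C-68p: ratings 3+1+0.5+{0,1} -> mean 5.0
    cell = cm[(cm.participant == 0) & (cm.resolution == "R2") & (cm.caricature == "C-68p")]
    assert cell["mean_rating"].iloc[0] == pytest.approx(5.0)


def test_sex_collapse_equals_weighted_mean_of_sex_cells():
    df = _toy_ratings()
    collapsed = condition_means(df, collapse_sex=True)
    split = condition_means(df, collapse_sex=False)
    merged = (
        split.groupby(["participant", "resolution", "caricature"])["mean_rating"]
        .mean()  # balanced design: simple mean of sex cells
        .reset_index()
    )
    joined = collapsed.merge(merged, on=["participant", "resolution", "caricature"])
    assert np.allclose(joined["mean_rating_x"], joined["mean_rating_y"])


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------


def test_paired_t_zero_for_identical_samples():
    res = paired_t([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.df == 2


def test_paired_t_three_value_worked_example():
    # differences 1, 2, 3: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641016...
    res = paired_t([5.0, 7.0, 9.0], [4.0, 5.0, 6.0])
    assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
    assert res.df == 2
    assert res.p == pytest.approx(0.07417990022744862, rel=1e-9)


@given(shift=st.floats(-10, 10))
def test_paired_t_invariant_to_per_participant_constants(shift):
    a = np.array([4.1, 5.2, 6.3, 5.5])
    b = np.array([3.9, 5.0, 5.1, 5.4])
    c = np.full(4, shift)
    r1 = paired_t(a, b)
    r2 = paired_t(a + c, b + c)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# ANOVAs and within-subject error bars
# ---------------------------------------------------------------------------


def test_within_subject_sem_zero_for_additive_data():
    subj = np.array([3.0, 4.0, 5.0, 6.0])[:, None]
    cond = np.array([0.0, 0.5, 1.0])[None, :]
    assert within_subject_sem(subj + cond) == pytest.approx(0.0, abs=1e-12)


def test_within_subject_sem_matches_ss_oracle(rng):
    x = rng.normal(5, 1, size=(4, 3))
    _, _, mse = oneway_rm_oracle(x)
    assert within_subject_sem(x) == pytest.approx(np.sqrt(mse / 4), rel=1e-9)


def test_within_subject_sem_scales_inverse_sqrt_n(rng):
    n = 5
    x = rng.normal(5, 1, size=(n, 3))
    doubled = np.vstack([x, x])  # participant duplication: SS doubles, 2N
    # exact relation: 1/sqrt(2) scaling times the residual-df correction
    df_factor = np.sqrt(2 * (n - 1) / (2 * n - 1))
    assert within_subject_sem(doubled) == pytest.approx(
        within_subject_sem(x) / np.sqrt(2) * df_factor, rel=1e-9
    )


def test_two_way_rm_anova_matches_ss_oracle(rng):
    x = rng.normal(5, 1, size=(5, 3, 3))
    result, table = rm_anova_2way(_long_2way(x))
    oracle = twoway_rm_oracle(x)
    f, df = oracle["AB"]
    assert result.statistic == pytest.approx(f, rel=1e-9)
    assert result.df == df
    # main effects agree too
    assert table.loc["resolution", "F Value"] == pytest.approx(oracle["A"][0], rel=1e-9)
    assert table.loc["caricature", "F Value"] == pytest.approx(oracle["B"][0], rel=1e-9)


def test_interaction_df_is_4_and_76_at_twenty_participants(rng):
    x = rng.normal(5, 1, size=(20, 3, 3))
    result, _ = rm_anova_2way(_long_2way(x))
    assert result.df == (4, 76)


def test_additive_data_interaction_f_near_one(rng):
    """Monte-Carlo: with no true interaction, E[F] = den/(den-2)."""
    fs = []
    for _ in range(300):
        x = rng.normal(0, 1, size=(10, 3, 3))
        x += rng.normal(0, 1, size=(10, 1, 1))  # participant offsets
        x += np.arange(3)[None, :, None] * 0.5  # additive main effects
        f, (d1, d2) = twoway_rm_oracle(x)["AB"]
        fs.append(f)
    assert np.mean(fs) == pytest.approx(36 / 34, abs=0.12)


def test_sex_check_anova_df_and_null_behaviour(rng):
    rows = []
    for p in range(20):
        off = rng.normal(0, 1)
        for res in ("R1", "R2", "R3"):
            for car in ("V", "C-68p", "C-147p"):
                for sex in ("M", "F"):
                    rows.append(
                        {"participant": p, "resolution": res, "caricature": car,
                         "sex": sex, "mean_rating": 5 + off + rng.normal(0, 0.5)}
                    )
    table = sex_check_anova(pd.DataFrame(rows))
    assert table.loc["sex", "Num DF"] == 1
    assert table.loc["sex", "Den DF"] == 19
    assert table.loc["sex", "Pr > F"] > 0.001  # symmetric data: no reliable effect


def test_sex_check_detects_injected_sex_effect(rng):
    hits = 0
    n_sim = 25
    for _ in range(n_sim):
        rows = []
        for p in range(20):
            off = rng.normal(0, 1)
            for res in ("R1", "R2", "R3"):
                for car in ("V", "C-68p", "C-147p"):
                    for sex in ("M", "F"):
                        bump = 0.5 if sex == "M" else 0.0
                        rows.append(
                            {"participant": p, "resolution": res, "caricature": car,
                             "sex": sex, "mean_rating": 5 + off + bump + rng.normal(0, 0.5)}
                        )
        table = sex_check_anova(pd.DataFrame(rows))
        hits += table.loc["sex", "Pr > F"] < 0.05
    assert hits / n_sim > 0.8


# ---------------------------------------------------------------------------
# relative effectiveness
# ---------------------------------------------------------------------------


def test_re_boundary_values():
    assert relative_effectiveness(4.0, 5.0, 5.0).re_percent == pytest.approx(100.0)
    assert relative_effectiveness(4.0, 4.0, 5.0).re_percent == pytest.approx(0.0)


def test_re_direct_substitution_example():
    assert relative_effectiveness(4.0, 4.52, 5.0).re_percent == pytest.approx(52.0)


def test_re_literal_printed_orientation_is_reciprocal():
    re = relative_effectiveness(4.0, 4.52, 5.0, literal_printed=True)
    assert re.re_percent == pytest.approx(100 * 1.0 / 0.52, rel=1e-9)


def test_re_undefined_when_reference_gain_vanishes():
    with pytest.raises(UndefinedRelativeEffectivenessError):
        relative_effectiveness(5.0, 5.2, 5.0)


@given(
    shift=st.floats(-3, 3),
    scale=st.floats(0.1, 4.0),
)
def test_re_invariant_to_affine_rescaling(shift, scale):
    base = relative_effectiveness(4.0, 4.7, 5.3).re_percent
    moved = relative_effectiveness(
        scale * 4.0 + shift, scale * 4.7 + shift, scale * 5.3 + shift
    ).re_percent
    assert moved == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# workbook ingestion
# ---------------------------------------------------------------------------


def _synthetic_ratings():
    from carilow.experiment_design import build_schedule
    from carilow.rater_sim import RaterModel, simulate_ratings
    from carilow import make_cohort
    from carilow.rater_sim import cohort_dissimilarities

    cohort = make_cohort(n_male=3, n_female=3, pool_size=6, seed=2, render=False)
    sched = build_schedule("E2", cohort.ids_by_sex("M"), cohort.ids_by_sex("F"), seed=2)
    model = RaterModel(seed=8)
    return simulate_ratings(sched, model, cohort_dissimilarities(cohort), n_participants=6)


def test_workbook_round_trip_reproduces_direct_analysis(tmp_path):
    ratings = _synthetic_ratings()
    path = tmp_path / "synthetic_ratings.xlsx"
    ratings.to_excel(path, index=False)
    report = reproduce_published(path)
    direct = analyze_ratings(ratings)
    assert report["re_overall"] == pytest.approx(direct["re_overall"], rel=1e-9)
    assert report["interaction"].statistic == pytest.approx(
        direct["interaction"].statistic, rel=1e-9
    )


def test_workbook_mapping_escape_hatch(tmp_path):
    ratings = _synthetic_ratings().rename(
        columns={"participant": "Subj", "rating": "Score"}
    )
    ratings["caricature"] = ratings["caricature"].map(
        {"V": "verid", "C-68p": "auto68", "C-147p": "hand147"}
    )
    path = tmp_path / "renamed.xlsx"
    ratings.to_excel(path, index=False)
    with pytest.raises(WorkbookSchemaError):
        load_ratings_workbook(path)
    mapping = {
        "participant": "Subj",
        "rating": "Score",
        "caricature_labels": {"verid": "V", "auto68": "C-68p", "hand147": "C-147p"},
    }
    out = load_ratings_workbook(path, mapping=mapping)
    assert set(out["caricature"]) == {"V", "C-68p", "C-147p"}
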