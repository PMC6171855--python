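"""Scoring and statistics for dissimilarity-rating tables.

Per participant, ratings are averaged within each (resolution, caricature)
cell — optionally split by face sex for the preliminary sex check — and the
cell means feed paired t-tests, repeated-measures ANOVAs (uncorrected df
throughout; the 3x3 interaction has df (4, 76) at N = 20), within-subject
error bars, and the relative-effectiveness statistic

    RE = 100 * (C68 - V) / (C147 - V),

the 68-point caricature's mean rating gain over veridical as a percentage of
the 147-point caricature's gain.  RE is invariant to any affine rescaling
applied uniformly to the three condition means, which is what makes it
comparable across rescaled blocks.  (Note the alternative orientation
100 * (C147 - V) / (C68 - V) is available via ``literal_printed=True``; it is
the reciprocal reading, reporting the 147-point gain relative to the
68-point gain.)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

CARICATURE_LEVELS = ("V", "C-68p", "C-147p")


class UndefinedRelativeEffectivenessError(ZeroDivisionError):
    """The reference caricature produced no gain over veridical."""


class WorkbookSchemaError(ValueError):
    """A published-data workbook does not match the expected layout."""


@dataclass(frozen=True)
class StatResult:
    """A single test statistic with its degrees of freedom and p value."""

    name: str
    statistic: float
    df: tuple[int, ...] | int
    p: float

    def __str__(self) -> str:
        if isinstance(self.df, tuple):
            dfs = ", ".join(str(d) for d in self.df)
            return f"{self.name}: F({dfs}) = {self.statistic:.2f}, p = {self.p:.4g}"
        return f"{self.name}: t({self.df}) = {self.statistic:.2f}, p = {self.p:.4g}"


@dataclass(frozen=True)
class RelativeEffectiveness:
    re_percent: float
    v_mean: float
    c68_mean: float
    c147_mean: float


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def condition_means(ratings: pd.DataFrame, collapse_sex: bool = True) -> pd.DataFrame:
    """Per-participant mean rating for each (resolution, caricature) cell.

    With ``collapse_sex=False`` the cells are additionally split by face sex,
    as in the preliminary sex-effect check.
    """
    keys = ["participant", "resolution", "caricature"]
    if not collapse_sex:
        keys.append("sex")
    out = ratings.groupby(keys, as_index=False)["rating"].mean()
    return out.rename(columns={"rating": "mean_rating"})


def _wide(cm: pd.DataFrame, resolution: str) -> pd.DataFrame:
    """participant x caricature-level wide grid for one resolution."""
    sub = cm[cm["resolution"] == resolution]
    wide = sub.pivot(index="participant", columns="caricature", values="mean_rating")
    missing = [c for c in CARICATURE_LEVELS if c not in wide.columns]
    if missing:
        raise ValueError(f"resolution {resolution!r} is missing levels {missing}")
    return wide[list(CARICATURE_LEVELS)]


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def paired_t(a: Sequence[float], b: Sequence[float], name: str = "paired t") -> StatResult:
    """Two-tailed paired-samples t-test (df = N - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.std(d, ddof=1) == 0:
        # degenerate case: constant differences
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
        return StatResult(name, float(t), len(a) - 1, p)
    res = stats.ttest_rel(a, b)
    return StatResult(name, float(res.statistic), len(a) - 1, float(res.pvalue))


def within_subject_sem(grid: np.ndarray | pd.DataFrame) -> float:
    """Within-subject error-bar half-width for a participants x levels grid.

    Runs a one-way repeated-measures decomposition and returns sqrt(MSE / N),
    where MSE is the condition x participant residual mean square — the error
    term appropriate for comparing levels varied within subjects.
    """
    x = np.asarray(grid, dtype=float)
    n, a = x.shape
    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    cond = x.mean(axis=0, keepdims=True)
    resid = x - subj - cond + grand
    mse = (resid**2).sum() / ((a - 1) * (n - 1))
    return float(np.sqrt(mse / n))


def rm_anova(
    means: pd.DataFrame, within: Sequence[str], depvar: str = "mean_rating"
) -> pd.DataFrame:
    """Repeated-measures ANOVA table (uncorrected df) for balanced cell means."""
    res = AnovaRM(
        means, depvar=depvar, subject="participant", within=list(within)
    ).fit()
    return res.anova_table


def rm_anova_2way(means: pd.DataFrame) -> tuple[StatResult, pd.DataFrame]:
    """3 x 3 (resolution x caricature) within-subjects ANOVA; returns the
    interaction statistic and the full table."""
    table = rm_anova(means, ["resolution", "caricature"])
    row = table.loc["resolution:caricature"]
    result = StatResult(
        "resolution x caricature interaction",
        float(row["F Value"]),
        (int(row["Num DF"]), int(row["Den DF"])),
        float(row["Pr > F"]),
    )
    return result, table


def sex_check_anova(means_by_sex: pd.DataFrame) -> pd.DataFrame:
    """Preliminary 3 x 3 x 2 (resolution x caricature x face sex) ANOVA.

    Input is the ``collapse_sex=False`` output of :func:`condition_means`.
    Used to justify collapsing scores across face sex when no sex effect or
    interaction is present.
    """
    return rm_anova(means_by_sex, ["resolution", "caricature", "sex"])


# ---------------------------------------------------------------------------
# relative effectiveness
# ---------------------------------------------------------------------------


def relative_effectiveness(
    v_mean: float,
    c68_mean: float,
    c147_mean: float,
    tolerance: float = 1e-9,
    literal_printed: bool = False,
) -> RelativeEffectiveness:
    """The 68-point gain over veridical as a percentage of the 147-point gain.

    RE = 100 when the two caricature levels are equally effective and 0 when
    the 68-point caricature adds nothing over veridical.  Undefined (raises)
    when the 147-point caricature itself produced no gain.
    """
    num, den = c68_mean - v_mean, c147_mean - v_mean
    if literal_printed:
        num, den = den, num
    if abs(den) < tolerance:
        raise UndefinedRelativeEffectivenessError(
            "reference caricature gain is zero; relative effectiveness undefined"
        )
    return RelativeEffectiveness(100.0 * num / den, v_mean, c68_mean, c147_mean)


def re_per_resolution(cm: pd.DataFrame, **kwargs) -> dict[str, RelativeEffectiveness]:
    """RE computed from group-level condition means, per resolution plot."""
    out: dict[str, RelativeEffectiveness] = {}
    for res in cm["resolution"].unique():
        wide = _wide(cm, res)
        m = wide.mean(axis=0)
        out[res] = relative_effectiveness(m["V"], m["C-68p"], m["C-147p"], **kwargs)
    return out


def re_overall(per_plot: Mapping[str, RelativeEffectiveness]) -> float:
    """Mean RE across resolution plots (six plots over the two experiments)."""
    return float(np.mean([r.re_percent for r in per_plot.values()]))


def re_from_grid(grid: np.ndarray, car_labels: Sequence[str] = CARICATURE_LEVELS) -> float:
    """Overall RE from a (participants x resolutions x caricature) mean grid.

    Group condition means are taken per resolution plot, RE computed per
    plot, then averaged — the same aggregation as the tabular route.
    """
    gm = np.asarray(grid, dtype=float).mean(axis=0)
    iv = list(car_labels).index("V")
    i68 = list(car_labels).index("C-68p")
    i147 = list(car_labels).index("C-147p")
    res = [
        relative_effectiveness(gm[i, iv], gm[i, i68], gm[i, i147]).re_percent
        for i in range(gm.shape[0])
    ]
    return float(np.mean(res))


# ---------------------------------------------------------------------------
# full report / published-workbook ingestion
# ---------------------------------------------------------------------------

#: default column mapping for a long-format ratings workbook
DEFAULT_WORKBOOK_MAPPING = {
    "participant": "participant",
    "resolution": "resolution",
    "caricature": "caricature",
    "rating": "rating",
    "sex": "sex",
    "caricature_labels": {"V": "V", "C-68p": "C-68p", "C-147p": "C-147p"},
}


def analyze_ratings(ratings: pd.DataFrame) -> dict:
    """Full analysis of one experiment's rating table.

    Returns condition means, C68-vs-V and C147-vs-V paired t's per
    resolution, the two-way interaction, within-subject error bars, and
    relative effectiveness per plot and overall.
    """
    cm = condition_means(ratings, collapse_sex=True)
    report: dict = {"condition_means": cm}
    t_tests: dict[str, StatResult] = {}
    sems: dict[str, float] = {}
    for res in cm["resolution"].unique():
        wide = _wide(cm, res)
        t_tests[f"C-68p vs V @ {res}"] = paired_t(
            wide["C-68p"], wide["V"], name=f"C-68p vs V @ {res}"
        )
        t_tests[f"C-147p vs V @ {res}"] = paired_t(
            wide["C-147p"], wide["V"], name=f"C-147p vs V @ {res}"
        )
        t_tests[f"C-147p vs C-68p @ {res}"] = paired_t(
            wide["C-147p"], wide["C-68p"], name=f"C-147p vs C-68p @ {res}"
        )
        sems[res] = within_subject_sem(wide.to_numpy())
    report["t_tests"] = t_tests
    report["within_subject_sem"] = sems
    interaction, table = rm_anova_2way(cm)
    report["interaction"] = interaction
    report["anova_table"] = table
    per_plot = re_per_resolution(cm)
    report["re_per_resolution"] = per_plot
    report["re_overall"] = re_overall(per_plot)
    return report


def load_ratings_workbook(
    path: str | Path,
    mapping: Mapping | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read a ratings workbook (XLSX) into the package's long rating format.

    ``mapping`` names the workbook's columns for participant / resolution /
    caricature / rating (and optionally face sex) and translates its
    caricature-level labels; this is the escape hatch for externally
    formatted workbooks.  Raises :class:`WorkbookSchemaError` when required
    columns cannot be found.
    """
    mapping = {**DEFAULT_WORKBOOK_MAPPING, **(mapping or {})}
    df = pd.read_excel(Path(path), sheet_name=sheet)
    required = ["participant", "resolution", "caricature", "rating"]
    missing = [k for k in required if mapping[k] not in df.columns]
    if missing:
        raise WorkbookSchemaError(
            f"workbook {path} lacks columns for {missing} "
            f"(looked for {[mapping[k] for k in missing]}); "
            "pass a mapping describing the actual layout"
        )
    out = pd.DataFrame(
        {
            "participant": df[mapping["participant"]],
            "resolution": df[mapping["resolution"]],
            "caricature": df[mapping["caricature"]].map(
                lambda v: mapping["caricature_labels"].get(v, v)
            ),
            "rating": df[mapping["rating"]].astype(float),
        }
    )
    if mapping.get("sex") in df.columns:
        out["sex"] = df[mapping["sex"]]
    bad = set(out["caricature"]) - set(CARICATURE_LEVELS)
    if bad:
        raise WorkbookSchemaError(
            f"unrecognised caricature labels {sorted(bad)}; extend the mapping"
        )
    return out


def reproduce_published(
    workbook: str | Path, mapping: Mapping | None = None, sheet: int | str = 0
) -> dict:
    """Recompute the headline statistics from a per-trial ratings workbook."""
    ratings = load_ratings_workbook(workbook, mapping=mapping, sheet=sheet)
    return analyze_ratings(ratings)
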