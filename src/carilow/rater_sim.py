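"""Simulated dissimilarity raters with a controllable true effect structure.

A trial's latent dissimilarity d is the mean Euclidean distance between the
two faces' corresponding ground-truth landmarks at the trial's viewpoint.
Caricaturing multiplies d by a per-level gain (g_V = 1 by definition;
g_C68 and g_C147 are the simulation's true effect sizes), and the resolution
condition applies a multiplicative attenuation.  Each rescaling block maps
its latent values affinely onto the interior of the 1-9 scale — emulating
observers who spread their ratings over the whole scale and reset their
criteria when instructed — then Gaussian rater noise is added and the result
is rounded and clipped to the integer scale.

Because each rescaling block contains the same face pairs in every
caricature condition and the block mapping is affine, the relative
effectiveness statistic recovered by the analysis stage equals
(g_C68 - 1) / (g_C147 - 1) up to rounding/clipping distortion and rater
noise, which is what makes parameter recovery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .experiment_design import TrialSchedule
from .landmark_io import LandmarkSet, require_compatible
from .synthetic_faces import Cohort

RATING_COLUMNS = [
    "participant", "trial", "block", "sex", "idA", "idB",
    "resolution", "caricature", "rating",
]

#: scale-use calibration: each rescaling block's mean rating sits at the scale
#: midpoint and its extreme pairs spread +-SCALE_SPAN/2 around it
SCALE_CENTER = 5.0
SCALE_SPAN = 4.5

#: default caricature gains; g_C147 = 1.6 matches the landmark geometry of a
#: 60% caricature (distances from the average scale by 1.6), and g_C68 is set
#: so the true relative effectiveness (g_C68-1)/(g_C147-1) is 52%
DEFAULT_GAINS = {"V": 1.0, "C-68p": 1.312, "C-147p": 1.6}


def gains_for_effectiveness(ratio: float, g_c147: float = 1.6) -> dict[str, float]:
    """Gain triple whose true relative effectiveness is ``ratio`` (0-1)."""
    return {"V": 1.0, "C-68p": 1.0 + ratio * (g_c147 - 1.0), "C-147p": g_c147}


@dataclass(frozen=True)
class RaterModel:
    """Latent-to-rating model shared by all simulated participants."""

    gains: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))
    attenuation: Mapping[str, float] = field(default_factory=dict)  # per resolution
    sigma: float = 1.0  # rater noise s.d., rating-scale units
    rescale_per_block: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("rater noise s.d. must be non-negative")

    def gain(self, caricature: str) -> float:
        try:
            return float(self.gains[caricature])
        except KeyError:
            raise KeyError(f"no gain configured for caricature level {caricature!r}")

    def atten(self, resolution: str) -> float:
        return float(self.attenuation.get(resolution, 1.0))


def latent_dissimilarity(a: LandmarkSet, b: LandmarkSet) -> float:
    """Mean Euclidean distance between corresponding landmarks."""
    require_compatible(a, b)
    return float(np.mean(np.linalg.norm(a.points - b.points, axis=1)))


def cohort_dissimilarities(
    cohort: Cohort, annotation: str = "hand"
) -> dict[tuple[str, str, str], float]:
    """(idA, idB, viewpoint) -> latent dissimilarity, symmetric in A/B."""
    by_sex: dict[str, list[str]] = {}
    for p in cohort.identities:
        by_sex.setdefault(p.sex, []).append(p.id)
    vps = sorted({vp for (_, vp, _) in cohort.landmarks})
    out: dict[tuple[str, str, str], float] = {}
    for ids in by_sex.values():
        for i, ida in enumerate(ids):
            for idb in ids[i + 1 :]:
                for vp in vps:
                    d = latent_dissimilarity(
                        cohort.landmarks[(ida, vp, annotation)],
                        cohort.landmarks[(idb, vp, annotation)],
                    )
                    out[(ida, idb, vp)] = d
                    out[(idb, ida, vp)] = d
    return out


def _latents_and_groups(
    trials: pd.DataFrame, model: RaterModel, dissim: Mapping[tuple[str, str, str], float]
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless latent value per trial plus rescaling-group index."""
    d = np.array(
        [dissim[(r.idA, r.idB, r.viewA)] for r in trials.itertuples()], dtype=float
    )
    g = np.array([model.gain(c) for c in trials["caricature"]])
    a = np.array([model.atten(r) for r in trials["resolution"]])
    latent = g * a * d
    if model.rescale_per_block:
        groups = np.cumsum(trials["rescale_marker"].to_numpy().astype(int)) - 1
        groups = np.maximum(groups, 0)
    else:
        groups = np.zeros(len(trials), dtype=int)
    return latent, groups


def simulate_rating_values(
    trials: pd.DataFrame,
    model: RaterModel,
    dissim: Mapping[tuple[str, str, str], float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer 1-9 ratings for one participant's trial table."""
    latent, groups = _latents_and_groups(trials, model, dissim)
    scaled = np.empty_like(latent)
    for gidx in np.unique(groups):
        sel = groups == gidx
        lo, hi = latent[sel].min(), latent[sel].max()
        if hi - lo < 1e-12:
            scaled[sel] = SCALE_CENTER
        else:
            # centre the block's mean at the scale midpoint and spread the
            # extreme pairs over +-SCALE_SPAN/2; with rater noise on top this
            # keeps condition means in the 4-6 band while trial-level ratings
            # reach the scale ends
            mid = latent[sel].mean()
            scaled[sel] = SCALE_CENTER + SCALE_SPAN * (latent[sel] - mid) / (hi - lo)
    noisy = scaled + rng.normal(0.0, model.sigma, size=len(scaled))
    return np.clip(np.round(noisy), 1, 9).astype(int)


def cell_masks(trials: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Boolean trial masks for each (resolution, caricature) cell.

    Returns (masks[res, car, trial], resolution labels, caricature labels);
    resolutions keep presentation order, caricature levels keep V, C-68p,
    C-147p order.
    """
    res_labels = list(dict.fromkeys(trials["resolution"]))
    car_labels = [c for c in ("V", "C-68p", "C-147p") if c in set(trials["caricature"])]
    res = trials["resolution"].to_numpy()
    car = trials["caricature"].to_numpy()
    masks = np.stack(
        [[(res == r) & (car == c) for c in car_labels] for r in res_labels]
    )
    return masks, res_labels, car_labels


def simulate_condition_grid(
    trials: pd.DataFrame,
    model: RaterModel,
    dissim: Mapping[tuple[str, str, str], float],
    n_participants: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo fast path: per-participant condition-mean grid.

    Returns an (n_participants, n_resolutions, n_caricature_levels) array of
    cell means, skipping the long-format rating table; used for replicate
    studies of the relative-effectiveness estimator.
    """
    masks, res_labels, car_labels = cell_masks(trials)
    out = np.empty((n_participants, len(res_labels), len(car_labels)))
    for p in range(n_participants):
        vals = simulate_rating_values(trials, model, dissim, rng)
        for i in range(len(res_labels)):
            for j in range(len(car_labels)):
                out[p, i, j] = vals[masks[i, j]].mean()
    return out


def simulate_ratings(
    schedules: TrialSchedule | Sequence[TrialSchedule],
    model: RaterModel,
    dissim: Mapping[tuple[str, str, str], float],
    n_participants: int | None = None,
) -> pd.DataFrame:
    """Rating table over participants (columns: ``RATING_COLUMNS``).

    Pass either one schedule per participant, or a single schedule plus
    ``n_participants`` (everyone then shares the trial order but draws
    independent noise).
    """
    if isinstance(schedules, TrialSchedule):
        n = n_participants if n_participants is not None else 20
        sched_list = [(p, schedules.trials) for p in range(n)]
    else:
        sched_list = [(s.participant, s.trials) for s in schedules]
    root = np.random.default_rng(model.seed)
    child = root.spawn(len(sched_list))
    frames = []
    for (pid, trials), rng in zip(sched_list, child):
        ratings = simulate_rating_values(trials, model, dissim, rng)
        df = trials[
            ["trial", "block", "sex", "idA", "idB", "resolution", "caricature"]
        ].copy()
        df.insert(0, "participant", pid)
        df["rating"] = ratings
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[RATING_COLUMNS]
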