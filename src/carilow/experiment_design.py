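"""Trial schedules for the two rating experiments.

Each trial presents a same-sex pair of faces at one (resolution, caricature)
condition.  Because rating all 13 same-sex faces against each other would
take too many trials, each sex is split into subsets of 7 and 6 and pairs
are enumerated within subsets only: C(7,2) + C(6,2) = 21 + 15 = 36 pairs per
sex, 72 pairs over both sexes, times 9 conditions (3 resolutions x 3
caricature levels) = 648 trials per participant.

Experiment 1 (blur) blocks trials by face sex, with block order
counterbalanced across participants, and intermixes all 9 conditions within
a sex block.  Experiment 2 (phosphenes) additionally blocks by resolution in
the fixed order 40x40ND, 40x40DO, 32x32DO for every participant, and emits a
rescaling marker at each new resolution block (observers were told to reset
their use of the 1-9 scale there, so between-resolution mean comparisons are
not valid in that experiment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .landmark_io import VIEWPOINTS

E1_RESOLUTIONS = ("highres", "Blur20", "Blur30")
E2_RESOLUTIONS = ("40x40ND", "40x40DO", "32x32DO")  # fixed presentation order
CARICATURE_LEVELS = ("V", "C-68p", "C-147p")

SCHEDULE_COLUMNS = [
    "participant", "block", "trial", "sex", "idA", "idB",
    "resolution", "caricature", "viewA", "viewB", "left_is_A", "rescale_marker",
]


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trials for one participant, as a dataframe with fixed columns."""

    experiment: str  # "E1" or "E2"
    participant: int
    seed: int
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SCHEDULE_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"schedule missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.trials)

    def counts_per_condition(self) -> pd.Series:
        return self.trials.groupby(["resolution", "caricature"]).size()


def split_subsets(ids: Sequence[str], seed: int = 0) -> tuple[list[str], list[str]]:
    """Split one sex's identities into rating subsets of 7 and 6."""
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_big = (len(ids) + 1) // 2
    return shuffled[:n_big], shuffled[n_big:]


def pairs_within(subset: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs within a subset (each face rated against the rest)."""
    return list(itertools.combinations(subset, 2))


def build_schedule(
    experiment: str,
    male_ids: Sequence[str],
    female_ids: Sequence[str],
    seed: int = 0,
    participant: int = 0,
    resolutions: Sequence[str] | None = None,
    caricatures: Sequence[str] = CARICATURE_LEVELS,
    viewpoints: Sequence[str] = VIEWPOINTS,
) -> TrialSchedule:
    """One participant's full trial schedule.

    The subset split is derived from ``seed`` alone (shared by all
    participants), while trial order, viewpoint assignment and left/right
    placement are drawn from (seed, participant).  Sex-block order is
    counterbalanced by participant parity.
    """
    if experiment not in ("E1", "E2"):
        raise ValueError(f"experiment must be 'E1' or 'E2', got {experiment!r}")
    if resolutions is None:
        resolutions = E1_RESOLUTIONS if experiment == "E1" else E2_RESOLUTIONS
    if len(resolutions) != 3 or len(caricatures) != 3:
        raise ValueError(
            f"condition grid must be 3 resolutions x 3 caricature levels, "
            f"got {len(resolutions)}x{len(caricatures)}"
        )

    pairs_by_sex = {}
    for sex, ids in (("M", male_ids), ("F", female_ids)):
        big, small = split_subsets(ids, seed=seed * 2 + (0 if sex == "M" else 1))
        pairs_by_sex[sex] = pairs_within(big) + pairs_within(small)

    rng = np.random.default_rng((seed, participant, 0xC0FFEE))
    sexes = ("M", "F") if participant % 2 == 0 else ("F", "M")

    rows: list[dict] = []
    trial_no = 0

    def emit(block_label, sex, pair, res, car, rescale):
        nonlocal trial_no
        vp = viewpoints[rng.integers(len(viewpoints))]
        rows.append(
            {
                "participant": participant,
                "block": block_label,
                "trial": trial_no,
                "sex": sex,
                "idA": pair[0],
                "idB": pair[1],
                "resolution": res,
                "caricature": car,
                "viewA": vp,
                "viewB": vp,
                "left_is_A": bool(rng.integers(2)),
                "rescale_marker": rescale,
            }
        )
        trial_no += 1

    if experiment == "E1":
        for sex in sexes:
            block = f"sex-{sex}"
            cells = [
                (pair, res, car)
                for res in resolutions
                for car in caricatures
                for pair in pairs_by_sex[sex]
            ]
            order = rng.permutation(len(cells))
            for i in order:
                pair, res, car = cells[i]
                # no rescaling between sex blocks: one scale for the session
                emit(block, sex, pair, res, car, trial_no == 0)
    else:
        for res in resolutions:  # fixed order, every participant
            first_in_res = True
            for sex in sexes:
                block = f"{res}/sex-{sex}"
                cells = [
                    (pair, car) for car in caricatures for pair in pairs_by_sex[sex]
                ]
                order = rng.permutation(len(cells))
                for i in order:
                    pair, car = cells[i]
                    emit(block, sex, pair, res, car, first_in_res)
                    first_in_res = False

    trials = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    return TrialSchedule(experiment, participant, seed, trials)


def build_all_schedules(
    experiment: str,
    male_ids: Sequence[str],
    female_ids: Sequence[str],
    n_participants: int = 20,
    seed: int = 0,
    **kwargs,
) -> list[TrialSchedule]:
    return [
        build_schedule(experiment, male_ids, female_ids, seed=seed, participant=p, **kwargs)
        for p in range(n_participants)
    ]


def save_schedule(schedule: TrialSchedule, path) -> None:
    schedule.trials.to_csv(path, index=False)
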