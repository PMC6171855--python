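# carilow

Face caricaturing for low vision, end to end: landmark-based shape
caricatures at defined strength, simulated low-vision viewing (peripheral
blur and prosthetic-vision phosphenisation), dissimilarity-rating experiment
design, and the repeated-measures analysis including the
relative-effectiveness statistic.

## The problem

Caricaturing — exaggerating how a face differs from an average face —
makes identities easier to tell apart, and has been proposed as an image
enhancement for people with severe vision loss (macular degeneration,
retinal prostheses).  Deploying it requires automatic landmarking, but
automatic detectors place only 68 points and skip whole regions (forehead,
ears, brow width, mid-nose width) that detailed 147-point hand annotation
covers.  The question this pipeline operationalises: how much of the
caricature benefit survives the drop from 147 to 68 landmarks, across
degraded viewing conditions?

The core model: with veridical landmark vector **v** and category-matched
average **a**, a caricature at strength *s* places each point at

    p′ = v + s·(v − a)

(*s* = 0.6 in the study regime; *s* = 1 doubles distances from the
average), and the image is warped from **v** to **p′** — shape only, no
texture blending.  Rated dissimilarity between face pairs feeds
repeated-measures contrasts, and the headline statistic is

    Relative Effectiveness = 100 · (C̄68 − V̄) / (C̄147 − V̄),

the 68-point caricature's mean rating gain over veridical as a percentage
of the 147-point caricature's gain.

Everything runs on synthetic data: a parametric face generator with
ground-truth landmarks in both schemes (26 identities × 4 viewpoints, plus
pool-based sex × viewpoint averages) and a simulated-rater model with a
controllable true effect structure, so the analysis stage supports
parameter recovery.  No external face data are required.

## Worked example

```python
import numpy as np
from carilow import (make_cohort, build_caricature_inventory,
                     simulate_ratings, analyze_ratings)
from carilow.experiment_design import build_schedule
from carilow.rater_sim import (RaterModel, cohort_dissimilarities,
                               gains_for_effectiveness)

cohort = make_cohort(seed=1)                      # 26 ids x 4 viewpoints
inv = build_caricature_inventory(cohort, strength=0.6)
print(len(inv.stimuli))                           # 312 (104 V, 104 C-68p, 104 C-147p)

sched = build_schedule("E2", cohort.ids_by_sex("M"), cohort.ids_by_sex("F"), seed=1)
print(len(sched))                                 # 648 trials, 72 per condition

model = RaterModel(gains=gains_for_effectiveness(0.52), seed=1)
ratings = simulate_ratings(sched, model, cohort_dissimilarities(cohort),
                           n_participants=20)
report = analyze_ratings(ratings)
print(report["interaction"])     # resolution x caricature interaction: F(4, 76) = ...
print(round(report["re_overall"], 1))             # ~52 : the recovered RE (%)
```

The rater model above is built with a true effectiveness ratio of 0.52;
`analyze_ratings` recovers it from the simulated 1–9 ratings.  A full
narrative run lives in `analysis/` (numbered scripts: build stimuli, render
low-vision formats, build schedules, simulate ratings, analyse).  On the
default seeds the analysis stage prints a recovered relative effectiveness
of 50.7% for the blur experiment, 53.0% for the phosphene experiment, and
51.8% across all six resolution plots, with every caricature-vs-veridical
paired contrast significant at p < .001.

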