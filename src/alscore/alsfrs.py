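"""ALSFRS-R function names and groupings.

The revised ALS Functional Rating Scale (ALSFRS-R) asks participants to rate
12 functional abilities on an integer scale from 0 ("can't do") to 4 ("normal
ability").  Individual scores sum to a global score between 0 (worst) and 48
(best).  The 12 functions fall into clinically coherent groups whose scores
are strongly correlated in longitudinal cohorts: the bulbar trio, the
fine-motor items, the lower-limb pair and the respiratory trio.
"""

from __future__ import annotations

#: The 12 ALSFRS-R functions, in the conventional questionnaire order.
FUNCTIONS: tuple[str, ...] = (
    "speech",
    "salivation",
    "swallowing",
    "handwriting",
    "cutting_food",
    "dressing_hygiene",
    "turning_in_bed",
    "walking",
    "climbing_stairs",
    "dyspnea",
    "orthopnea",
    "respiratory_insufficiency",
)

#: Clinically coherent groups with correlated severity trajectories.
GROUPS: dict[str, tuple[str, ...]] = {
    "bulbar": ("speech", "salivation", "swallowing"),
    "fine_motor": ("handwriting", "cutting_food", "dressing_hygiene", "turning_in_bed"),
    "lower_limb": ("walking", "climbing_stairs"),
    "respiratory": ("dyspnea", "orthopnea", "respiratory_insufficiency"),
}

#: The six limb-related functions (fine-motor items plus the lower-limb pair).
LIMB_FUNCTIONS: tuple[str, ...] = GROUPS["fine_motor"] + GROUPS["lower_limb"]

#: The nine functions targeted by the multi-label accelerometer models:
#: six limb-related plus the three respiratory functions.
ACCEL_FUNCTIONS: tuple[str, ...] = LIMB_FUNCTIONS + GROUPS["respiratory"]

#: Score classes of every ALSFRS-R item.
SCORE_CLASSES: tuple[int, ...] = (0, 1, 2, 3, 4)

N_CLASSES: int = len(SCORE_CLASSES)

#: Accelerometer limb placements: left/right ankle and left/right wrist.
LIMBS: tuple[str, ...] = ("LA", "LW", "RA", "RW")
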