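"""Rule-based assignment of capsule PK profiles to gastric-motility groups.

Groups are defined on the observed-grid Tmax and, for the intermediate
Tmax window, the ratio of the 0.5 h concentration to Cmax:

* group 1: Tmax <= 0.5 h (very early housekeeper wave)
* groups 2/3/4: 0.5 < Tmax <= 1.0 h with C(0.5h)/Cmax in [0.6, 0.95] /
  [0.3, 0.6) / [0, 0.3) (strong / weak / negligible early intragastric
  stress)
* group 5: 1.0 < Tmax <= 1.5 h; group 6: Tmax > 1.5 h (late wave)

Tmax bins are left-open/right-closed.  A ratio above 0.95 with Tmax in
(0.5, 1.0] is outside the published ranges and is flagged, not guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pkcore import PlasmaProfile, nca

__all__ = ["MotilityAssignment", "classify_profile", "classify_trial"]


@dataclass(frozen=True)
class MotilityAssignment:
    subject: str
    group: int | None  # None when flagged unclassifiable
    t_max: float
    ratio: float | None  # C(0.5h)/Cmax, intermediate Tmax window only
    flag: str = ""


def classify_profile(t_max: float, c_half_hour: float, c_max: float) -> int | None:
    """Assign a motility group from Tmax and the 0.5 h/Cmax ratio.

    Returns the group 1-6, or None for the undefined region
    (ratio > 0.95 with Tmax in (0.5, 1.0]).
    """
    if c_max <= 0:
        raise ValueError("c_max must be > 0")
    if t_max <= 0.5:
        return 1
    if t_max <= 1.0:
        ratio = c_half_hour / c_max
        if ratio > 0.95:
            return None
        if ratio >= 0.6:
            return 2
        if ratio >= 0.3:
            return 3
        return 4
    if t_max <= 1.5:
        return 5
    return 6


def classify_trial(
    profiles: Sequence[PlasmaProfile],
    subjects: Sequence[str] | None = None,
) -> tuple[list[MotilityAssignment], pd.Series]:
    """Classify each profile via NCA and tabulate group prevalences.

    Prevalences are fractions of classified subjects (flagged subjects are
    excluded from the denominator) and sum to 1.
    """
    assignments: list[MotilityAssignment] = []
    for i, prof in enumerate(profiles):
        sid = subjects[i] if subjects is not None else f"S{i + 1:04d}"
        res = nca(prof)
        if res.c_max <= 0:
            assignments.append(
                MotilityAssignment(sid, None, res.t_max, None, flag="no quantifiable concentrations")
            )
            continue
        if not (prof.times.min() <= 0.5 <= prof.times.max()):
            assignments.append(
                MotilityAssignment(sid, None, res.t_max, None, flag="0.5 h point not covered")
            )
            continue
        group = classify_profile(res.t_max, res.c_half_hour, res.c_max)
        ratio = res.c_half_hour / res.c_max if 0.5 < res.t_max <= 1.0 else None
        flag = "" if group is not None else "ratio above 0.95 in intermediate Tmax window"
        assignments.append(MotilityAssignment(sid, group, res.t_max, ratio, flag))

    groups = [a.group for a in assignments if a.group is not None]
    counts = pd.Series(groups, dtype=int).value_counts().reindex(range(1, 7), fill_value=0)
    prevalence = counts / max(len(groups), 1)
    prevalence.index.name = "group"
    return assignments, prevalence
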