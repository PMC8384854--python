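"""Septal spacing, ontogenetic stages, one-way ANOVA, Tukey-Kramer pairs.

Septal spacing is the rotational angle about the coiling axis between
successive septa.  Chambers are numbered from 2 (the earliest chamber is
excluded from analysis), and the spacing series element j belongs to chamber
j + 2.  Ontogenetic stages follow conch diameter: pre-hatching below 30 mm,
mature for the last two chambers, juvenile-submature in between.  Hatching
leaves a detectable signature: the spacing rises through the embryonic
chambers and then drops steeply (>= 20% relative to the running maximum)
at the hatching chamber.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StageAssignment",
    "AnovaResult",
    "PairwiseComparison",
    "septal_angles",
    "assign_stage",
    "select_stage_points",
    "anova_oneway",
    "pairwise_comparisons",
    "hatching_chamber",
]

log = logging.getLogger(__name__)

PRE_HATCHING = "pre_hatching"
JUVENILE = "juvenile_submature"
MATURE = "mature"

#: conch diameter below which a chamber is pre-hatching (mm); the rule is
#: "< 30" / ">= 30", so exactly 30 mm is juvenile-submature
PRE_HATCHING_MAX_DIAMETER = 30.0


@dataclass
class StageAssignment:
    """Stage per chamber (aligned with `chambers`), plus the rule version."""

    chambers: np.ndarray  # chamber numbers, starting at 2
    stages: list[str]
    rule_version: str = "diameter30-lasttwo-v1"

    def counts(self) -> dict[str, int]:
        out = {PRE_HATCHING: 0, JUVENILE: 0, MATURE: 0}
        for s in self.stages:
            out[s] += 1
        return out


def septal_angles(record) -> np.ndarray:
    """Successive differences of cumulative septal rotational positions.

    `record` is a SpecimenRecord (or anything with `septal_positions` in
    degrees, cumulative, starting at the rotational origin).  The series has
    length chambers - 1 and must be strictly increasing.
    """
    pos = np.asarray(record.septal_positions, float)
    if pos.ndim != 1 or pos.size < 2:
        raise ValueError("need at least two septal positions")
    diffs = np.diff(pos)
    if np.any(diffs <= 0.0) or not np.all(np.isfinite(diffs)):
        raise ValueError("septal rotational positions must increase strictly")
    return diffs


def assign_stage(record, pre_hatching_max_diameter: float = PRE_HATCHING_MAX_DIAMETER) -> StageAssignment:
    """Assign each chamber its ontogenetic stage.

    Mature = last two chambers (regardless of diameter); pre-hatching =
    conch diameter < 30 mm among the rest; juvenile-submature otherwise
    (diameter >= 30 mm up to the third chamber from the last).
    """
    diam = np.asarray(record.diameters_at_chamber, float)
    chambers = np.asarray(record.chamber_numbers, int)
    if diam.size != chambers.size:
        raise ValueError("diameters and chamber numbers must align")
    if diam.size < 4:
        raise ValueError("stages are undefined for fewer than 4 chambers")
    stages = []
    for i, d in enumerate(diam):
        if i >= diam.size - 2:
            stages.append(MATURE)
        elif d < pre_hatching_max_diameter:
            stages.append(PRE_HATCHING)
        else:
            stages.append(JUVENILE)
    return StageAssignment(chambers=chambers, stages=stages)


def select_stage_points(diameters, target) -> tuple[int, int]:
    """Indices of the two entries closest to a target conch diameter.

    `target` may be a diameter in mm or "max"/None, which selects the last
    two entries (maturity: the last two chambers / cross-sections).  Ties in
    |diameter - target| are broken toward the smaller diameter; the returned
    pair is ordered by position in the series.
    """
    d = np.asarray(diameters, float)
    if d.size < 2:
        raise ValueError("need at least two diameters")
    if target is None or (isinstance(target, str) and target.lower() in ("max", "maturity")):
        return int(d.size - 2), int(d.size - 1)
    t = float(target)
    order = sorted(range(d.size), key=lambda i: (abs(d[i] - t), d[i]))
    pair = sorted(order[:2])
    return int(pair[0]), int(pair[1])


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_ns: dict[str, int]


def anova_oneway(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Between/within sums of squares and the upper-tail F probability.  If all
    values are identical across all groups, F is defined as 0 and p as 1.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], float).ravel() for g in names]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([s.size for s in samples])
    if np.any(ns < 1) or not np.any(ns >= 2):
        raise ValueError("each group needs >= 1 value and at least one group >= 2")
    allv = np.concatenate(samples)
    grand = allv.mean()
    means = np.array([s.mean() for s in samples])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((s - m) ** 2) for s, m in zip(samples, means)))
    df_b = len(samples) - 1
    df_w = int(ns.sum()) - len(samples)
    if ss_between + ss_within == 0.0:
        F, p = 0.0, 1.0
    elif ss_within == 0.0:
        F, p = np.inf, 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means={g: float(m) for g, m in zip(names, means)},
        group_ns={g: int(n) for g, n in zip(names, ns)},
    )


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    adjusted_interval: tuple[float, float]
    adjusted_p: float
    significant: bool


def pairwise_comparisons(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[PairwiseComparison]:
    """Tukey-Kramer honestly-significant-difference tests on all group pairs.

    Uses the studentized-range distribution with the Tukey-Kramer
    unbalanced-n standard error.  Groups with a single observation are
    excluded with a logged warning (no within-group variance).  With the same
    critical quantile building both p-values and intervals, significance at
    alpha, p < alpha, and the interval excluding 0 coincide.
    """
    usable = {}
    for g, v in groups.items():
        v = np.asarray(v, float).ravel()
        if v.size < 2:
            log.warning("group %r has n=%d < 2: excluded from pairwise tests", g, v.size)
            continue
        usable[g] = v
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with n >= 2 for pairwise tests")
    names = list(usable)
    k = len(names)
    ns = {g: usable[g].size for g in names}
    means = {g: float(usable[g].mean()) for g in names}
    df_w = sum(ns.values()) - k
    ms_within = sum(float(np.sum((usable[g] - means[g]) ** 2)) for g in names) / df_w
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_w))
    out = []
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            a, b = names[a_i], names[b_i]
            diff = means[a] - means[b]
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
                half = 0.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
                half = q_crit * se
            out.append(
                PairwiseComparison(
                    group_a=a,
                    group_b=b,
                    mean_difference=diff,
                    adjusted_interval=(diff - half, diff + half),
                    adjusted_p=min(max(p, 0.0), 1.0),
                    significant=bool(p < alpha),
                )
            )
    return out


def hatching_chamber(angles, drop_fraction: float = 0.2, search_limit_chamber: int = 12):
    """Chamber at which septal spacing first drops steeply after its rise.

    Scans the spacing series (element j = chamber j + 2) for the first angle
    that is at least `drop_fraction` below the running maximum of the
    preceding angles, within the first `search_limit_chamber` chambers.
    Returns the chamber number of the drop, or None when no qualifying drop
    exists (e.g. a monotone series): "not detected".
    """
    a = np.asarray(angles, float)
    if a.size < 10:
        raise ValueError("need at least 10 spacing angles")
    run_max = a[0]
    last_j = min(a.size - 1, search_limit_chamber - 2)
    for j in range(1, last_j + 1):
        if a[j] <= (1.0 - drop_fraction) * run_max:
            return j + 2
        run_max = max(run_max, a[j])
    return None
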