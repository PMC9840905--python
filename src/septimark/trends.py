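"""Three-point time-course trend profiles and trend-differential calls.

Each protein's path over (healthy control, burn day 1, burn day 3) is reduced
to a pair of step signs — did the group mean rise, fall, or stay flat from C
to day 1, and from day 1 to day 3?  The eight non-flat sign pairs are numbered
0-7 (a short-time-series profile in the STEM tradition); the all-flat pair has
no profile.  A configurable class map partitions the eight ids into "up" and
"down" trends, and a protein whose NS-path and S-path classes are opposite, or
that trends on exactly one path, is a trend-differential protein — the
candidate pool for sepsis-specific early-warning markers.

Two orientations of the id -> up/down key are in circulation for this family
of profile numberings and they disagree; both are provided here
(:data:`RESULTS_TEXT_MAP`, the default, reads ids 0,1,3,5 as down;
:data:`FIGURE_CAPTION_MAP` reads them as up).  The differential call is
invariant under swapping the two (a class-symmetric rule), so downstream
results do not depend on the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .matrix import AbundanceMatrix

Sign = int  # -1, 0, +1

#: Lexicographic enumeration of the eight non-flat sign pairs, -1 < 0 < +1.
#: ``_PROFILE_SIGNS[profile_id] == (s1, s2)``; (0, 0) has no profile.
_PROFILE_SIGNS: tuple[tuple[Sign, Sign], ...] = (
    (-1, -1),  # 0
    (-1, 0),   # 1
    (-1, +1),  # 2
    (0, -1),   # 3
    (0, +1),   # 4
    (+1, -1),  # 5
    (+1, 0),   # 6
    (+1, +1),  # 7
)
_PROFILE_BY_SIGNS = {signs: i for i, signs in enumerate(_PROFILE_SIGNS)}

TREND_CLASSES = ("up", "down", "none")


@dataclass(frozen=True)
class ProfileClassMap:
    """Partition of profile ids 0-7 into up-trend and down-trend classes."""

    up_ids: frozenset[int]
    down_ids: frozenset[int]

    def __post_init__(self):
        up, down = frozenset(self.up_ids), frozenset(self.down_ids)
        object.__setattr__(self, "up_ids", up)
        object.__setattr__(self, "down_ids", down)
        if up & down:
            raise ConfigError(f"class map up/down ids overlap: {sorted(up & down)}")
        if up | down != frozenset(range(8)):
            raise ConfigError("class map must cover profile ids 0..7 exactly")

    def inverted(self) -> "ProfileClassMap":
        return ProfileClassMap(up_ids=self.down_ids, down_ids=self.up_ids)


#: Default: ids 0, 1, 3, 5 are down-trends, 2, 4, 6, 7 up-trends.
RESULTS_TEXT_MAP = ProfileClassMap(up_ids=frozenset({2, 4, 6, 7}),
                                   down_ids=frozenset({0, 1, 3, 5}))
#: The opposite orientation of the same key.
FIGURE_CAPTION_MAP = RESULTS_TEXT_MAP.inverted()

CLASS_MAPS = {"results-text": RESULTS_TEXT_MAP, "figure-caption": FIGURE_CAPTION_MAP}


def step_sign(mean_from: float, mean_to: float, step_fc_threshold: float = 1.5) -> Sign:
    """Sign of a step between two log2 group means.

    Returns +1 when the rise exceeds log2(threshold), -1 when the fall does,
    and 0 otherwise (strict inequalities: a step of exactly the threshold is
    flat).  The threshold is a fold ratio and must exceed 1.
    """
    if not step_fc_threshold > 1:
        raise ConfigError(f"step_fc_threshold must exceed 1, got {step_fc_threshold}")
    if not (np.isfinite(mean_from) and np.isfinite(mean_to)):
        raise ValidationError("step_sign requires finite log2 means")
    delta = mean_to - mean_from
    cut = np.log2(step_fc_threshold)
    if delta > cut:
        return 1
    if delta < -cut:
        return -1
    return 0


def assign_profile(signs: tuple[Sign, Sign]) -> int | None:
    """Map a step-sign pair to its profile id (None for the flat pair)."""
    s1, s2 = signs
    for s in (s1, s2):
        if s not in (-1, 0, 1):
            raise ValidationError(f"invalid step sign {s!r}; expected -1, 0, or +1")
    if (s1, s2) == (0, 0):
        return None
    return _PROFILE_BY_SIGNS[(s1, s2)]


def signs_for_profile(profile_id: int) -> tuple[Sign, Sign]:
    """Inverse of :func:`assign_profile` on the eight non-flat profiles."""
    if profile_id not in range(8):
        raise ValidationError(f"profile id must be 0..7, got {profile_id!r}")
    return _PROFILE_SIGNS[profile_id]


def classify_trend(profile_id: int | None, class_map: ProfileClassMap = RESULTS_TEXT_MAP) -> str:
    """Trend class ("up"/"down"/"none") of a profile id under a class map."""
    if profile_id is None:
        return "none"
    if profile_id not in range(8):
        raise ValidationError(f"profile id must be 0..7 or None, got {profile_id!r}")
    return "up" if profile_id in class_map.up_ids else "down"


@dataclass(frozen=True)
class TrendDiffCall:
    """Outcome of comparing the NS-path and S-path trend classes."""

    call_ns: str
    call_s: str
    is_differential: bool
    reason: str  # "opposite" | "one-sided-trend" | "none"


def trend_differential(call_ns: str, call_s: str) -> TrendDiffCall:
    """Differential rule: opposite classes, or a trend on exactly one path."""
    for c in (call_ns, call_s):
        if c not in TREND_CLASSES:
            raise ValidationError(f"invalid trend class {c!r}; expected {TREND_CLASSES}")
    if {call_ns, call_s} == {"up", "down"}:
        reason = "opposite"
    elif (call_ns == "none") != (call_s == "none"):
        reason = "one-sided-trend"
    else:
        reason = "none"
    return TrendDiffCall(call_ns, call_s, reason != "none", reason)


def trend_analysis(
    mean_c: pd.Series,
    mean_ns_d1: pd.Series,
    mean_ns_d3: pd.Series,
    mean_s_d1: pd.Series,
    mean_s_d3: pd.Series,
    step_fc_threshold: float = 1.5,
    class_map: ProfileClassMap = RESULTS_TEXT_MAP,
) -> pd.DataFrame:
    """Per-feature trend calls from log2 group means.

    The healthy-control mean anchors both paths (C -> NS day1 -> NS day3 and
    C -> S day1 -> S day3).  Returns one row per feature with step signs,
    profile ids (pandas NA for flat), classes, and the differential call.
    """
    series = {"mean_ns_d1": mean_ns_d1, "mean_ns_d3": mean_ns_d3,
              "mean_s_d1": mean_s_d1, "mean_s_d3": mean_s_d3}
    for name, s in series.items():
        if not s.index.equals(mean_c.index):
            raise ValidationError(f"{name} is not aligned with the control means")
    rows = []
    for feat in mean_c.index:
        paths = {}
        for path, (d1, d3) in (("ns", (mean_ns_d1, mean_ns_d3)),
                               ("s", (mean_s_d1, mean_s_d3))):
            s1 = step_sign(mean_c[feat], d1[feat], step_fc_threshold)
            s2 = step_sign(d1[feat], d3[feat], step_fc_threshold)
            pid = assign_profile((s1, s2))
            paths[path] = (s1, s2, pid, classify_trend(pid, class_map))
        call = trend_differential(paths["ns"][3], paths["s"][3])
        rows.append({
            "feature": feat,
            "s1_ns": paths["ns"][0], "s2_ns": paths["ns"][1],
            "profile_ns": paths["ns"][2], "class_ns": paths["ns"][3],
            "s1_s": paths["s"][0], "s2_s": paths["s"][1],
            "profile_s": paths["s"][2], "class_s": paths["s"][3],
            "is_differential": call.is_differential,
            "reason": call.reason,
        })
    out = pd.DataFrame(rows)
    out["profile_ns"] = out["profile_ns"].astype("Int64")
    out["profile_s"] = out["profile_s"].astype("Int64")
    return out


def group_day_mean(m: AbundanceMatrix, samples: pd.DataFrame, group: str, day: int,
                   min_observed: int = 2) -> pd.Series:
    """Per-feature mean log2 intensity over one group at one day.

    On an ``imputed`` matrix this is a plain mean.  On a ``log2`` matrix
    (missing cells preserved) the mean is taken over observed values only —
    the right summary for step comparisons under intensity-dependent
    missingness, where constant-minimum imputation would shift small-group
    means by several log2 units — and features with fewer than
    ``min_observed`` observations in the cell are returned as NaN.
    """
    if m.state not in ("imputed", "log2"):
        raise ValidationError(f"trend means require an imputed or log2 matrix, state is {m.state!r}")
    ids = samples.loc[(samples["group"] == group) & (samples["day"] == int(day)), "sample_id"]
    ids = [s for s in ids if s in m.values.columns]
    if not ids:
        raise ValidationError(f"no samples of group {group!r} at day {day} in the matrix")
    block = m.values.loc[:, ids]
    if m.state == "imputed":
        return block.mean(axis=1)
    means = block.mean(axis=1, skipna=True)
    means[block.notna().sum(axis=1) < min_observed] = np.nan
    return means


def trend_analysis_matrix(
    m: AbundanceMatrix,
    samples: pd.DataFrame,
    step_fc_threshold: float = 1.5,
    class_map: ProfileClassMap = RESULTS_TEXT_MAP,
) -> pd.DataFrame:
    """Trend calls from a pooled matrix holding C day-0, day-1 and day-3 samples.

    With a ``log2`` (non-imputed) matrix, features lacking 2 observed values
    in any of the five group-day cells are dropped from the result.
    """
    means = [
        group_day_mean(m, samples, "C", 0),
        group_day_mean(m, samples, "NS", 1),
        group_day_mean(m, samples, "NS", 3),
        group_day_mean(m, samples, "S", 1),
        group_day_mean(m, samples, "S", 3),
    ]
    defined = ~np.logical_or.reduce([s.isna().to_numpy() for s in means])
    means = [s[defined] for s in means]
    return trend_analysis(*means, step_fc_threshold=step_fc_threshold, class_map=class_map)
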