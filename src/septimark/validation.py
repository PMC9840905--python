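"""Per-day two-group testing and ROC/AUC validation of candidate marker panels.

This mirrors a targeted (PRM-style) verification stage: each candidate
protein is re-measured in an expanded cohort and judged per day by (i) a
two-group test — Student's pooled t or Mann-Whitney U, auto-selected by a
Shapiro-Wilk normality screen — and (ii) the area under the ROC curve with
the sepsis (S) group as the positive class, so AUC > 0.5 means higher
abundance in sepsis.

The ROC curve places one point per distinct score threshold (descending),
plus the (0,0) endpoint; tied scores collapse to a single threshold.  The
AUC is the trapezoidal area and, by construction, equals the fraction of
(positive, negative) score pairs won by the positive, counting ties as half
— the Mann-Whitney U statistic scaled by 1/(n_pos * n_neg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SeptimarkError, ValidationError
from .matrix import AbundanceMatrix, samples_in_group


class GroupTestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str  # "t" or "rank"


def group_test(values_a: Sequence[float], values_b: Sequence[float],
               method: str = "auto") -> GroupTestResult:
    """Two-sided two-group test: pooled t, Mann-Whitney, or auto-selected.

    ``auto`` runs a Shapiro-Wilk screen at 0.05 per group and falls back to
    the rank test when either group fails it (constant groups count as
    failing; groups of fewer than 3 values cannot be screened and default to
    the t test).  The rank test uses the normal approximation with tie
    correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SeptimarkError("each group needs at least 2 values")
    if method not in ("t", "rank", "auto"):
        raise SeptimarkError(f"unknown test method {method!r}")
    if np.ptp(np.concatenate([a, b])) == 0:
        # all observations identical: no evidence of any difference
        chosen = "t" if method in ("t", "auto") else "rank"
        return GroupTestResult(0.0, 1.0, chosen)
    if method == "auto":
        method = "rank" if any(_fails_normality(g) for g in (a, b)) else "t"
    if method == "t":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupTestResult(float(stat), float(min(p, 1.0)), method)


def _fails_normality(g: np.ndarray, alpha: float = 0.05) -> bool:
    if g.size < 3:
        return False
    if np.ptp(g) == 0:
        return True
    return stats.shapiro(g).pvalue < alpha


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> np.ndarray:
    """(FPR, TPR) pairs, one per distinct threshold, from (0,0) to (1,1).

    Thresholds sweep the distinct score values in descending order; all
    observations tied at a score enter at the same threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SeptimarkError("ROC requires both label classes to be present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    # keep the last index of each run of tied scores
    last = np.r_[s[1:] != s[:-1], True]
    fpr = np.r_[0.0, fp[last] / n_neg]
    tpr = np.r_[0.0, tp[last] / n_pos]
    return np.column_stack([fpr, tpr])


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Trapezoidal area under :func:`roc_curve`.

    Equals (concordant pairs + tied pairs / 2) / (n_pos * n_neg).
    """
    pts = roc_curve(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


@dataclass
class MarkerReport:
    """Per-candidate, per-day effect sizes, tests, and ROC discrimination."""

    table: pd.DataFrame
    roc: dict = field(default_factory=dict)  # (feature, day) -> ndarray of (FPR, TPR)
    day1_exceeds_day3: dict = field(default_factory=dict)  # feature -> bool

    def to_json(self, path=None) -> str:
        doc = {
            "table": self.table.to_dict(orient="records"),
            "day1_exceeds_day3": dict(sorted(self.day1_exceeds_day3.items())),
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def evaluate_panel(
    panel: Sequence[str],
    day_matrices: Mapping[int, AbundanceMatrix],
    samples: pd.DataFrame,
    positive_group: str = "S",
    reference_group: str = "NS",
) -> MarkerReport:
    """Validate a candidate panel on each day's matrix.

    For every feature x day: mean log2 difference (positive minus reference
    group), auto-selected two-group test, and AUC with the positive group's
    samples scored as positives.  Missing cells are dropped pairwise.  A
    feature absent from any day's matrix is an error listing the absentees.
    """
    panel = list(panel)
    if not panel:
        raise SeptimarkError("panel is empty")
    rows = []
    roc_store: dict = {}
    aucs: dict[str, dict[int, float]] = {f: {} for f in panel}
    for day in sorted(day_matrices):
        m = day_matrices[day]
        absent = [f for f in panel if f not in m.values.index]
        if absent:
            raise SeptimarkError(f"panel features absent from day-{day} matrix: {absent}")
        vals = m.values
        if m.state in ("raw", "normalized"):
            if (vals.to_numpy()[~np.isnan(vals.to_numpy())] <= 0).any():
                raise ValidationError("raw intensities must be positive for log2 scaling")
            vals = np.log2(vals)
        ids_pos = [s for s in samples_in_group(samples, positive_group, day) if s in vals.columns]
        ids_ref = [s for s in samples_in_group(samples, reference_group, day) if s in vals.columns]
        if len(ids_pos) < 2 or len(ids_ref) < 2:
            raise SeptimarkError(
                f"day {day}: need >=2 samples per group, got "
                f"{len(ids_pos)} {positive_group} / {len(ids_ref)} {reference_group}")
        for feat in panel:
            a = vals.loc[feat, ids_pos].dropna().to_numpy()
            b = vals.loc[feat, ids_ref].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                raise SeptimarkError(
                    f"feature {feat!r} day {day}: fewer than 2 observed values in a group")
            test = group_test(a, b, method="auto")
            scores = np.concatenate([a, b])
            labels = np.r_[np.ones(a.size, dtype=bool), np.zeros(b.size, dtype=bool)]
            area = auc(scores, labels)
            roc_store[(feat, day)] = roc_curve(scores, labels)
            aucs[feat][day] = area
            rows.append({
                "feature": feat, "day": day,
                "n_s": int(a.size), "n_ns": int(b.size),
                "mean_diff_log2": float(a.mean() - b.mean()),
                "test": test.method, "statistic": test.statistic, "p": test.pvalue,
                "auc": area, "significant": bool(test.pvalue < 0.05),
            })
    table = pd.DataFrame(rows)
    day1_exceeds = {}
    for feat, per_day in aucs.items():
        if 1 in per_day and 3 in per_day:
            day1_exceeds[feat] = bool(per_day[1] > per_day[3])
    return MarkerReport(table=table, roc=roc_store, day1_exceeds_day3=day1_exceeds)
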