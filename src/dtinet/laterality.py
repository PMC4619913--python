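"""Laterality statistics: LI ratios, sign tests, Bonferroni, paired t-tests.

For every homotopic region pair and each nodal property, the laterality
index LI = (L - R)/(L + R) is computed per subject, with the path-length
property entered as its reciprocal 1/L_i (nodal efficiency) so that a
positive LI uniformly means "better topology on the left" — larger degree,
larger betweenness, shorter path length.

Group-level nullity of LI is tested with the exact one-tailed sign test:
zeros (ties) are dropped, and with n nonzero values of which k match the
tested direction, p = P(X >= k), X ~ Binomial(n, 1/2).  Both directions are
tested per pair and the smaller tail is reported with its direction; the two
tails are mutually exclusive at small alpha, so the Bonferroni family stays
the number of homotopic pairs per property (45 for a 90-region parcellation).

Tract asymmetries (mean FA, fiber number) use two-sided paired t-tests over
the subjects in whom both hemispheres are trackable, significant at p < 0.05
uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import NodalMetrics
from .parcellation import homotopic_pairs
from .tracts import TractStats

__all__ = [
    "laterality_index",
    "sign_test",
    "bonferroni",
    "paired_t_test",
    "PairedTResult",
    "AsymmetryReport",
    "run_asymmetry_analysis",
]

NODAL_PROPERTIES = ("degree", "efficiency", "betweenness")


def laterality_index(left_value, right_value):
    """LI = (L - R)/(L + R); inputs must be nonnegative.

    The degenerate case L = R = 0 returns 0 (no evidence either way); such
    ties are excluded from the sign test downstream anyway.
    """
    left = np.asarray(left_value, dtype=float)
    right = np.asarray(right_value, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("laterality inputs must be nonnegative")
    total = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(total > 0, (left - right) / np.where(total > 0, total, 1.0), 0.0)
    return float(li) if li.ndim == 0 else li


def sign_test(li_values, direction: str = "leftward") -> float:
    """Exact one-tailed sign test on LI signs; ties excluded.

    ``direction`` 'leftward' tests for a preponderance of positive LI,
    'rightward' for negative.  All-zero input yields p = 1 with a warning.
    """
    if direction not in ("leftward", "rightward"):
        raise ValueError(f"unknown direction {direction!r}")
    li = np.asarray(li_values, dtype=float)
    nonzero = li[li != 0]
    n = nonzero.size
    if n == 0:
        warnings.warn("sign test on all-zero laterality values; p = 1")
        return 1.0
    k = int((nonzero > 0).sum()) if direction == "leftward" else int((nonzero < 0).sum())
    # P(X >= k), X ~ Binomial(n, 1/2)
    return float(stats.binom.sf(k - 1, n, 0.5))


def bonferroni(pvalues, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    """Family-wise significance flags: p < alpha / m."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m


@dataclass
class PairedTResult:
    t: float
    p: float
    n: int
    mean_difference: float
    degenerate: bool = False  # nonzero constant differences: t undefined


def paired_t_test(left_values, right_values) -> PairedTResult:
    """Two-sided paired t-test on left-right differences.

    Pairs with a missing (NaN) side are dropped.  All-zero differences give
    p = 1 by convention; nonzero zero-variance differences are flagged
    degenerate (the t statistic is unbounded).
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(left) & np.isfinite(right)
    left, right = left[ok], right[ok]
    if left.size < 2:
        raise ValueError("paired t-test needs >= 2 complete pairs")
    diff = left - right
    scale = np.abs(diff).max()
    if np.ptp(diff) <= 1e-10 * scale or scale == 0:  # constant differences
        if diff[0] == 0:
            return PairedTResult(t=0.0, p=1.0, n=diff.size, mean_difference=0.0)
        return PairedTResult(
            t=np.inf if diff[0] > 0 else -np.inf, p=np.nan, n=diff.size,
            mean_difference=float(diff.mean()), degenerate=True,
        )
    t, p = stats.ttest_rel(left, right)
    return PairedTResult(t=float(t), p=float(p), n=diff.size,
                         mean_difference=float(diff.mean()))


@dataclass
class AsymmetryReport:
    """Laterality table, per-subject LI values, and tract comparisons."""

    laterality: pd.DataFrame  # one row per (pair, property)
    li_values: dict[tuple[tuple[int, int], str], np.ndarray]
    tracts: pd.DataFrame  # one row per (tract, measure)
    alpha: float
    n_pairs: int

    def significant_pairs(self, prop: str) -> list[tuple[int, int]]:
        t = self.laterality
        rows = t[(t["property"] == prop) & t["significant"]]
        return [(int(l), int(r)) for l, r in zip(rows["left_label"], rows["right_label"])]


def _property_values(metrics: NodalMetrics, prop: str) -> np.ndarray:
    if prop == "degree":
        return metrics.degree
    if prop == "efficiency":
        with np.errstate(divide="ignore"):
            return np.where(np.isinf(metrics.path_length), 0.0, 1.0 / metrics.path_length)
    if prop == "betweenness":
        return metrics.norm_betweenness
    raise KeyError(prop)


def run_asymmetry_analysis(nodal_metrics: list[NodalMetrics],
                           tract_stats: list[list[TractStats]] | None = None,
                           alpha: float = 0.05,
                           tract_alpha: float = 0.05) -> AsymmetryReport:
    """Full group laterality analysis over a cohort.

    Parameters
    ----------
    nodal_metrics
        One :class:`NodalMetrics` per subject (same node count).
    tract_stats
        Optional per-subject lists of :class:`TractStats`; per tract name, a
        paired t compares left vs right mean FA and fiber number over the
        subjects where both hemispheres are trackable.
    """
    if len(nodal_metrics) < 2:
        raise ValueError("asymmetry analysis needs >= 2 subjects")
    n_nodes = nodal_metrics[0].n_nodes
    if any(m.n_nodes != n_nodes for m in nodal_metrics):
        raise ValueError("subjects disagree on node count")
    if tract_stats is not None and len(tract_stats) != len(nodal_metrics):
        raise ValueError("tract stats and nodal metrics cover different subject counts")

    pairs = homotopic_pairs(n_nodes)
    m_pairs = len(pairs)
    rows = []
    li_store: dict[tuple[tuple[int, int], str], np.ndarray] = {}
    for prop in NODAL_PROPERTIES:
        values = np.stack([_property_values(met, prop) for met in nodal_metrics])
        for left_label, right_label in pairs:
            li = laterality_index(values[:, left_label - 1], values[:, right_label - 1])
            li_store[((left_label, right_label), prop)] = li
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_left = sign_test(li, "leftward")
                p_right = sign_test(li, "rightward")
            if p_left <= p_right:
                p, direction = p_left, "leftward"
            else:
                p, direction = p_right, "rightward"
            rows.append(
                {
                    "left_label": left_label,
                    "right_label": right_label,
                    "property": prop,
                    "median_li": float(np.median(li)),
                    "n_nonzero": int((li != 0).sum()),
                    "p": p,
                    "direction": direction,
                }
            )
    laterality = pd.DataFrame(rows)
    laterality["significant"] = bonferroni(laterality["p"].to_numpy(), alpha, m_pairs)

    tract_rows = []
    if tract_stats is not None:
        names = sorted({t.name for subj in tract_stats for t in subj})
        for name in names:
            sides = {"left": [], "right": []}
            for subj in tract_stats:
                by_hemi = {t.hemisphere: t for t in subj if t.name == name}
                for hemi in sides:
                    t = by_hemi.get(hemi)
                    both = all(
                        h in by_hemi and by_hemi[h].trackable for h in ("left", "right")
                    )
                    sides[hemi].append(t if both else None)
            for measure in ("mean_fa", "fiber_number"):
                left = np.array([getattr(t, measure) if t else np.nan for t in sides["left"]])
                right = np.array([getattr(t, measure) if t else np.nan for t in sides["right"]])
                n_complete = int((np.isfinite(left) & np.isfinite(right)).sum())
                if n_complete < 2:
                    tract_rows.append(
                        {"tract": name, "measure": measure, "n": n_complete,
                         "t": np.nan, "p": np.nan, "mean_difference": np.nan,
                         "significant": False, "direction": "none"}
                    )
                    continue
                res = paired_t_test(left, right)
                significant = (not res.degenerate) and res.p < tract_alpha
                direction = "leftward" if res.mean_difference > 0 else (
                    "rightward" if res.mean_difference < 0 else "none"
                )
                tract_rows.append(
                    {"tract": name, "measure": measure, "n": res.n, "t": res.t,
                     "p": res.p, "mean_difference": res.mean_difference,
                     "significant": bool(significant), "direction": direction}
                )
    tracts = pd.DataFrame(
        tract_rows,
        columns=["tract", "measure", "n", "t", "p", "mean_difference",
                 "significant", "direction"],
    )
    return AsymmetryReport(laterality=laterality, li_values=li_store,
                           tracts=tracts, alpha=alpha, n_pairs=m_pairs)
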