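"""Differential latent-variable testing between clinical groups.

Per-LV two-sided Mann–Whitney tests with Benjamini–Hochberg control of the
false discovery rate across the tested LV family (typically the
interpretable LVs only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .plier import LVScores

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater"}


@dataclass
class DiffTestResult:
    lv: str
    u_stat: float
    p_value: float
    fdr: float
    direction: str  # higher_in_group1 | higher_in_group2 | none
    group_medians: tuple

    def as_dict(self) -> dict:
        return {
            "lv": self.lv,
            "u_stat": self.u_stat,
            "p_value": self.p_value,
            "fdr": self.fdr,
            "direction": self.direction,
            "median_group1": self.group_medians[0],
            "median_group2": self.group_medians[1],
        }


def mann_whitney(x, y, alternative: str = "two_sided"):
    """Mann–Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of the permutation distribution)
    when the combined sample size is at most 20 and there are no ties;
    otherwise the normal approximation with tie and continuity correction
    is used.  Returns ``(u_stat, p_value)`` where the U statistic counts
    pairs in which x exceeds y (ties counted one half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        # every pair tied: U is its null mean and no evidence either way
        return x.size * y.size / 2.0, 1.0
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method,
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_lv_analysis(scores, labels, lv_subset=None) -> list:
    """Two-sided Mann–Whitney tests of per-LV scores between two groups.

    Parameters
    ----------
    scores : LVScores or DataFrame (LVs × samples)
    labels : mapping/Series of sample → binary group (0/1 or two labels)
    lv_subset : iterable of LV names, optional
        Restrict testing (and the BH family) to these LVs; defaults to all
        rows of ``scores`` — pass the interpretable set for the standard
        workflow.
    """
    df = scores.to_frame() if isinstance(scores, LVScores) else pd.DataFrame(scores)
    labels = pd.Series(labels)
    labels = labels.reindex(df.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {len(groups)}")
    g1, g2 = sorted(groups, key=str)
    mask1 = (labels == g1).to_numpy()

    if lv_subset is not None:
        missing = [lv for lv in lv_subset if lv not in df.index]
        if missing:
            raise ValueError(f"unknown LVs in subset: {missing[:5]}")
        df = df.loc[list(lv_subset)]

    results = []
    for lv, row in df.iterrows():
        x = row.to_numpy()[mask1]
        y = row.to_numpy()[~mask1]
        u, p = mann_whitney(x, y, alternative="two_sided")
        m1, m2 = float(np.median(x)), float(np.median(y))
        if m1 > m2:
            direction = "higher_in_group1"
        elif m2 > m1:
            direction = "higher_in_group2"
        else:
            direction = "none"
        results.append(DiffTestResult(str(lv), u, p, np.nan, direction, (m1, m2)))

    fdrs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def diff_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
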