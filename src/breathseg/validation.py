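"""Scoring predicted segmentations against truth, and group summaries.

Predicted and truth cycle lists are paired greedily by inspiratory start
time; matched pairs contribute absolute errors on all four burst boundaries
and the intersection-over-union of the inhalation and exhalation phase
spans.  Group summaries report mean, standard error, standard deviation and
a Student-t 95% confidence interval per (variable, group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phase_segmentation import RespiratoryCycle

__all__ = ["CyclePairing", "SegmentationScore", "match_cycles", "score_segmentation", "summarize_groups"]


@dataclass
class CyclePairing:
    predicted: list[RespiratoryCycle]
    truth: list[RespiratoryCycle]
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (pred_idx, truth_idx)


@dataclass
class SegmentationScore:
    n_true: int
    n_detected: int
    n_matched: int
    mean_abs_boundary_err_s: float
    median_abs_boundary_err_s: float
    mean_phase_iou: float

    @property
    def detection_rate(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")


def match_cycles(
    predicted: list[RespiratoryCycle],
    truth: list[RespiratoryCycle],
    max_offset_s: float = 1.0,
) -> CyclePairing:
    """Greedy one-to-one pairing by |s1_start difference| (closest first)."""
    cands = [
        (abs(p.s1_start_s - t.s1_start_s), i, j)
        for i, p in enumerate(predicted)
        for j, t in enumerate(truth)
        if abs(p.s1_start_s - t.s1_start_s) <= max_offset_s
    ]
    cands.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_p or j in used_t:
            continue
        pairs.append((i, j))
        used_p.add(i)
        used_t.add(j)
    pairs.sort(key=lambda ij: ij[1])
    return CyclePairing(predicted, truth, pairs)


def _iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def score_segmentation(pairing: CyclePairing) -> SegmentationScore:
    """Boundary errors (all four burst boundaries) and mean phase IoU over
    matched pairs."""
    errs: list[float] = []
    ious: list[float] = []
    for i, j in pairing.pairs:
        p, t = pairing.predicted[i], pairing.truth[j]
        errs += [
            abs(p.s1_start_s - t.s1_start_s),
            abs(p.s1_end_s - t.s1_end_s),
            abs(p.s2_start_s - t.s2_start_s),
            abs(p.s2_end_s - t.s2_end_s),
        ]
        ious.append(
            0.5 * (_iou(p.inhalation_span, t.inhalation_span) + _iou(p.exhalation_span, t.exhalation_span))
        )
    return SegmentationScore(
        n_true=len(pairing.truth),
        n_detected=len(pairing.predicted),
        n_matched=len(pairing.pairs),
        mean_abs_boundary_err_s=float(np.mean(errs)) if errs else float("nan"),
        median_abs_boundary_err_s=float(np.median(errs)) if errs else float("nan"),
        mean_phase_iou=float(np.mean(ious)) if ious else float("nan"),
    )


def summarize_groups(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group_col: str = "group",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-(variable, group) mean, standard error, sample sd and Student-t CI.

    ``sd`` uses the n-1 denominator, ``se = sd/sqrt(n)`` and the CI is
    ``mean ± t(1-(1-confidence)/2, n-1) * se``.  Groups of fewer than two
    observations raise.
    """
    if variables is None:
        variables = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for var in variables:
        for group, sub in table.groupby(group_col, sort=True):
            vals = sub[var].dropna().to_numpy(dtype=float)
            n = vals.size
            if n < 2:
                raise ValueError(f"group {group!r} has fewer than 2 observations of {var!r}")
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            se = sd / np.sqrt(n)
            tcrit = float(stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, n - 1))
            rows.append({
                "variable": var, "group": group, "n": n, "mean": mean,
                "std_err": se, "std_dev": sd,
                "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se,
            })
    return pd.DataFrame(rows, columns=["variable", "group", "n", "mean", "std_err", "std_dev", "ci_low", "ci_high"])
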