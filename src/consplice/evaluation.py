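"""Evaluation statistics for pathogenic/benign variant discrimination.

Precision-recall is used throughout (the truth sets are heavily imbalanced);
the primary summary is the step-sum average precision
sum_i (R_i - R_{i-1}) * P_i over descending score thresholds, with the
trapezoidal PR area reported as a clearly-labeled secondary. Enrichment is an
odds ratio of pathogenic to benign variants per score decile with a 95%
normal-approximation CI on the log odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CANONICAL_LABELS

PATHOGENIC = "pathogenic"
BENIGN = "benign"

SPLICE_REGION_LABELS = CANONICAL_LABELS + (
    "splice_region_intronic",
    "splice_region_exonic",
)


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    return arr == PATHOGENIC


@dataclass
class PRCurve:
    """Precision/recall at every distinct score threshold, descending."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_pathogenic: int
    n_benign: int

    @property
    def baseline(self) -> float:
        return pr_baseline(self.n_pathogenic, self.n_benign)


def pr_curve(scores, labels) -> PRCurve:
    """PR curve with one point per distinct score, thresholds descending.

    At threshold t everything scoring >= t is called pathogenic. Ties share a
    threshold (a single curve point). Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = _to_binary(labels)
    if len(s) != len(y) or len(s) == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_path = int(y.sum())
    n_ben = int(len(y) - n_path)
    if n_path == 0 or n_ben == 0:
        raise ValueError("both classes are required for a PR curve")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tp = np.cumsum(y)
    calls = np.arange(1, len(s) + 1)
    # last index of each tie group = the point where score >= threshold
    is_last = np.r_[s[1:] != s[:-1], True]
    thresholds = s[is_last]
    tp_t = tp[is_last]
    calls_t = calls[is_last]
    precision = tp_t / calls_t
    recall = tp_t / n_path
    return PRCurve(
        thresholds=thresholds, precision=precision, recall=recall,
        n_pathogenic=n_path, n_benign=n_ben,
    )


def average_precision(curve: PRCurve) -> float:
    """Step-sum average precision: sum_i (R_i - R_{i-1}) P_i with R_0 = 0."""
    r_prev = np.r_[0.0, curve.recall[:-1]]
    return float(np.sum((curve.recall - r_prev) * curve.precision))


def pr_auc_trapezoid(curve: PRCurve) -> float:
    """Trapezoidal area under the PR curve (secondary summary)."""
    return float(np.trapezoid(curve.precision, curve.recall))


def pr_baseline(n_pathogenic: int, n_benign: int) -> float:
    """Random-chance precision: P / (P + B)."""
    total = n_pathogenic + n_benign
    if total <= 0:
        raise ValueError("empty truth set")
    return n_pathogenic / total


@dataclass(frozen=True)
class DecileBinning:
    """Ten bins over [0, 1]; left-closed, right-open except the last (closed)."""

    n_bins: int = 10

    def index(self, score: float) -> int:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score {score} outside [0, 1]")
        return int(self.indices([score])[0])

    def indices(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        if np.any((s < 0) | (s > 1)):
            raise ValueError("scores outside [0, 1]")
        # searchsorted on rounded edges keeps e.g. 0.7 in its own bin despite
        # binary floating point; the last bin is closed above.
        idx = np.searchsorted(self.edges(), s, side="right") - 1
        return np.minimum(idx, self.n_bins - 1)

    def edges(self) -> np.ndarray:
        return np.round(np.linspace(0.0, 1.0, self.n_bins + 1), 12)


def decile_index(score: float, binning: DecileBinning | None = None) -> int:
    return (binning or DecileBinning()).index(score)


def odds_ratio_enrichment(
    scores,
    labels,
    binning: DecileBinning | None = None,
) -> pd.DataFrame:
    """Per-decile odds ratio of pathogenic to benign variants with 95% CI.

    OR_i = (A_i/B_i) / (C_i/D_i) with A/B the pathogenic/benign counts in the
    decile and C/D the counts outside it; s.e. = sqrt(1/A + 1/B + 1/C + 1/D)
    on the log OR, CI = exp(ln OR +/- 1.96 s.e.). Deciles with any zero cell
    get the Haldane-Anscombe 0.5 correction on all four cells and are flagged.
    """
    binning = binning or DecileBinning()
    y = _to_binary(labels)
    bins = binning.indices(scores)
    total_path = int(y.sum())
    total_ben = int(len(y) - total_path)
    if total_path == 0 or total_ben == 0:
        raise ValueError("both classes are required for enrichment")
    edges = binning.edges()
    rows = []
    for i in range(binning.n_bins):
        in_bin = bins == i
        a = int((in_bin & y).sum())
        b = int((in_bin & ~y).sum())
        c = total_path - a
        d = total_ben - b
        corrected = 0 in (a, b, c, d)
        aa, bb, cc, dd = (
            (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
        )
        oratio = (aa / bb) / (cc / dd)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        rows.append(
            {
                "decile": i,
                "bin_lo": edges[i],
                "bin_hi": edges[i + 1],
                "A": a,
                "B": b,
                "C": c,
                "D": d,
                "OR": oratio,
                "se": se,
                "CI_lo": float(np.exp(np.log(oratio) - 1.96 * se)),
                "CI_hi": float(np.exp(np.log(oratio) + 1.96 * se)),
                "corrected": corrected,
            }
        )
    return pd.DataFrame(rows)


SUBSET_RULES = ("drop-canonical", "drop-splice-region", "low-spliceai")


def subset_filter(examples: pd.DataFrame, rules) -> pd.DataFrame:
    """Stratified evaluation subsets, composable.

    drop-canonical removes A-1/A-2/D+1/D+2 variants; drop-splice-region
    removes the 8-intronic/3-exonic splice region (canonical sites included);
    low-spliceai keeps variants with max splice-prediction score < 0.2.
    Requires ``position_label`` and/or ``spliceai_max`` columns.
    """
    if isinstance(rules, str):
        rules = [rules]
    out = examples
    for rule in rules:
        if rule == "drop-canonical":
            out = out[~out["position_label"].isin(CANONICAL_LABELS)]
        elif rule == "drop-splice-region":
            out = out[~out["position_label"].isin(SPLICE_REGION_LABELS)]
        elif rule == "low-spliceai":
            out = out[out["spliceai_max"] < 0.2]
        else:
            raise ValueError(f"unknown subset rule {rule!r}; choose from {SUBSET_RULES}")
    return out.copy()


def evaluation_frame(scores_by_method: dict[str, np.ndarray], labels, subset: str = "all") -> pd.DataFrame:
    """One report row per method: average precision, PR area, and baseline."""
    rows = []
    for method, scores in scores_by_method.items():
        curve = pr_curve(scores, labels)
        rows.append(
            {
                "method": method,
                "subset": subset,
                "n_path": curve.n_pathogenic,
                "n_benign": curve.n_benign,
                "avg_precision": average_precision(curve),
                "pr_auc": pr_auc_trapezoid(curve),
                "baseline": curve.baseline,
            }
        )
    return pd.DataFrame(rows)
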