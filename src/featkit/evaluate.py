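"""Site-wise prediction evaluation: confusion counts, ratio metrics, MCC,
ranking metrics, and per-protein / pooled aggregation.

Conventions: a site is predicted positive when its score >= threshold
(closed on the left).  Ratio metrics with a zero denominator are reported as
None rather than 0, so macro-averaging can skip them instead of biasing the
mean.  AUROC uses the rank-based Mann-Whitney formulation with average ranks
for ties; AUPRC is the trapezoidal area under the precision-recall
staircase and is therefore approximate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    f1: float | None = None
    mcc: float | None = None
    auroc: float | None = None
    auprc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _validate(y_true, y_score):
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_score.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_score.shape}")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return y_true.astype(int), y_score


def confusion(y_true, y_score, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) with prediction = score >= threshold."""
    y_true, y_score = _validate(y_true, y_score)
    pred = y_score >= threshold
    tp = int(np.sum(pred & (y_true == 1)))
    fp = int(np.sum(pred & (y_true == 0)))
    fn = int(np.sum(~pred & (y_true == 1)))
    tn = int(np.sum(~pred & (y_true == 0)))
    return tp, fp, fn, tn


def _ratio(num, den):
    return num / den if den > 0 else None


def metrics(counts) -> MetricReport:
    """Derive the site-wise metric suite from (tp, fp, fn, tn) counts."""
    tp, fp, fn, tn = (int(c) for c in counts)
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("negative confusion count")
    n = tp + fp + fn + tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = _ratio(tp + tn, n)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None if precision is None or recall is None else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricReport(tp=tp, fp=fp, fn=fn, tn=tn, accuracy=accuracy,
                        precision=precision, recall=recall,
                        specificity=specificity, f1=f1, mcc=mcc)


def auroc(y_true, y_score) -> float | None:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the probability that a random positive outranks a random
    negative; ties receive average ranks.  None (with a warning) when only
    one class is present.
    """
    y_true, y_score = _validate(y_true, y_score)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUROC undefined: only one class present")
        return None
    ranks = rankdata(y_score)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(y_true, y_score) -> float | None:
    """Trapezoidal area under the precision-recall staircase."""
    y_true, y_score = _validate(y_true, y_score)
    n_pos = int(y_true.sum())
    if n_pos == 0 or n_pos == y_true.size:
        warnings.warn("AUPRC undefined: only one class present")
        return None
    order = np.argsort(-y_score, kind="stable")
    y_sorted = y_true[order]
    s_sorted = y_score[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # evaluate at distinct thresholds only (last index of each tied block)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.append(distinct, y_true.size - 1)
    precision = tps[idx] / (tps[idx] + fps[idx])
    recall = tps[idx] / n_pos
    recall = np.concatenate(([0.0], recall))
    precision = np.concatenate(([precision[0]], precision))
    return float(np.trapezoid(precision, recall))


def evaluate_sites(y_true, y_score, threshold: float = 0.5) -> MetricReport:
    """Full metric report (confusion + ratios + ranking metrics) in one call."""
    report = metrics(confusion(y_true, y_score, threshold))
    y_arr = np.asarray(y_true)
    if 0 < y_arr.sum() < y_arr.size:
        report.auroc = auroc(y_true, y_score)
        report.auprc = auprc(y_true, y_score)
    return report


def aggregate(reports: list[MetricReport], mode: str = "pooled"):
    """Combine per-protein reports.

    pooled: sum confusion counts, then recompute metrics — equivalent to
    evaluating the concatenated sites.  macro: average each metric over
    proteins, skipping None values (the skip count is reported).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    if mode == "pooled":
        tp = sum(r.tp for r in reports)
        fp = sum(r.fp for r in reports)
        fn = sum(r.fn for r in reports)
        tn = sum(r.tn for r in reports)
        return metrics((tp, fp, fn, tn))
    if mode == "macro":
        out: dict[str, float | int | None] = {}
        skipped: dict[str, int] = {}
        for name in ("accuracy", "precision", "recall", "specificity",
                     "f1", "mcc", "auroc", "auprc"):
            vals = [getattr(r, name) for r in reports]
            present = [v for v in vals if v is not None]
            skipped[name] = len(vals) - len(present)
            out[name] = float(np.mean(present)) if present else None
        out["n_proteins"] = len(reports)
        out["skipped"] = skipped
        return out
    raise ValueError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# Plotting helpers (smoke-level surface; not a numerical interface)

def plot_metrics(reports: dict[str, MetricReport], path) -> None:
    """Grouped bar plot of the ratio metrics for one or more models."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not reports:
        raise ValueError("no reports to plot")
    names = ["accuracy", "precision", "recall", "specificity", "f1", "mcc"]
    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / len(reports)
    x = np.arange(len(names))
    for k, (label, rep) in enumerate(reports.items()):
        vals = [getattr(rep, m) if getattr(rep, m) is not None else np.nan
                for m in names]
        ax.bar(x + k * width, vals, width=width, label=label)
    ax.set_xticks(x + width * (len(reports) - 1) / 2)
    ax.set_xticklabels(names)
    ax.set_ylabel("value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_conservation(profile, path) -> None:
    """Line plot of a per-column conservation profile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(profile.scores if hasattr(profile, "scores") else profile)
    if scores.size == 0:
        raise ValueError("empty conservation profile")
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(np.arange(1, scores.size + 1), scores)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("conservation (bits)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
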