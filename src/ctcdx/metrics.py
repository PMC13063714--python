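"""Diagnostic-test evaluation: confusion metrics, ROC/AUC, subgroup reports.

AUC is computed by the Mann-Whitney pair-counting formulation (ties credited
1/2), with an analytic DeLong confidence interval and a stratified-bootstrap
(within-class resampling) percentile interval.  Confusion-matrix ratios with
zero denominators are reported as NA, never as 0.  Display rounding is
half-up to two decimals; raw values are always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionSummary",
    "ROCCurve",
    "confusion_metrics",
    "mann_whitney_auc",
    "delong_interval",
    "roc_auc",
    "sweep_thresholds",
    "probability_group_tests",
    "subgroup_metrics",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report display)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts and the derived diagnostic metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.n)

    @property
    def cer(self) -> float:
        acc = self.accuracy
        return float("nan") if np.isnan(acc) else 1.0 - acc

    def as_dict(self, rounded: bool = False) -> dict:
        vals = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "cer": self.cer,
        }
        if rounded:
            for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "cer"):
                vals[k] = round_half_up(vals[k])
        return vals


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("empty input")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return y.astype(int)


def confusion_metrics(labels, probabilities, threshold: float = 0.5) -> ConfusionSummary:
    """Confusion summary calling positive when probability strictly exceeds
    the threshold."""
    y = _check_binary(labels)
    p = np.asarray(probabilities, dtype=float)
    if p.shape != y.shape:
        raise ValueError("labels and probabilities must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p > threshold).astype(int)
    return ConfusionSummary(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# AUC / ROC
# ---------------------------------------------------------------------------


def mann_whitney_auc(labels, scores) -> float:
    """AUC as the Mann-Whitney U statistic (ties count 1/2), via midranks."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties with 1/2 credit
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def delong_interval(labels, scores, alpha: float = 0.05) -> tuple[float, float, float]:
    """DeLong variance and normal-approximation CI for a single AUC.

    Returns ``(auc, lo, hi)``; the interval is truncated to [0, 1].
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    # placement values via the Heaviside-with-ties kernel
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive placements
    v01 = psi.mean(axis=0)  # per-negative placements
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def _stratified_bootstrap_auc(
    y: np.ndarray, s: np.ndarray, n_bootstrap: int, rng: np.random.Generator
) -> np.ndarray:
    pos, neg = s[y == 1], s[y == 0]
    aucs = np.empty(n_bootstrap)
    labels = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    for b in range(n_bootstrap):
        sample = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        aucs[b] = mann_whitney_auc(labels, sample)
    return aucs


@dataclass
class ROCCurve:
    """ROC points with AUC and analytic + bootstrap intervals."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci_delong: tuple[float, float]
    auc_ci_bootstrap: tuple[float, float]
    n_bootstrap: int = 2000
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_delong": list(self.auc_ci_delong),
            "auc_ci_bootstrap": list(self.auc_ci_bootstrap),
            "n_bootstrap": self.n_bootstrap,
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
        }


def roc_auc(
    labels,
    scores,
    n_bootstrap: int = 2000,
    alpha: float = 0.05,
    random_state: int | None = 0,
) -> ROCCurve:
    """ROC curve with Mann-Whitney AUC, DeLong CI and stratified-bootstrap CI."""
    from sklearn.metrics import roc_curve as _sk_roc_curve

    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    auc, lo_d, hi_d = delong_interval(y, s, alpha=alpha)
    rng = np.random.default_rng(random_state)
    boot = _stratified_bootstrap_auc(y, s, n_bootstrap, rng)
    lo_b, hi_b = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return ROCCurve(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_ci_delong=(lo_d, hi_d),
        auc_ci_bootstrap=(float(max(lo_b, 0.0)), float(min(hi_b, 1.0))),
        n_bootstrap=n_bootstrap,
        thresholds=thr,
    )


def plot_roc(curve: ROCCurve, path, label: str = "") -> None:
    """Write a ROC plot (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve.fpr, curve.tpr, lw=1.5,
            label=f"{label} AUC={curve.auc:.2f}".strip())
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Threshold sweep and distribution tests
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.30, 0.8001, 0.05), 2)


def sweep_thresholds(labels, probabilities, grid=None) -> pd.DataFrame:
    """Confusion metrics across an operating-threshold grid (default 0.3-0.8)."""
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    rows = [
        confusion_metrics(labels, probabilities, threshold=float(t)).as_dict()
        for t in grid
    ]
    return pd.DataFrame(rows).set_index("threshold")


def probability_group_tests(probabilities, labels) -> dict:
    """Compare predicted-probability distributions between outcome groups.

    Returns the two-sided Mann-Whitney-Wilcoxon p (exact for small tie-free
    samples, asymptotic with continuity correction otherwise), the two-sample
    Kolmogorov-Smirnov p, and per-group mean/SD.
    """
    y = _check_binary(labels)
    p = np.asarray(probabilities, dtype=float)
    pos, neg = p[y == 1], p[y == 0]
    out = {
        "cancer_mean": float(pos.mean()) if pos.size else float("nan"),
        "cancer_sd": float(pos.std(ddof=1)) if pos.size > 1 else float("nan"),
        "benign_mean": float(neg.mean()) if neg.size else float("nan"),
        "benign_sd": float(neg.std(ddof=1)) if neg.size > 1 else float("nan"),
    }
    if pos.size == 0 or neg.size == 0:
        out.update(wmw_p=float("nan"), ks_p=float("nan"))
        return out
    if np.ptp(p) == 0:
        warnings.warn("degenerate (constant) probabilities", RuntimeWarning, stacklevel=2)
        out.update(wmw_p=float("nan"), ks_p=float("nan"))
        return out
    has_ties = np.unique(p).size < p.size
    method = "exact" if (max(pos.size, neg.size) <= 50 and not has_ties) else "asymptotic"
    out["wmw_p"] = float(
        stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )
    out["ks_p"] = float(stats.ks_2samp(pos, neg, method="asymp").pvalue)
    out["wmw_method"] = method
    return out


# ---------------------------------------------------------------------------
# Subgroup reports
# ---------------------------------------------------------------------------


def subgroup_metrics(
    predictions: pd.DataFrame,
    cohort_frame: pd.DataFrame,
    grouping: str,
    threshold: float = 0.5,
) -> dict:
    """Per-level confusion summaries for a subgroup variable.

    ``predictions`` needs columns ``subject_id``, ``probability`` and
    ``label`` (0/1 truth).  ``grouping`` may be ``birads``, ``stage``,
    ``subtype``, ``density`` or ``birads34`` (BI-RADS categories 3 and 4
    pooled).  Rows with NA grouping are excluded and counted; each level also
    reports outcome prevalence (detection rate).
    """
    source_col = "birads" if grouping == "birads34" else grouping
    if source_col not in cohort_frame.columns:
        raise ValueError(f"cohort has no column {source_col!r}")
    merged = predictions.merge(
        cohort_frame[["subject_id", source_col]], on="subject_id", how="left"
    )
    group = merged[source_col].astype("string")
    if grouping == "birads34":
        group = group.where(group.isin(["3", "4"]), pd.NA)
        group = group.map(lambda v: "3+4" if pd.notna(v) else v)
    n_na = int(group.isna().sum())
    levels = {}
    for level, rows in merged[group.notna()].groupby(group[group.notna()], observed=True):
        if rows.empty:
            continue
        cs = confusion_metrics(
            rows["label"].to_numpy(int),
            rows["probability"].to_numpy(float),
            threshold=threshold,
        )
        levels[str(level)] = {
            "n": int(len(rows)),
            "prevalence": float(rows["label"].mean()),
            **cs.as_dict(),
        }
    return {"grouping": grouping, "n_na": n_na, "levels": levels}
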