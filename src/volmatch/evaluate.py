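"""Metrics and diagnostics: accuracy, ROC/AUC, ROC averaging, femaleness /
covariate correlations, the TIV-threshold baseline, cross-cohort
evaluation, learning curves and the exact paired sign test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

__all__ = [
    "EvalReport", "CorrelationReport", "PairedComparison",
    "roc_auc", "average_roc", "femaleness_covariate_correlation",
    "tiv_threshold_baseline", "cross_cohort_eval", "learning_curve",
    "sign_test",
]


@dataclass
class EvalReport:
    """Classification report for one set of femaleness scores."""

    accuracy: float
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    optimal_threshold: float
    optimal_accuracy: float

    @property
    def probabilities(self) -> np.ndarray:
        from .nn import sigmoid
        return sigmoid(self.scores)


def roc_auc(scores, labels) -> EvalReport:
    """Accuracy (at score threshold 0) and trapezoidal ROC/AUC.

    ``labels`` are femaleness indicators (1 = female); a subject is
    predicted female iff its score is strictly positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    accuracy = float(np.mean((scores > 0).astype(int) == labels))
    fpr, tpr, thr = skmetrics.roc_curve(labels, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    # threshold maximizing accuracy, for the score-distribution diagnostics
    cand = np.concatenate([[scores.min() - 1.0],
                           (np.sort(scores)[1:] + np.sort(scores)[:-1]) / 2,
                           [scores.max() + 1.0]])
    accs = [(np.mean((scores > t).astype(int) == labels), -t) for t in cand]
    best_acc, neg_t = max(accs)
    return EvalReport(accuracy=accuracy, auc=auc, fpr=fpr, tpr=tpr,
                      scores=scores, labels=labels,
                      optimal_threshold=-neg_t,
                      optimal_accuracy=float(best_acc))


def average_roc(reports: list[EvalReport], n_grid: int = 101
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertically average ROC curves on a fixed FPR grid.

    Returns ``(fpr_grid, mean_tpr, mean_auc)`` where ``mean_auc`` is the
    arithmetic mean of the per-run AUCs.
    """
    if len(reports) < 2:
        raise ValueError("need at least two runs to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = [np.interp(grid, r.fpr, r.tpr) for r in reports]
    mean_tpr = np.mean(tprs, axis=0)
    return grid, mean_tpr, float(np.mean([r.auc for r in reports]))


@dataclass
class CorrelationReport:
    """Within-group Pearson correlation with a Wald test on the slope."""

    group: str
    covariate: str
    n: int
    rho: float
    p_value: float
    slope: float
    degenerate: bool = False


def femaleness_covariate_correlation(
    frame: pd.DataFrame,
    covariate: str = "tiv_ml",
    score_col: str = "score",
    by_sex: bool = True,
) -> list[CorrelationReport]:
    """Correlate femaleness scores with a covariate (TIV or age) within sex.

    The p-value is the two-sided Wald test for a zero slope of the simple
    linear regression of score on covariate (equivalently, the t-test of
    the regression slope).
    """
    groups = frame.groupby("sex") if by_sex else [("all", frame)]
    out = []
    for name, g in groups:
        if len(g) < 3:
            raise ValueError(f"need n >= 3 per group, got {len(g)} for {name}")
        x = g[covariate].to_numpy(dtype=float)
        y = g[score_col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationReport(group=str(name), covariate=covariate,
                                         n=len(g), rho=float("nan"),
                                         p_value=float("nan"),
                                         slope=float("nan"), degenerate=True))
            continue
        fit = stats.linregress(x, y)
        out.append(CorrelationReport(group=str(name), covariate=covariate,
                                     n=len(g), rho=float(fit.rvalue),
                                     p_value=float(fit.pvalue),
                                     slope=float(fit.slope)))
    return out


def tiv_threshold_baseline(frame: pd.DataFrame) -> tuple[float, float]:
    """Best single-TIV-threshold classifier: female iff TIV < threshold.

    Scans all midpoints of adjacent sorted TIVs plus the two extremes;
    returns ``(threshold_ml, accuracy)``, preferring the smallest
    threshold on accuracy ties.
    """
    sexes = set(frame["sex"])
    if sexes != {"male", "female"}:
        raise ValueError("both sexes required")
    tiv = frame["tiv_ml"].to_numpy(dtype=float)
    female = (frame["sex"] == "female").to_numpy()
    u = np.unique(tiv)
    cand = np.concatenate([[u[0] - 1.0], (u[1:] + u[:-1]) / 2.0,
                           [u[-1] + 1.0]])
    pred_female = tiv[None, :] < cand[:, None]
    accs = (pred_female == female[None, :]).mean(axis=1)
    best = int(np.argmax(accs))  # argmax takes the first (smallest) on ties
    return float(cand[best]), float(accs[best])


def cross_cohort_eval(cv_results, images, labels) -> dict:
    """Score every subject of another cohort with each CV model.

    No retraining: each fitted model from the nested CV scores the full
    other cohort; per-model reports and their means are returned.
    """
    reports = []
    for res in cv_results.models:
        if res is None:
            raise ValueError("CV results were run with keep_models=False")
        reports.append(roc_auc(res.predict(images), labels))
    return {
        "reports": reports,
        "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
        "mean_auc": float(np.mean([r.auc for r in reports])),
    }


def learning_curve(
    images: np.ndarray,
    labels: np.ndarray,
    frame: pd.DataFrame,
    sizes: list[int],
    model_kind: str = "logreg",
    *,
    repeats: int = 1,
    seed: int = 0,
    scenario: str = "reduced",
    k: int = 5,
    l: int = 5,
    epochs: int | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Mean nested-CV AUC as a function of training-set size.

    For each size, ``repeats`` random subsets are drawn and a full nested
    CV is run on each (``repeats * k * l`` training runs per size).
    """
    from .cv import run_nested_cv
    from .matching import random_reduced_subsample

    ids = frame["subject_id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    rows = []
    for size in sizes:
        if size > len(ids):
            raise ValueError(f"size {size} exceeds cohort size {len(ids)}")
        subsets = random_reduced_subsample(frame, size, repeats=repeats,
                                           seed=seed + size)
        aucs, accs = [], []
        for rep, subset in enumerate(subsets):
            idx = [pos[s] for s in subset]
            cvres = run_nested_cv(images[idx], labels[idx], subset,
                                  model_kind, scenario,
                                  seed=seed + rep, k=k, l=l, epochs=epochs,
                                  keep_models=False, **cv_kwargs)
            aucs.append(cvres.mean_auc)
            accs.append(cvres.mean_accuracy)
        rows.append({"size": size, "mean_auc": float(np.mean(aucs)),
                     "mean_accuracy": float(np.mean(accs)),
                     "n_runs": len(subsets) * k * l})
    return pd.DataFrame(rows)


def plot_roc_curves(reports: list[EvalReport], path=None, title: str = "ROC"):
    """Plot per-run ROC curves (blue) with their vertical average (black).

    Requires matplotlib; returns the figure, optionally saving to ``path``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in reports:
        ax.plot(r.fpr, r.tpr, color="tab:blue", alpha=0.3, lw=1)
    if len(reports) >= 2:
        grid, mean_tpr, mean_auc = average_roc(reports)
        ax.plot(grid, mean_tpr, color="black", lw=2,
                label=f"mean AUC = {mean_auc:.3f}")
        ax.legend(loc="lower right")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig


@dataclass(frozen=True)
class PairedComparison:
    """2x2 paired-outcome table of two classifiers on the same cases."""

    both_correct: int
    a_only: int  # correct by A, wrong by B
    b_only: int  # correct by B, wrong by A
    both_wrong: int

    @property
    def n(self) -> int:
        return self.both_correct + self.a_only + self.b_only + self.both_wrong


def sign_test(paired: PairedComparison) -> dict:
    """Exact two-sided sign test on the discordant pairs.

    Under the null that both classifiers are equally accurate, the number
    of A-only-correct cases among the discordant pairs is
    Binomial(b + c, 1/2); the two-sided p doubles the smaller tail,
    capped at 1.
    """
    b, c = paired.a_only, paired.b_only
    m = b + c
    if m == 0:
        return {"p_value": 1.0, "discordant": 0, "degenerate": True}
    tail = stats.binom.cdf(min(b, c), m, 0.5)
    return {"p_value": float(min(1.0, 2.0 * tail)), "discordant": m,
            "degenerate": False}
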