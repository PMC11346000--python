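"""Cohort-level comparison statistics for the Ki67 assay.

The assay is validated against the pathologist's labelling index the way
method-comparison studies in this field report it: Spearman rank correlation
printed alongside an ordinary least-squares line on the raw percentages (an
unusual pairing, kept deliberately: the rank statistic carries the
concordance claim, the OLS line the visual slope/intercept), a paired t-test
for within-section protocol effects, ROC analysis against a 20% labelling
index cut-off with the Youden operating point, and a reproducibility
coefficient of variation across serial sections.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "spearman_with_fit",
    "paired_t",
    "roc_analysis",
    "reproducibility_cv",
]


def spearman_with_fit(x, y) -> dict:
    """Spearman rank correlation plus an OLS line on the raw values.

    ``x`` is the reference (e.g. pathology LI, percent), ``y`` the method
    under evaluation.  Ties receive average ranks.  Requires n >= 3 and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    fit = sps.linregress(x, y)
    return {"rho": float(rho), "p": float(p),
            "slope": float(fit.slope), "intercept": float(fit.intercept),
            "n": int(x.size)}


def paired_t(before, after) -> dict:
    """Classical paired t-test on the per-case differences (two-sided p)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise ValueError("paired t-test requires n >= 2")
    diff = after - before
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return {"t": 0.0, "p": 1.0, "n": int(before.size)}
        raise ValueError("zero-variance non-zero differences: t is unbounded")
    t, p = sps.ttest_rel(after, before)
    return {"t": float(t), "p": float(p), "n": int(before.size)}


def roc_analysis(scores, labels, *, positive_cutoff: float | None = None) -> dict:
    """Empirical ROC of ``scores`` against boolean ``labels``.

    ``labels`` may be booleans or, with ``positive_cutoff`` given, raw
    reference values dichotomized at that cut-off (e.g. labelling index
    >= 20%).  A case is called positive when its score is strictly above a
    threshold.  AUC is the trapezoidal area of the empirical curve (equal to
    the normalized Mann-Whitney U statistic).  The Youden threshold
    maximizes sensitivity + specificity - 1; ties break toward the higher
    threshold, i.e. toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if positive_cutoff is not None:
        labels = labels.astype(float) >= positive_cutoff
    labels = labels.astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    pos = scores[labels]
    neg = scores[~labels]
    thresholds = np.unique(scores)
    sens = np.array([np.mean(pos > t) for t in thresholds])
    spec = np.array([np.mean(neg <= t) for t in thresholds])
    # curve endpoints: everything positive / everything negative
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    youden = sens + spec - 1.0
    ties = np.flatnonzero(youden >= youden.max() - 1e-12)
    best = int(ties[-1])  # highest threshold, i.e. higher specificity
    return {
        "auc": auc,
        "youden_threshold": float(thresholds[best]),
        "sensitivity": float(sens[best]),
        "specificity": float(spec[best]),
        "n_pos": n_pos,
        "n_neg": n_neg,
    }


def reproducibility_cv(replicates) -> dict:
    """Per-case coefficient of variation across replicate measurements.

    ``replicates`` is a sequence of per-case positivity lists (serial
    sections of the same block).  Each case needs >= 2 replicates and a
    non-zero mean; CV = 100 * sample SD / mean.  The summary is the pooled
    mean of the per-case means and the mean of the per-case CVs.
    """
    per_case = []
    for i, reps in enumerate(replicates):
        reps = np.asarray(reps, dtype=float)
        if reps.size < 2:
            raise ValueError(f"case {i}: at least 2 replicates required")
        m = reps.mean()
        if m == 0:
            raise ValueError(f"case {i}: CV undefined for zero mean")
        per_case.append({"mean": float(m),
                         "cv_percent": float(100.0 * reps.std(ddof=1) / m)})
    if not per_case:
        raise ValueError("no cases supplied")
    return {
        "mean": float(np.mean([c["mean"] for c in per_case])),
        "cv_percent": float(np.mean([c["cv_percent"] for c in per_case])),
        "per_case": per_case,
    }
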