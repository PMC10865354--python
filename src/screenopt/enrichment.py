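"""Enrichment metrics: semilog ROC, LogAUC and normalized LogAUC.

Docking scores follow the energy convention: **lower is better**.  The ROC
is built by ranking all molecules by score ascending; early enrichment is
emphasized by integrating the ROC against log10(FPR) above a floor ``lam``
(default 0.001, i.e. 0.1% FPR).  Normalized LogAUC rescales the semilog
area so that a random classifier scores 0 and a perfect classifier scores
exactly 1; worse-than-random rankings are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_LAMBDA = 0.001

__all__ = [
    "DEFAULT_LAMBDA",
    "ScoredClasses",
    "RocCurve",
    "roc_curve",
    "logauc",
    "normalized_logauc",
    "adjusted_logauc",
    "random_baseline",
    "normalized_logauc_from_ranks",
    "get_criterion",
    "CRITERIA",
]


@dataclass(frozen=True)
class ScoredClasses:
    """Docking scores split by binary class (lower score = better rank)."""

    scores_pos: np.ndarray
    scores_neg: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores_pos", np.asarray(self.scores_pos, dtype=float))
        object.__setattr__(self, "scores_neg", np.asarray(self.scores_neg, dtype=float))
        if self.scores_pos.size == 0 or self.scores_neg.size == 0:
            raise ValueError("both classes must be non-empty for enrichment computation")


@dataclass(frozen=True)
class RocCurve:
    """Piecewise-linear ROC curve from (0,0) to (1,1).

    ``points`` is an (n, 2) array of (fpr, tpr) vertices; tied scores
    contribute diagonal segments, equivalent to averaging over all
    orderings of the tie.  ``lambda_floor`` is the FPR floor used by the
    semilog integral.
    """

    points: np.ndarray
    lambda_floor: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if np.any(np.diff(pts, axis=0) < -1e-12):
            raise ValueError("ROC points must be monotone non-decreasing")
        object.__setattr__(self, "points", pts)


def roc_curve(scored: ScoredClasses, lam: float = DEFAULT_LAMBDA) -> RocCurve:
    """Build the tie-averaged ROC step curve from scored classes.

    Molecules are ranked by score ascending (best first).  Each distinct
    score value contributes one vertex; a score shared by ``p`` positives
    and ``q`` negatives yields a diagonal segment spanning p/|P| in TPR and
    q/|N| in FPR.
    """
    pos = np.sort(scored.scores_pos)
    neg = np.sort(scored.scores_neg)
    thresholds = np.unique(np.concatenate([pos, neg]))
    # cumulative counts of molecules with score <= threshold
    tp = np.searchsorted(pos, thresholds, side="right") / pos.size
    fp = np.searchsorted(neg, thresholds, side="right") / neg.size
    points = np.column_stack([np.concatenate([[0.0], fp]), np.concatenate([[0.0], tp])])
    return RocCurve(points=points, lambda_floor=lam)


def _semilog_area(points: np.ndarray, lam: float) -> float:
    """Integral of TPR d(log10 FPR) over FPR in [lam, 1] for a piecewise-linear curve."""
    x = points[:, 0]
    y = points[:, 1]
    ln10 = np.log(10.0)
    total = 0.0
    for i in range(len(x) - 1):
        x1, x2, y1, y2 = x[i], x[i + 1], y[i], y[i + 1]
        if x2 <= lam or x2 <= x1:
            continue  # below the floor, or a vertical segment (zero measure)
        if x1 < lam:
            y1 = y1 + (y2 - y1) * (lam - x1) / (x2 - x1)
            x1 = lam
        m = (y2 - y1) / (x2 - x1)
        # closed form of \int y(x) dlog10(x) on [x1, x2] with y linear in x
        total += ((y1 - m * x1) * np.log(x2 / x1) + m * (x2 - x1)) / ln10
    return total


def logauc(curve: RocCurve) -> float:
    """Semilog AUC: area under TPR vs log10(FPR) on [lam, 1], normalized by log10(1/lam).

    Lies in [0, 1]; 1 for a perfect classifier, ``random_baseline(lam)``
    for the diagonal.
    """
    lam = curve.lambda_floor
    pts = curve.points
    # exact fast path: TPR already 1 at or below the floor => integrand is 1 on [lam, 1]
    if np.any((pts[:, 0] <= lam) & (pts[:, 1] >= 1.0)):
        return 1.0
    return _semilog_area(pts, lam) / np.log10(1.0 / lam)


def random_baseline(lam: float = DEFAULT_LAMBDA) -> float:
    """Expected LogAUC of the diagonal (random) ROC: (1 - lam) / (ln10 * log10(1/lam))."""
    return (1.0 - lam) / (np.log(10.0) * np.log10(1.0 / lam))


def normalized_logauc(scored: ScoredClasses, lam: float = DEFAULT_LAMBDA) -> float:
    """LogAUC rescaled so random -> 0 and perfect -> 1.

    Returns ``(logauc - R) / (1 - R)`` with ``R = random_baseline(lam)``.
    Negative values indicate worse-than-random ranking, with floor
    ``-R / (1 - R)`` for the classifier that ranks every negative first.
    """
    la = logauc(roc_curve(scored, lam))
    r = random_baseline(lam)
    return (la - r) / (1.0 - r)


def adjusted_logauc(scored: ScoredClasses, lam: float = DEFAULT_LAMBDA) -> float:
    """Un-rescaled variant: LogAUC minus the random baseline (perfect < 1)."""
    return logauc(roc_curve(scored, lam)) - random_baseline(lam)


def normalized_logauc_from_ranks(
    negatives_before: np.ndarray, n_neg: int, lam: float = DEFAULT_LAMBDA
) -> float:
    """Normalized LogAUC of a fully ranked list given per-positive rank context.

    ``negatives_before[i]`` is the number of negatives ranked strictly
    better than the i-th best positive (ascending).  All ranks are assumed
    distinct, so the ROC is a staircase; this is the fast path used by the
    null-distribution simulator and agrees exactly with
    :func:`normalized_logauc` on such inputs.
    """
    b = np.asarray(negatives_before, dtype=float)
    n_pos = b.size
    x = np.clip(b / n_neg, lam, 1.0)
    xnext = np.concatenate([x[1:], [1.0]])
    tpr = np.arange(1, n_pos + 1) / n_pos
    area = np.sum(tpr * (np.log10(xnext) - np.log10(x)))
    la = area / np.log10(1.0 / lam)
    r = random_baseline(lam)
    return float((la - r) / (1.0 - r))


#: Registry of evaluation criteria addressable by name; pipeline steps may
#: specify different criteria per step.
CRITERIA = {
    "normalized_logauc": normalized_logauc,
    "adjusted_logauc": adjusted_logauc,
    "logauc": lambda s, lam=DEFAULT_LAMBDA: logauc(roc_curve(s, lam)),
}


def get_criterion(name: str):
    """Look up an enrichment criterion by registry name."""
    try:
        return CRITERIA[name]
    except KeyError:
        raise KeyError(
            f"unknown criterion {name!r}; available: {sorted(CRITERIA)}"
        ) from None
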