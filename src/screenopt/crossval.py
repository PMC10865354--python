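"""Clustered leave-one-out cross-validation for docking-model optimization.

Optimizing parameters against a retrospective dataset can in principle
overfit it.  To test for that, positives are clustered by fingerprint
Tanimoto distance with complete linkage — so every cluster contains only
molecules within a maximum Tc distance of the cutoff (default 0.6) of
each other — and one fold is built per cluster: the held-out cluster
forms the test positives (chemically dissimilar from every training
positive), with negatives split to preserve the dataset's class ratio.
Running the beam search on each training set and scoring the best models
of the first and the last step on the test set shows whether iterating
the search degrades generalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from screenopt.nullstats import SignificanceConfig, significance_threshold, simulate_null

if TYPE_CHECKING:
    from screenopt.dataset import RetrospectiveDataset

__all__ = [
    "ClusterAssignment",
    "CvFold",
    "tanimoto_distance",
    "cluster_positives",
    "make_folds",
    "compare_first_last",
]


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) distance between bit fingerprints: 1 - |a&b| / |a|b|.

    Two all-zero fingerprints are defined as identical (distance 0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(1.0 - np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of the positive class: molecule id -> cluster id (1-based)."""

    assignment: dict[str, int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return [mid for mid, c in self.assignment.items() if c == cluster]

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.assignment.values()))


def cluster_positives(dataset: "RetrospectiveDataset", cutoff: float = 0.6) -> ClusterAssignment:
    """Complete-linkage clustering of positive fingerprints at a Tc-distance cutoff.

    Complete linkage is the method whose merge criterion — the maximum
    pairwise distance — matches the cluster definition used here: every
    cluster contains only molecules at most ``cutoff`` apart.  The output
    satisfies that invariant by construction.
    """
    positives = dataset.positives
    ids = [m.id for m in positives]
    if len(ids) == 1:
        return ClusterAssignment(assignment={ids[0]: 1}, cutoff=cutoff)
    X = dataset.fingerprint_matrix("positive").astype(bool)
    dist = pdist(X, metric="jaccard")
    labels = fcluster(linkage(dist, method="complete"), t=cutoff, criterion="distance")
    return ClusterAssignment(assignment=dict(zip(ids, (int(c) for c in labels))), cutoff=cutoff)


@dataclass(frozen=True)
class CvFold:
    """One leave-one-cluster-out split: molecule id sets for train and test."""

    held_out_cluster: int
    train: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if self.train & self.test:
            raise ValueError("train/test leakage: overlapping molecule ids")


def make_folds(
    dataset: "RetrospectiveDataset",
    assignment: ClusterAssignment,
    seed: int = 0,
) -> list[CvFold]:
    """One fold per cluster: test positives = the held-out cluster.

    Negatives are partitioned across folds (one shuffle, contiguous
    blocks) so each fold's test set keeps the dataset's negative:positive
    ratio for its positive count, within rounding; all remaining
    molecules go to train, so each fold's train and test partition the
    dataset.  Requires >= 2 clusters — with a single cluster there is no
    chemically distinct test set and cross-validation is meaningless.
    """
    clusters = assignment.clusters
    if len(clusters) < 2:
        raise ValueError(
            "only one fingerprint cluster: leave-one-cluster-out CV needs >= 2 clusters"
        )
    neg_ids = [m.id for m in dataset.negatives]
    all_ids = {m.id for m in dataset.molecules}
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(neg_ids))
    ratio = dataset.ratio

    folds = []
    start = 0
    for i, cluster in enumerate(clusters):
        test_pos = assignment.members(cluster)
        want = int(round(ratio * len(test_pos)))
        if i == len(clusters) - 1:
            want = min(want, len(shuffled) - start)
        test_neg = shuffled[start : start + want]
        start += len(test_neg)
        test = frozenset(test_pos) | frozenset(test_neg)
        folds.append(
            CvFold(held_out_cluster=cluster, train=frozenset(all_ids - test), test=test)
        )
    return folds


def compare_first_last(
    folds: list[CvFold],
    dataset: "RetrospectiveDataset",
    pipeline,
    p_value: float = 0.01,
    n_tests: int = 1,
    null_reps: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """First-step vs last-step generalization comparison across CV folds.

    For each fold, ``pipeline.search(train_dataset, seed)`` runs the beam
    search and must return ``(ranked, history)``; the best model of step 0
    and the best overall are then scored on the fold's test set with
    ``pipeline.evaluate(parameterization, test_dataset, seed)``.  Each
    test enrichment is flagged significant against the empirical null
    conditioned on that fold's *test* positive count (significance depends
    on the number of positives) at the Bonferroni-corrected level
    ``p_value / n_tests``.

    Returns one row per fold: cluster id, n_test_pos, first/last
    enrichment, threshold, significance flags.
    """
    if len(folds) < 2:
        raise ValueError("need >= 2 folds for a first-vs-last comparison")
    rows = []
    for k, fold in enumerate(folds):
        train_ds = dataset.subset(set(fold.train))
        test_ds = dataset.subset(set(fold.test))
        n_test_pos = len(test_ds.positives)
        fold_seed = (seed * 100003 + k) % 2**31

        ranked, history = pipeline.search(train_ds, fold_seed)
        first_records = [r for r in history if r.step == 0 and r.ok]
        first_best = max(first_records, key=lambda r: (r.value, r.parameterization.id))
        last_best_param = ranked[0][0]

        first_enrich = pipeline.evaluate(first_best.parameterization, test_ds, fold_seed)
        last_enrich = pipeline.evaluate(last_best_param, test_ds, fold_seed)

        ratio = len(test_ds.negatives) / max(1, n_test_pos)
        null = simulate_null(n_pos=n_test_pos, ratio=ratio, reps=null_reps, seed=fold_seed)
        threshold = significance_threshold(
            null, SignificanceConfig(p_value=p_value, n_tests=n_tests)
        )
        rows.append(
            {
                "cluster": fold.held_out_cluster,
                "n_test_pos": n_test_pos,
                "first_enrichment": first_enrich,
                "last_enrichment": last_enrich,
                "threshold": threshold,
                "first_significant": first_enrich >= threshold,
                "last_significant": last_enrich >= threshold,
            }
        )
    return pd.DataFrame(rows)
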