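"""Fisher-score feature ranking and the two source-selection comparison protocols.

The Fisher score of feature i over classes j = 1..l is

    FS(f_i) = sum_j n_j (mu_ij - mu_i)^2 / sum_j n_j s_ij^2

with class sizes n_j, class means mu_ij, overall mean mu_i and class
variances s_ij^2 (population convention, ddof=0).  Features are eliminated
from least to most relevant; a source "survives" a sweep if it keeps at
least one feature at the best-performing count.

Two protocols compare this per-feature baseline with kernel-weight source
selection:

* feature-selection-then-source-survival: Fisher sweep over the concatenated
  table, then see which sources survive;
* selection-then-feature-reduction: MKL source selection first, then a
  Fisher sweep restricted to the selected sources' features (sources fixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GroupMap, MultiSourceDataset, SplitSpec, split_dataset, standardize
from .exceptions import LabelError
from .metrics import PerformanceReport, reduction_rate
from .mkl import MKLConfig, MKLSourceSelection
from .selection import elimination_curve, select_minimal

__all__ = [
    "FisherRanking",
    "fisher_scores",
    "fisher_eliminate",
    "FisherSweep",
    "make_svm_evaluator",
    "select_then_reduce",
]


@dataclass
class FisherRanking:
    """Per-feature Fisher scores and the most-to-least-relevant ordering."""

    scores: np.ndarray
    order: np.ndarray  # feature indices, most relevant first
    group_map: GroupMap | None = None


def fisher_scores(X, y, group_map: GroupMap | None = None) -> FisherRanking:
    """Fisher score per feature column of a (concatenated) table.

    Zero within-class variance with a positive between-class numerator gives
    an infinite score (such features rank above all finite ones, ties by
    column order); an all-constant feature scores 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise LabelError("Fisher score needs at least two classes")
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        xc = X[y == c]
        nj = xc.shape[0]
        num += nj * (xc.mean(axis=0) - mu) ** 2
        den += nj * xc.var(axis=0)  # population variance (ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                          np.where(num > 0, np.inf, 0.0))
    order = np.argsort(-scores, kind="stable")  # stable: ties by column order
    return FisherRanking(scores=scores, order=order, group_map=group_map)


@dataclass
class FisherSweep:
    """Result of a least-relevant-first feature elimination sweep."""

    reports: list[PerformanceReport]  # index k -> keeping order[: D - k] ... stored per count
    counts: list[int]
    best_count: int
    best_report: PerformanceReport
    kept_features: np.ndarray
    surviving_sources: list[str]
    source_reduction: float


def fisher_eliminate(ranking: FisherRanking, evaluator) -> FisherSweep:
    """Sweep retained-feature counts from all features down to 1.

    ``evaluator(feature_indices) -> PerformanceReport`` scores a candidate
    subset.  The chosen count maximizes accuracy (ties -> fewest features);
    the chosen subset is always a prefix of the ranking.  Source survival
    and the source-level reduction rate are derived from the group map when
    one is attached.
    """
    D = ranking.order.size
    counts, reports = [], []
    best_count, best_report = D, None
    for k in range(D, 0, -1):
        rep = evaluator(ranking.order[:k])
        counts.append(k)
        reports.append(rep)
        # iterating D -> 1, ">=" keeps the smallest count among accuracy ties
        if best_report is None or rep.accuracy >= best_report.accuracy - 1e-12:
            best_count, best_report = k, rep
    kept = np.sort(ranking.order[:best_count])

    surviving, src_reduction = [], 0.0
    if ranking.group_map is not None:
        gm = ranking.group_map
        kept_set = set(kept.tolist())
        for name in gm.source_order:
            if kept_set & set(gm.columns_for(name).tolist()):
                surviving.append(name)
        src_reduction = reduction_rate(len(surviving), len(gm.source_order))
    return FisherSweep(
        reports=reports,
        counts=counts,
        best_count=best_count,
        best_report=best_report,
        kept_features=kept,
        surviving_sources=surviving,
        source_reduction=src_reduction,
    )


def make_svm_evaluator(
    X_train, y_train, X_test, y_test, cfg: MKLConfig | None = None
):
    """Evaluator closure: a single-kernel locally-scaled Gaussian SVM (the
    P=1 case of the MKL core) trained on a feature subset and scored on the
    held-out samples."""
    cfg = cfg or MKLConfig()
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)

    def evaluate(feature_idx) -> PerformanceReport:
        idx = np.asarray(feature_idx, dtype=int)
        tr = MultiSourceDataset([X_train[:, idx]], ["features"], y_train)
        te = MultiSourceDataset([X_test[:, idx]], ["features"], y_test)
        res = MKLSourceSelection(tr, cfg).fit()
        return res.score_report(te)

    return evaluate


def select_then_reduce(
    ds: MultiSourceDataset,
    mkl_cfg: MKLConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> dict:
    """Source selection first, then Fisher feature reduction within the kept
    sources (the sources themselves are not re-eliminated in stage 2).

    Returns a dict with the selected sources, source- and feature-level
    reduction rates and the stage reports.
    """
    mkl_cfg = mkl_cfg or MKLConfig()
    split_spec = split_spec or SplitSpec(seed=mkl_cfg.seed)
    train, test = split_dataset(ds, split_spec)
    train, (test,) = standardize(train, [test])

    results = MKLSourceSelection(train, mkl_cfg).fit()
    curve = elimination_curve(results, train, test, mode="reweight")
    n_star, kept_sources, source_report = select_minimal(curve)

    sub_train = train.select_sources(kept_sources)
    sub_test = test.select_sources(kept_sources)
    Xtr, gm = sub_train.concatenated()
    Xte, _ = sub_test.concatenated()
    ranking = fisher_scores(Xtr, sub_train.labels, group_map=gm)
    sweep = fisher_eliminate(
        ranking,
        make_svm_evaluator(Xtr, sub_train.labels, Xte, sub_test.labels, mkl_cfg),
    )
    return {
        "selected_sources": kept_sources,
        "source_reduction_rate": reduction_rate(len(kept_sources), ds.n_sources),
        "source_stage_report": source_report,
        "n_features_total": Xtr.shape[1],
        "n_features_kept": int(sweep.best_count),
        "feature_reduction_rate": reduction_rate(sweep.best_count, Xtr.shape[1]),
        "final_report": sweep.best_report,
        "sweep": sweep,
    }
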