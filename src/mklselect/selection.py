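"""Source ranking, sequential elimination curves and relevance aggregation.

The trained kernel weights eta order the sources by relevance.  Sources are
then dropped from least to most relevant; performance at every subset size,
together with the reduction rate, locates the minimal subset that preserves
(or improves) accuracy.  Across repeated runs the eta vectors are aggregated
into a single relevance table weighted by each run's accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultiSourceDataset
from .exceptions import ConfigError, ParameterError
from .metrics import PerformanceReport, reduction_rate, score
from .mkl import MKLResults, MKLSourceSelection

__all__ = [
    "CurvePoint",
    "EliminationCurve",
    "RelevanceTable",
    "rank_sources",
    "elimination_curve",
    "select_minimal",
    "aggregate_relevance",
]


def rank_sources(results: MKLResults) -> list[str]:
    """Source names by descending eta; ties keep the original source order."""
    order = np.argsort(-results.eta, kind="stable")
    return [results.source_names[i] for i in order]


@dataclass
class CurvePoint:
    n_sources: int
    sources: list[str]
    report: PerformanceReport
    reduction: float


@dataclass
class EliminationCurve:
    """Performance at every retained-subset size, n = P down to 1."""

    ranking: list[str]
    points: list[CurvePoint]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = {"n_sources": pt.n_sources, "sources": "|".join(pt.sources),
                   "reduction_rate": pt.reduction}
            row.update(pt.report.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def plot(self, ax=None, label=None):
        """Accuracy vs number of retained sources (most relevant kept first)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = [pt.n_sources for pt in self.points]
        acc = [pt.report.accuracy for pt in self.points]
        ax.plot(n, acc, marker="o", label=label or self.mode)
        ax.set_xlabel("number of information sources kept")
        ax.set_ylabel("accuracy (%)")
        ax.invert_xaxis()
        return ax


def _renormalize(eta_sub: np.ndarray, p: float) -> np.ndarray:
    nrm = float(np.sum(np.abs(eta_sub) ** p)) ** (1.0 / p)
    if nrm == 0:
        # all retained weights zero: fall back to uniform over the subset
        return np.full(eta_sub.size, eta_sub.size ** (-1.0 / p))
    return eta_sub / nrm


def elimination_curve(
    results: MKLResults,
    train_ds: MultiSourceDataset,
    test_ds: MultiSourceDataset,
    mode: str = "reweight",
) -> EliminationCurve:
    """Drop sources from least to most relevant, scoring at every size.

    mode="reweight" (default) renormalizes the retained eta onto the model's
    lp ball and re-predicts with the stored alpha and b — prediction-stage
    reduction with the already-trained global model.  mode="retrain" refits
    the full MKL on each retained subset.
    """
    if mode not in ("reweight", "retrain"):
        raise ConfigError(f"unknown curve mode {mode!r}")
    names = results.source_names
    order = np.argsort(-results.eta, kind="stable")
    P = len(names)
    points = []
    for n in range(P, 0, -1):
        kept_idx = sorted(order[:n])  # manifest order within the subset
        kept_names = [names[i] for i in kept_idx]
        if mode == "reweight":
            eta_sub = _renormalize(results.eta[kept_idx], results.config.p)
            pred = results.predict(
                test_ds, source_subset=kept_idx, eta_override=eta_sub
            )
            report = score(test_ds.labels, pred)
        else:
            sub_train = train_ds.select_sources(kept_names)
            sub_test = test_ds.select_sources(kept_names)
            sub_res = MKLSourceSelection(sub_train, results.config).fit()
            report = sub_res.score_report(sub_test)
        points.append(
            CurvePoint(
                n_sources=n,
                sources=kept_names,
                report=report,
                reduction=reduction_rate(n, P),
            )
        )
    return EliminationCurve(ranking=rank_sources(results), points=points, mode=mode)


def select_minimal(curve: EliminationCurve):
    """Smallest subset size whose accuracy attains the curve maximum."""
    if not curve.points:
        raise ParameterError("empty elimination curve")
    best_acc = max(pt.report.accuracy for pt in curve.points)
    candidates = [pt for pt in curve.points if pt.report.accuracy >= best_acc - 1e-12]
    pt = min(candidates, key=lambda q: q.n_sources)
    return pt.n_sources, pt.sources, pt.report


@dataclass
class RelevanceTable:
    """Accuracy-weighted aggregate relevance, normalized to sum 100."""

    scores: pd.Series
    runs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.scores.sort_values(ascending=False).to_frame("relevance")


def aggregate_relevance(runs) -> RelevanceTable:
    """Aggregate (eta, accuracy) pairs: score_m ∝ sum_runs acc * eta_m.

    ``runs`` is a list of (eta, accuracy) where eta is a pandas Series
    indexed by source name (or an array sharing one implicit order) and
    accuracy is in (0, 100].
    """
    if not runs:
        raise ParameterError("need at least one run")
    etas, accs = [], []
    index = None
    for eta, acc in runs:
        if not 0 < acc <= 100:
            raise ParameterError(f"accuracy must lie in (0,100], got {acc}")
        if isinstance(eta, pd.Series):
            index = eta.index if index is None else index
            etas.append(eta.reindex(index).to_numpy(dtype=float))
        else:
            etas.append(np.asarray(eta, dtype=float))
        accs.append(float(acc))
    mat = np.vstack(etas)
    raw = (np.asarray(accs)[:, None] * mat).sum(axis=0)
    if raw.sum() <= 0:
        raise ParameterError("aggregate relevance is all zero")
    scores = 100.0 * raw / raw.sum()
    if index is None:
        index = pd.RangeIndex(mat.shape[1])
    return RelevanceTable(scores=pd.Series(scores, index=index, name="relevance"),
                          runs=list(runs))
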