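"""lp-penalized multiple-kernel-learning SVM with locally-scaled Gaussian kernels.

The model assigns one locally-scaled Gaussian kernel K_m to each information
source and learns a classifier on the weighted sum

    K_eta(x_i, x_j) = sum_m eta_m K_m(x_i^m, x_j^m),

with the kernel weights eta constrained to the unit lp ball (the simplex for
p=1, which drives irrelevant sources' weights to zero).  Training alternates
(a) an SVM dual solve on the current combined Gram — delegated to libsvm's
SMO via scikit-learn's precomputed-kernel ``SVC`` — and (b) the closed-form
weight update

    eta_m  proportional to  ||w_m||^(2/(p+1)),      ||w_m||^2 = eta_m^2 *
            sum_ij alpha_i alpha_j y_i y_j K_m(x_i^m, x_j^m),

normalized so ||eta||_p = 1, until eta stops moving.  The trained eta ranks
the sources by relevance; alpha, b and the per-sample bandwidths support
prediction under one of the three test-bandwidth assignment algorithms.

Organized statsmodels-style: :class:`MKLSourceSelection` is the model bound
to a dataset + config; ``fit()`` returns :class:`MKLResults` carrying the
estimates, diagnostics, ``summary()``, prediction and serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import json

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import local_scaling as ls
from .data import MultiSourceDataset
from .exceptions import (
    ConfigError,
    DegenerateModelError,
    LabelError,
    ParameterError,
    StructuralError,
)
from .metrics import PerformanceReport, score

__all__ = [
    "MKLConfig",
    "MKLSourceSelection",
    "MKLResults",
    "combine_kernels",
    "compute_wm_norms",
    "update_eta",
]

_FORMAT_VERSION = 1
_SV_THRESHOLD = 1e-8  # numerical-zero cut for alpha


@dataclass
class MKLConfig:
    """Hyperparameters of the MKL-SVM.

    C : SVM regularization (> 0).
    p : norm order of the eta penalty; 1 (sparse simplex) or 2 in practice,
        any p >= 1 accepted.
    tau : SMO stopping tolerance passed to the inner solver.
    K : local-scaling neighbour index (1 <= K < N_train).
    algorithm_id : test-bandwidth assignment strategy (1, 2 or 3).
    max_outer_iters / eta_tol : outer-loop convergence control.
    """

    C: float = 1.0
    p: float = 1.0
    tau: float = 1e-3
    K: int = 7
    algorithm_id: int = 1
    max_outer_iters: int = 100
    eta_tol: float = 1e-4
    floor: float = ls.DEFAULT_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError("C must be positive")
        if self.p < 1:
            raise ConfigError("p must be >= 1")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.algorithm_id not in (1, 2, 3):
            raise ConfigError("algorithm_id must be 1, 2 or 3")
        if self.max_outer_iters < 1:
            raise ConfigError("max_outer_iters must be >= 1")


# ---------------------------------------------------------------------------
# kernel-weight algebra
# ---------------------------------------------------------------------------

def combine_kernels(gram_stack, eta) -> np.ndarray:
    """Weighted sum of Gram matrices: K_eta = sum_m eta_m K_m."""
    eta = np.asarray(eta, dtype=float).ravel()
    grams = [np.asarray(g, dtype=float) for g in gram_stack]
    if len(grams) != eta.size:
        raise StructuralError("eta length does not match number of Grams")
    shape = grams[0].shape
    if any(g.shape != shape for g in grams):
        raise StructuralError("Gram matrices differ in shape")
    out = np.zeros(shape)
    for w, g in zip(eta, grams):
        out += w * g
    return out


def compute_wm_norms(eta, alpha, labels, gram_stack) -> np.ndarray:
    """Per-source squared block norms ||w_m||^2 = eta_m^2 * (ay)' K_m (ay).

    Tiny negatives that spectral clipping can introduce are set to zero.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    ay = np.asarray(alpha, dtype=float).ravel() * np.asarray(labels, dtype=float).ravel()
    out = np.empty(eta.size)
    for m, g in enumerate(gram_stack):
        out[m] = eta[m] ** 2 * float(ay @ np.asarray(g, dtype=float) @ ay)
    return np.clip(out, 0.0, None)


def update_eta(wm_norms, p: float) -> np.ndarray:
    """Closed-form lp weight update, normalized so ||eta||_p = 1.

    eta_m  proportional to  ||w_m||_2^(2/(p+1));  for p=1 this reduces to
    eta_m = ||w_m|| / sum_h ||w_h|| (the simplex condition holds exactly).
    Sources with a zero block norm get eta_m = 0.
    """
    wm2 = np.asarray(wm_norms, dtype=float).ravel()
    if np.any(wm2 < 0):
        raise ParameterError("||w_m||^2 must be non-negative")
    if not np.any(wm2 > 0):
        raise DegenerateModelError("all block norms are zero; cannot update eta")
    wm = np.sqrt(wm2)  # ||w_m||_2
    num = wm ** (2.0 / (p + 1.0))
    denom = float(np.sum(wm ** (2.0 * p / (p + 1.0)))) ** (1.0 / p)
    return num / denom


def _normalize_lp(v: np.ndarray, p: float) -> np.ndarray:
    nrm = float(np.sum(np.abs(v) ** p)) ** (1.0 / p)
    return v / nrm


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MKLSourceSelection:
    """MKL-SVM source-selection model bound to a training dataset.

    Parameters
    ----------
    dataset : MultiSourceDataset
        Training data (standardize beforehand if desired; Gaussian kernels
        are scale-sensitive).
    config : MKLConfig, optional

    ``fit()`` returns an :class:`MKLResults` instance.
    """

    def __init__(self, dataset: MultiSourceDataset, config: MKLConfig | None = None):
        self.dataset = dataset
        self.config = config or MKLConfig()
        if len(np.unique(dataset.labels)) < 2:
            raise LabelError("training labels contain a single class")
        if self.config.K >= dataset.n_samples:
            raise ParameterError(
                f"K={self.config.K} must be < N_train={dataset.n_samples}"
            )

    @classmethod
    def from_manifest(cls, manifest_path, config: MKLConfig | None = None):
        from .data import load_dataset

        return cls(load_dataset(manifest_path), config)

    # -- internals --------------------------------------------------------
    def _source_grams(self):
        cfg = self.config
        sigmas = [
            ls.compute_local_sigmas(x, cfg.K, cfg.floor) for x in self.dataset.sources
        ]
        grams = [
            ls.local_gaussian_gram(x, x, s, s)
            for x, s in zip(self.dataset.sources, sigmas)
        ]
        return sigmas, grams

    def _solve_svm(self, K_combined, y):
        cfg = self.config
        svc = SVC(C=cfg.C, kernel="precomputed", tol=cfg.tau)
        svc.fit(K_combined, y)
        alpha = np.zeros(len(y))
        alpha[svc.support_] = np.abs(svc.dual_coef_[0])
        return alpha, float(svc.intercept_[0])

    def fit(self) -> "MKLResults":
        """Alternate SVM solves and eta updates until eta stabilizes."""
        cfg = self.config
        ds = self.dataset
        y = ds.labels.astype(float)
        sigmas, grams = self._source_grams()
        P = ds.n_sources

        eta = _normalize_lp(np.ones(P), cfg.p)
        eta_history = [eta.copy()]
        n_iter, converged = 0, False
        alpha = np.zeros(ds.n_samples)
        bias = 0.0
        for n_iter in range(1, cfg.max_outer_iters + 1):
            K_comb = ls.clip_psd(combine_kernels(grams, eta))
            alpha, bias = self._solve_svm(K_comb, y)
            wm2 = compute_wm_norms(eta, alpha, y, grams)
            new_eta = update_eta(wm2, cfg.p)
            delta = float(np.max(np.abs(new_eta - eta)))
            eta = new_eta
            eta_history.append(eta.copy())
            if delta <= cfg.eta_tol:
                converged = True
                break
        # final solve so (alpha, b) are consistent with the converged eta
        K_comb = ls.clip_psd(combine_kernels(grams, eta))
        alpha, bias = self._solve_svm(K_comb, y)

        sv = np.flatnonzero(alpha > _SV_THRESHOLD)
        if sv.size == 0:
            raise DegenerateModelError("no support vectors after training")

        # per-source state needed at prediction time
        if cfg.algorithm_id == 1:
            stored_blocks = [x.copy() for x in ds.sources]
            stored_sigmas = [s.copy() for s in sigmas]
            stored_alpha, stored_y = alpha.copy(), y.copy()
            mean_sigmas = None
        else:
            stored_blocks = [x[sv] for x in ds.sources]
            stored_sigmas = [s[sv] for s in sigmas]
            stored_alpha, stored_y = alpha[sv], y[sv]
            mean_sigmas = None
            if cfg.algorithm_id == 3:
                mean_sigmas = [
                    ls.compute_mean_sv_sigmas(x, s, sv)
                    for x, s in zip(ds.sources, sigmas)
                ]

        return MKLResults(
            config=replace(cfg),
            source_names=list(ds.source_names),
            n_features=ds.n_features,
            eta=eta,
            alpha=alpha,
            bias=bias,
            sv_indices=sv,
            labels=y,
            stored_blocks=stored_blocks,
            stored_sigmas=stored_sigmas,
            stored_mean_sigmas=mean_sigmas,
            stored_alpha=stored_alpha,
            stored_labels=stored_y,
            n_iter=n_iter,
            converged=converged,
            eta_history=np.vstack(eta_history),
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class MKLResults:
    """Trained MKL-SVM: estimates, diagnostics, prediction, serialization.

    Attributes
    ----------
    eta : (P,) kernel weights on the unit lp ball — the source relevances.
    alpha, bias : SVM dual coefficients (length N_train) and intercept.
    sv_indices : training indices with alpha > 1e-8.
    stored_* : the per-source blocks/bandwidths the configured prediction
        algorithm needs (full training set for algorithm 1, support vectors
        only for 2 and 3).
    """

    def __init__(
        self,
        config: MKLConfig,
        source_names,
        n_features,
        eta,
        alpha,
        bias,
        sv_indices,
        labels,
        stored_blocks,
        stored_sigmas,
        stored_mean_sigmas,
        stored_alpha,
        stored_labels,
        n_iter,
        converged,
        eta_history,
    ):
        self.config = config
        self.source_names = list(source_names)
        self.n_features = tuple(n_features)
        self.eta = np.asarray(eta, dtype=float)
        self.alpha = np.asarray(alpha, dtype=float)
        self.bias = float(bias)
        self.sv_indices = np.asarray(sv_indices, dtype=int)
        self.labels = np.asarray(labels, dtype=float)
        self.stored_blocks = [np.asarray(b, dtype=float) for b in stored_blocks]
        self.stored_sigmas = [np.asarray(s, dtype=float) for s in stored_sigmas]
        self.stored_mean_sigmas = (
            None
            if stored_mean_sigmas is None
            else [np.asarray(s, dtype=float) for s in stored_mean_sigmas]
        )
        self.stored_alpha = np.asarray(stored_alpha, dtype=float)
        self.stored_labels = np.asarray(stored_labels, dtype=float)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.eta_history = np.asarray(eta_history, dtype=float)

    # -- presentation -----------------------------------------------------
    @property
    def eta_series(self) -> pd.Series:
        """Kernel weights indexed by source name (eta below 1e-8 shown as 0)."""
        eta = np.where(self.eta < 1e-8, 0.0, self.eta)
        return pd.Series(eta, index=self.source_names, name="eta")

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "MKL-SVM source selection results",
            "=" * 44,
            f"sources: P={len(self.source_names)}   "
            f"train samples: N={self.alpha.size}",
            f"penalty: l{cfg.p:g}   C={cfg.C:g}   K={cfg.K}   tau={cfg.tau:g}   "
            f"prediction algorithm: {cfg.algorithm_id}",
            f"outer iterations: {self.n_iter}"
            f" ({'converged' if self.converged else 'not converged'})   "
            f"support vectors: {self.sv_indices.size}",
            "-" * 44,
            "kernel weights (source relevance, descending):",
        ]
        order = np.argsort(-self.eta, kind="stable")
        for i in order:
            lines.append(f"  {self.source_names[i]:<16s} eta = {self.eta[i]:.6f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    # -- prediction -------------------------------------------------------
    def _check_test(self, test_ds: MultiSourceDataset) -> None:
        if list(test_ds.source_names) != self.source_names:
            raise StructuralError("test sources do not match training sources")
        if test_ds.n_features != self.n_features:
            raise StructuralError("test feature counts do not match training")

    def _test_sigmas(self, m: int, Xt: np.ndarray) -> np.ndarray:
        cfg = self.config
        if cfg.algorithm_id == 1:
            return ls.assign_sigmas_alg1(
                self.stored_blocks[m], Xt, cfg.K, cfg.floor
            )
        if cfg.algorithm_id == 2:
            return ls.assign_sigmas_alg2(
                self.stored_blocks[m], self.stored_sigmas[m], Xt
            )
        return ls.assign_sigmas_alg3(
            self.stored_blocks[m], self.stored_mean_sigmas[m], Xt
        )

    def decision_function(
        self, test_ds: MultiSourceDataset, source_subset=None, eta_override=None
    ) -> np.ndarray:
        """Signed distance f(x) = sum_i alpha_i y_i K_eta(x_i, x) + b.

        ``source_subset`` (indices into the source list) and ``eta_override``
        support elimination curves: scoring with a retained subset whose
        weights were renormalized, while keeping the stored alpha and b.
        """
        self._check_test(test_ds)
        subset = (
            range(len(self.source_names)) if source_subset is None else source_subset
        )
        eta = self.eta if eta_override is None else np.asarray(eta_override, float)
        ay = self.stored_alpha * self.stored_labels
        f = np.full(test_ds.n_samples, self.bias)
        for k, m in enumerate(subset):
            w = eta[m] if eta_override is None else eta[k]
            if w == 0.0:
                continue
            Xt = test_ds.sources[m]
            st = self._test_sigmas(m, Xt)
            g = ls.local_gaussian_gram(
                self.stored_blocks[m], Xt, self.stored_sigmas[m], st
            )
            f += w * (ay @ g)
        return f

    def predict(self, test_ds: MultiSourceDataset, **kw) -> np.ndarray:
        """Labels in {-1,+1}; a score of exactly 0 maps to +1."""
        f = self.decision_function(test_ds, **kw)
        return np.where(f >= 0, 1, -1)

    def score_report(self, test_ds: MultiSourceDataset, **kw) -> PerformanceReport:
        return score(test_ds.labels, self.predict(test_ds, **kw))

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Single-file archive (.npz) with a format-version tag."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "config": asdict(self.config),
            "source_names": self.source_names,
            "n_features": list(self.n_features),
            "has_mean_sigmas": self.stored_mean_sigmas is not None,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        arrays = {
            "eta": self.eta,
            "alpha": self.alpha,
            "bias": np.array([self.bias]),
            "sv_indices": self.sv_indices,
            "labels": self.labels,
            "stored_alpha": self.stored_alpha,
            "stored_labels": self.stored_labels,
            "eta_history": self.eta_history,
        }
        for m in range(len(self.source_names)):
            arrays[f"block_{m}"] = self.stored_blocks[m]
            arrays[f"sigma_{m}"] = self.stored_sigmas[m]
            if self.stored_mean_sigmas is not None:
                arrays[f"mean_sigma_{m}"] = self.stored_mean_sigmas[m]
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MKLResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["format_version"] != _FORMAT_VERSION:
                raise StructuralError(
                    f"unsupported model format {meta['format_version']}"
                )
            P = len(meta["source_names"])
            mean_sigmas = (
                [z[f"mean_sigma_{m}"] for m in range(P)]
                if meta["has_mean_sigmas"]
                else None
            )
            return cls(
                config=MKLConfig(**meta["config"]),
                source_names=meta["source_names"],
                n_features=meta["n_features"],
                eta=z["eta"],
                alpha=z["alpha"],
                bias=float(z["bias"][0]),
                sv_indices=z["sv_indices"],
                labels=z["labels"],
                stored_blocks=[z[f"block_{m}"] for m in range(P)],
                stored_sigmas=[z[f"sigma_{m}"] for m in range(P)],
                stored_mean_sigmas=mean_sigmas,
                stored_alpha=z["stored_alpha"],
                stored_labels=z["stored_labels"],
                n_iter=meta["n_iter"],
                converged=meta["converged"],
                eta_history=z["eta_history"],
            )
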