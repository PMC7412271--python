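"""Particle-swarm hyperparameter tuning against a cross-validated geo-mean.

The tunable parameters are the SVM regularization C, the local-scaling
neighbour index K (integer) and the SMO tolerance tau.  The objective is the
mean geometric mean of sensitivity and specificity over a stratified K-fold
cross-validation (10 folds by default) — a measure robust to class
imbalance.  The optimizer is a global-best PSO with 40 particles, cognitive
and social coefficients 1.1931, and inertia decreasing linearly from 1.1 to
0.1 over 60 iterations; the direction of the inertia schedule is a
convention choice and is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import MultiSourceDataset, standardize
from .exceptions import ConfigError, SplitError
from .mkl import MKLConfig, MKLSourceSelection

__all__ = ["ParamBound", "PSOConfig", "TuningResult", "cv_geo_mean",
           "pso_optimize", "tune_mkl"]

logger = logging.getLogger(__name__)


@dataclass
class ParamBound:
    """Box bound for one search dimension; integers are rounded at evaluation."""

    name: str
    lo: float
    hi: float
    integer: bool = False
    log10: bool = False  # position searched in log10 space, decoded before use

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ConfigError(f"bound for {self.name!r} is not well-ordered")

    def decode(self, x: float) -> float:
        v = 10.0 ** x if self.log10 else x
        return int(round(v)) if self.integer else v


@dataclass
class PSOConfig:
    """Global-best PSO settings."""

    n_particles: int = 40
    cognitive: float = 1.1931
    social: float = 1.1931
    inertia_start: float = 1.1
    inertia_end: float = 0.1
    max_iters: int = 60
    seed: int = 0
    bounds: list[ParamBound] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ConfigError("n_particles must be >= 2")
        for v in (self.inertia_start, self.inertia_end):
            if not 0.1 - 1e-12 <= v <= 1.1 + 1e-12:
                raise ConfigError("inertia values must lie within [0.1, 1.1]")
        if self.max_iters < 1:
            raise ConfigError("max_iters must be >= 1")


@dataclass
class TuningResult:
    best_params: dict
    best_objective: float
    trajectory: np.ndarray  # per-iteration global best (non-decreasing)


def cv_geo_mean(
    ds: MultiSourceDataset, cfg: MKLConfig, folds: int = 10, seed: int = 0
) -> float:
    """Mean geo-mean (%) over a stratified K-fold cross-validation.

    Each fold-complement is standardized by its own statistics, the model
    fitted on it, and the held-out fold scored with the identical transform.
    """
    y = ds.labels
    counts = np.bincount((y > 0).astype(int), minlength=2)
    if folds < 2:
        raise SplitError("folds must be >= 2")
    if counts.min() < folds:
        raise SplitError(
            f"each class needs >= {folds} samples for {folds}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gms = []
    for train_idx, test_idx in skf.split(np.zeros((len(y), 1)), y):
        tr, te = ds.subset(train_idx), ds.subset(test_idx)
        tr, (te,) = standardize(tr, [te])
        res = MKLSourceSelection(tr, cfg).fit()
        gms.append(res.score_report(te).geo_mean)
    return float(np.mean(gms))


def pso_optimize(objective, pso_cfg: PSOConfig) -> TuningResult:
    """Maximize ``objective`` (called with a decoded parameter list) by PSO.

    Positions are clamped to the box, velocities to half the box width.
    Non-finite objective values are treated as -inf and logged.  Fully
    deterministic under ``pso_cfg.seed``.
    """
    bounds = pso_cfg.bounds
    if not bounds:
        raise ConfigError("PSO needs at least one parameter bound")
    rng = np.random.default_rng(pso_cfg.seed)
    dim = len(bounds)
    lo = np.array([b.lo for b in bounds])
    hi = np.array([b.hi for b in bounds])
    span = hi - lo
    vmax = np.where(span > 0, span / 2.0, 1.0)

    def evaluate(x) -> float:
        val = objective([b.decode(v) for b, v in zip(bounds, x)])
        if not np.isfinite(val):
            logger.warning("non-finite objective at %s; treating as -inf", x)
            return -np.inf
        return float(val)

    pos = lo + rng.random((pso_cfg.n_particles, dim)) * span
    vel = np.zeros_like(pos)
    pbest_pos = pos.copy()
    pbest_val = np.array([evaluate(x) for x in pos])
    g = int(np.argmax(pbest_val))
    gbest_pos, gbest_val = pbest_pos[g].copy(), float(pbest_val[g])

    trajectory = []
    denom = max(pso_cfg.max_iters - 1, 1)
    for it in range(pso_cfg.max_iters):
        w = pso_cfg.inertia_start + (
            pso_cfg.inertia_end - pso_cfg.inertia_start
        ) * it / denom
        r1 = rng.random((pso_cfg.n_particles, dim))
        r2 = rng.random((pso_cfg.n_particles, dim))
        vel = (
            w * vel
            + pso_cfg.cognitive * r1 * (pbest_pos - pos)
            + pso_cfg.social * r2 * (gbest_pos - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([evaluate(x) for x in pos])
        improved = vals > pbest_val
        pbest_pos[improved] = pos[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmax(pbest_val))
        if pbest_val[g] > gbest_val:
            gbest_val = float(pbest_val[g])
            gbest_pos = pbest_pos[g].copy()
        trajectory.append(gbest_val)

    best = {b.name: b.decode(v) for b, v in zip(bounds, gbest_pos)}
    return TuningResult(
        best_params=best,
        best_objective=gbest_val,
        trajectory=np.asarray(trajectory),
    )


def default_bounds(n_train_fold: int) -> list[ParamBound]:
    """Search box: C in [1e-2, 1e3] and tau in [1e-6, 1e-1] (log-scaled),
    K integer in {1, ..., min(20, n_train_fold - 1)}."""
    k_hi = max(1, min(20, n_train_fold - 1))
    return [
        ParamBound("C", -2.0, 3.0, log10=True),
        ParamBound("K", 1.0, float(k_hi), integer=True),
        ParamBound("tau", -6.0, -1.0, log10=True),
    ]


def tune_mkl(
    ds: MultiSourceDataset,
    base_cfg: MKLConfig | None = None,
    pso_cfg: PSOConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[TuningResult, MKLConfig]:
    """PSO-tune (C, K, tau) by cross-validated geo-mean; returns the result
    and an MKLConfig ready for final training on the full training data."""
    base_cfg = base_cfg or MKLConfig()
    n_fold_train = ds.n_samples - int(np.ceil(ds.n_samples / folds))
    if pso_cfg is None:
        pso_cfg = PSOConfig(seed=seed, bounds=default_bounds(n_fold_train))
    elif not pso_cfg.bounds:
        pso_cfg = replace(pso_cfg, bounds=default_bounds(n_fold_train))

    names = [b.name for b in pso_cfg.bounds]

    def objective(params):
        kw = dict(zip(names, params))
        cfg = replace(base_cfg, **kw)
        try:
            return cv_geo_mean(ds, cfg, folds=folds, seed=seed)
        except Exception as exc:  # infeasible point (e.g. K >= fold size)
            logger.warning("objective failed at %s: %s", kw, exc)
            return -np.inf

    result = pso_optimize(objective, pso_cfg)
    tuned = replace(base_cfg, **result.best_params)
    return result, tuned
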