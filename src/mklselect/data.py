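"""Multi-source dataset container, manifest I/O, splitting and standardization.

A dataset is a tuple of P feature matrices (one per information source) over a
shared set of N samples, plus a binary label vector in {-1, +1}.  Sources may
have different feature counts; sample order is the alignment key across
sources.  Matrices travel as delimited text referenced from a small YAML
manifest, or as one concatenated table plus a column->source group map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit

from .exceptions import LabelError, SplitError, StateError, StructuralError

__all__ = [
    "MultiSourceDataset",
    "GroupMap",
    "SplitSpec",
    "load_dataset",
    "save_dataset",
    "split_dataset",
    "standardize",
    "Standardizer",
]


@dataclass
class MultiSourceDataset:
    """P feature matrices over N shared samples with labels in {-1, +1}.

    Parameters
    ----------
    sources : list of ndarray
        One (N, D_m) float matrix per information source, identical sample
        order across sources.
    source_names : list of str
        Identifier per source, same order as ``sources``.
    labels : ndarray
        Length-N vector with entries in {-1, +1}; both classes present.
    sample_ids : list of str, optional
        Length-N identifiers; synthesized as "s0..s{N-1}" when omitted.
    """

    sources: list[np.ndarray]
    source_names: list[str]
    labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise StructuralError("a dataset needs at least one source")
        if len(self.sources) != len(self.source_names):
            raise StructuralError("source_names length does not match sources")
        if len(set(self.source_names)) != len(self.source_names):
            raise StructuralError("source names must be unique")
        self.sources = [np.asarray(x, dtype=float) for x in self.sources]
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        n = self.sources[0].shape[0]
        for name, x in zip(self.source_names, self.sources):
            if x.ndim != 2 or x.shape[1] < 1:
                raise StructuralError(f"source {name!r} is not a 2-D matrix")
            if x.shape[0] != n:
                raise StructuralError(
                    f"source {name!r} has {x.shape[0]} samples, expected {n}"
                )
            if not np.all(np.isfinite(x)):
                raise StructuralError(f"source {name!r} contains non-finite values")
        if self.labels.shape[0] != n:
            raise LabelError(f"label vector length {self.labels.shape[0]} != N={n}")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise LabelError(f"labels outside {{-1,+1}}: {sorted(bad)}")
        if len(np.unique(self.labels)) < 2:
            raise LabelError("both classes must be present")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise StructuralError("sample_ids length does not match N")

    # -- shape bookkeeping ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.sources[0].shape[0]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_features(self) -> tuple[int, ...]:
        return tuple(x.shape[1] for x in self.sources)

    # -- derived views ----------------------------------------------------
    def subset(self, indices) -> "MultiSourceDataset":
        """Row-subset all sources and labels by integer index array."""
        idx = np.asarray(indices, dtype=int)
        return MultiSourceDataset(
            sources=[x[idx] for x in self.sources],
            source_names=list(self.source_names),
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def select_sources(self, names) -> "MultiSourceDataset":
        """Keep only the named sources, in the order given."""
        pos = {n: i for i, n in enumerate(self.source_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise StructuralError(f"unknown sources: {missing}")
        return MultiSourceDataset(
            sources=[self.sources[pos[n]] for n in names],
            source_names=list(names),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )

    def concatenated(self) -> tuple[np.ndarray, "GroupMap"]:
        """Concatenate all source blocks column-wise; return table + GroupMap."""
        X = np.hstack(self.sources)
        cols: list[str] = []
        for name, x in zip(self.source_names, self.sources):
            cols.extend([name] * x.shape[1])
        return X, GroupMap(assignments=cols, source_order=list(self.source_names))

    @classmethod
    def from_concatenated(
        cls, X, group_map: "GroupMap", labels, sample_ids=None
    ) -> "MultiSourceDataset":
        """Split one feature table back into per-source blocks via a GroupMap."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(group_map.assignments):
            raise StructuralError(
                f"group map covers {len(group_map.assignments)} columns, "
                f"table has {X.shape[1]}"
            )
        blocks = [X[:, group_map.columns_for(name)] for name in group_map.source_order]
        return cls(
            sources=blocks,
            source_names=list(group_map.source_order),
            labels=labels,
            sample_ids=sample_ids,
        )


@dataclass
class GroupMap:
    """Feature-column -> source-name mapping for a concatenated table.

    ``assignments[j]`` names the source owning column j; ``source_order``
    fixes the source ordering (defaults to first appearance).
    """

    assignments: list[str]
    source_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise StructuralError("empty group map")
        seen: list[str] = []
        for name in self.assignments:
            if name not in seen:
                seen.append(name)
        if not self.source_order:
            self.source_order = seen
        if set(self.source_order) != set(seen):
            raise StructuralError("source_order does not match assigned sources")

    def columns_for(self, source: str) -> np.ndarray:
        idx = np.array([j for j, s in enumerate(self.assignments) if s == source])
        if idx.size == 0:
            raise StructuralError(f"source {source!r} receives no columns")
        return idx


@dataclass
class SplitSpec:
    """Hold-out split specification: default 80% train, stratified."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise SplitError(f"train_fraction must be in (0,1), got {self.train_fraction}")


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def load_dataset(manifest_path) -> MultiSourceDataset:
    """Load a dataset from a YAML manifest referencing delimited-text matrices.

    Manifest keys: ``sources`` (list of {name, path}), ``labels`` (path, one
    label per line), optional ``orientation`` ("samples_rows" default or
    "samples_cols"), ``delimiter`` (default ","), ``header`` (default false).
    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    base = manifest_path.parent
    delim = spec.get("delimiter", ",")
    header = bool(spec.get("header", False))
    orientation = spec.get("orientation", "samples_rows")
    if orientation not in ("samples_rows", "samples_cols"):
        raise StructuralError(f"unknown orientation {orientation!r}")

    blocks, names = [], []
    for entry in spec["sources"]:
        name, path = entry["name"], base / entry["path"]
        x = np.loadtxt(path, delimiter=delim, skiprows=1 if header else 0, ndmin=2)
        if orientation == "samples_cols":
            x = x.T
        names.append(name)
        blocks.append(x)
    labels = np.loadtxt(base / spec["labels"], ndmin=1)
    n = blocks[0].shape[0]
    for name, x in zip(names, blocks):
        if x.shape[0] != n:
            raise StructuralError(
                f"source {name!r} has {x.shape[0]} samples, expected {n}"
            )
    return MultiSourceDataset(sources=blocks, source_names=names, labels=labels)


def save_dataset(ds: MultiSourceDataset, out_dir, manifest_name="manifest.yaml") -> Path:
    """Write a dataset as CSV matrices + label file + manifest; returns manifest path.

    Floats are written with 17 significant digits so load(save(ds)) round-trips
    bit-identically for finite inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, x in zip(ds.source_names, ds.sources):
        fname = f"{name}.csv"
        np.savetxt(out / fname, x, delimiter=",", fmt="%.17g")
        entries.append({"name": name, "path": fname})
    np.savetxt(out / "labels.txt", ds.labels, fmt="%d")
    manifest = {
        "sources": entries,
        "labels": "labels.txt",
        "orientation": "samples_rows",
        "delimiter": ",",
        "header": False,
    }
    mpath = out / manifest_name
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    ds: MultiSourceDataset, spec: SplitSpec
) -> tuple[MultiSourceDataset, MultiSourceDataset]:
    """Disjoint, exhaustive train/test partition; stratified by default.

    Deterministic under a fixed ``spec.seed``; indices are re-sorted so the
    original sample order is preserved within each part.
    """
    y = ds.labels
    if spec.stratified:
        counts = np.bincount((y > 0).astype(int), minlength=2)
        if counts.min() < 2:
            raise SplitError("each class needs >= 2 samples for a stratified split")
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=spec.train_fraction, random_state=spec.seed
        )
        train_idx, test_idx = next(splitter.split(np.zeros((len(y), 1)), y))
    else:
        splitter = ShuffleSplit(
            n_splits=1, train_size=spec.train_fraction, random_state=spec.seed
        )
        train_idx, test_idx = next(splitter.split(np.zeros((len(y), 1))))
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class Standardizer:
    """Per-feature z-scoring with training statistics (population std).

    Zero-variance training columns are mapped to all-zeros instead of
    dividing by zero; the identical affine transform is applied to any other
    dataset (leakage-free).  Labels are never touched.
    """

    def __init__(self) -> None:
        self.means_: list[np.ndarray] | None = None
        self.stds_: list[np.ndarray] | None = None
        self.source_names_: list[str] | None = None

    def fit(self, train: MultiSourceDataset) -> "Standardizer":
        self.means_ = [x.mean(axis=0) for x in train.sources]
        self.stds_ = [x.std(axis=0) for x in train.sources]  # ddof=0
        self.source_names_ = list(train.source_names)
        return self

    def transform(self, ds: MultiSourceDataset) -> MultiSourceDataset:
        if self.means_ is None:
            raise StateError("Standardizer used before fit")
        blocks = []
        for x, mu, sd in zip(ds.sources, self.means_, self.stds_):
            safe = np.where(sd > 0, sd, 1.0)
            z = (x - mu) / safe
            z[:, sd == 0] = 0.0
            blocks.append(z)
        return MultiSourceDataset(
            sources=blocks,
            source_names=list(ds.source_names),
            labels=ds.labels.copy(),
            sample_ids=list(ds.sample_ids),
        )


def standardize(
    train: MultiSourceDataset, others: list[MultiSourceDataset] = ()
) -> tuple[MultiSourceDataset, list[MultiSourceDataset]]:
    """Z-score ``train`` by its own statistics and apply the same map to ``others``."""
    sc = Standardizer().fit(train)
    return sc.transform(train), [sc.transform(d) for d in others]
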