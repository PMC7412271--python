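import numpy as np
import pytest

import mklselect as m
from mklselect.exceptions import LabelError, SplitError, StructuralError


def _toy(n=10, d=(3, 5), seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([1, -1] * (n // 2))
    return m.MultiSourceDataset(
        [rng.normal(size=(n, k)) for k in d], [f"s{i}" for i in range(len(d))], labels
    )


class TestContainer:
    def test_shape_bookkeeping(self):
        ds = _toy()
        assert (ds.n_samples, ds.n_sources, ds.n_features) == (10, 2, (3, 5))

    def test_mismatched_sample_count_names_source(self):
        rng = np.random.default_rng(0)
        with pytest.raises(StructuralError, match="s1"):
            m.MultiSourceDataset(
                [rng.normal(size=(10, 3)), rng.normal(size=(9, 5))],
                ["s0", "s1"],
                np.array([1, -1] * 5),
            )

    def test_bad_labels_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(LabelError):
            m.MultiSourceDataset(
                [rng.normal(size=(4, 2))], ["s0"], np.array([0, 1, 1, -1])
            )
        with pytest.raises(LabelError):
            m.MultiSourceDataset(
                [rng.normal(size=(4, 2))], ["s0"], np.array([1, 1, 1, 1])
            )

    def test_nonfinite_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(StructuralError):
            m.MultiSourceDataset([x], ["s0"], np.array([1, -1, 1, -1]))

    def test_concatenated_roundtrip_equals_per_source_form(self):
        ds = _toy()
        X, gm = ds.concatenated()
        assert X.shape == (10, 8)
        back = m.MultiSourceDataset.from_concatenated(X, gm, ds.labels)
        for a, b in zip(back.sources, ds.sources):
            np.testing.assert_array_equal(a, b)
        assert back.source_names == ds.source_names


class TestManifestIO:
    def test_load_save_load_roundtrips_bit_identically(self, tmp_path):
        ds = _toy(seed=3)
        manifest = m.save_dataset(ds, tmp_path)
        ds2 = m.load_dataset(manifest)
        ds3 = m.load_dataset(m.save_dataset(ds2, tmp_path / "again"))
        for a, b in zip(ds2.sources, ds3.sources):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ds2.labels, ds3.labels)
        for a, b in zip(ds.sources, ds2.sources):
            np.testing.assert_array_equal(a, b)

    def test_samples_as_columns_orientation(self, tmp_path):
        ds = _toy()
        manifest = m.save_dataset(ds, tmp_path)
        # rewrite first source transposed and flip the orientation flag
        np.savetxt(tmp_path / "s0.csv", ds.sources[0].T, delimiter=",", fmt="%.17g")
        np.savetxt(tmp_path / "s1.csv", ds.sources[1].T, delimiter=",", fmt="%.17g")
        text = (tmp_path / "manifest.yaml").read_text()
        (tmp_path / "manifest.yaml").write_text(
            text.replace("samples_rows", "samples_cols")
        )
        ds2 = m.load_dataset(manifest)
        np.testing.assert_array_equal(ds2.sources[0], ds.sources[0])

    def test_mismatched_rows_raise_structural_error(self, tmp_path):
        ds = _toy()
        manifest = m.save_dataset(ds, tmp_path)
        np.savetxt(tmp_path / "s1.csv", ds.sources[1][:-1], delimiter=",", fmt="%.17g")
        with pytest.raises(StructuralError, match="s1"):
            m.load_dataset(manifest)


class TestSplit:
    def test_exact_stratification_balanced(self):
        ds = _toy(n=100, d=(2,))
        tr, te = m.split_dataset(ds, m.SplitSpec(train_fraction=0.8, seed=0))
        assert tr.n_samples == 80 and te.n_samples == 20
        assert np.sum(tr.labels == 1) == 40 and np.sum(te.labels == 1) == 10

    def test_partition_disjoint_exhaustive_and_deterministic(self):
        ds = _toy(n=50, d=(2,))
        tr1, te1 = m.split_dataset(ds, m.SplitSpec(seed=5))
        tr2, te2 = m.split_dataset(ds, m.SplitSpec(seed=5))
        assert tr1.sample_ids == tr2.sample_ids and te1.sample_ids == te2.sample_ids
        assert set(tr1.sample_ids) | set(te1.sample_ids) == set(ds.sample_ids)
        assert not set(tr1.sample_ids) & set(te1.sample_ids)

    def test_imbalanced_split_sizes(self):
        # 61 negative / 85 positive ROIs, 80/20 hold-out
        rng = np.random.default_rng(0)
        labels = np.array([-1] * 61 + [1] * 85)
        ds = m.MultiSourceDataset([rng.normal(size=(146, 4))], ["s0"], labels)
        tr, te = m.split_dataset(ds, m.SplitSpec(train_fraction=0.8, seed=1))
        assert te.n_samples in (29, 30)
        n_neg = np.sum(te.labels == -1)
        n_pos = np.sum(te.labels == 1)
        assert abs(n_neg - 12.2) <= 1.2 and abs(n_pos - 17.0) <= 1.0

    def test_small_class_raises(self):
        x = np.arange(8, dtype=float).reshape(-1, 1)
        ds = m.MultiSourceDataset([x], ["s0"], np.array([1] * 7 + [-1]))
        with pytest.raises(SplitError):
            m.split_dataset(ds, m.SplitSpec())


class TestStandardize:
    def test_zscore_population_std(self):
        x = np.array([[1.0], [2.0], [3.0]])
        ds = m.MultiSourceDataset([x], ["s0"], np.array([1, -1, 1]))
        tr, _ = m.standardize(ds)
        np.testing.assert_allclose(
            tr.sources[0].ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_constant_column_maps_to_zeros(self):
        x = np.column_stack([np.ones(4), np.arange(4.0)])
        ds = m.MultiSourceDataset([x], ["s0"], np.array([1, -1, 1, -1]))
        tr, _ = m.standardize(ds)
        np.testing.assert_array_equal(tr.sources[0][:, 0], np.zeros(4))
        assert np.all(np.isfinite(tr.sources[0]))

    def test_refit_on_standardized_gives_unit_moments_and_labels_untouched(self):
        ds = _toy(n=20)
        tr, _ = m.standardize(ds)
        tr2, _ = m.standardize(tr)
        for x in tr2.sources:
            np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(x.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_array_equal(tr.labels, ds.labels)

    def test_same_transform_applied_to_others(self):
        ds = _toy(n=20, seed=1)
        other = _toy(n=6, seed=2)
        tr, (oth,) = m.standardize(ds, [other])
        mu = ds.sources[0].mean(axis=0)
        sd = ds.sources[0].std(axis=0)
        np.testing.assert_allclose(oth.sources[0], (other.sources[0] - mu) / sd)
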