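"""Synthetic task generation, pool splitting, client partitioning, I/O."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from privatekt.datasets import (
    LabeledDataset,
    PartitionSpec,
    build_federation,
    make_synthetic_classification,
    partition_clients,
    read_csv_dataset,
    read_idx_images,
    read_idx_labels,
    read_partition_manifest,
    split_public_pool,
    write_csv_dataset,
    write_partition_manifest,
)


class TestMakeSyntheticClassification:
    def test_balanced_labels_and_shapes(self):
        data = make_synthetic_classification(103, 10, 8, 3.0, seed=0)
        counts = np.bincount(data.labels, minlength=10)
        assert counts.max() - counts.min() <= 1
        assert data.features.shape == (103, 8)
        assert len(set(data.sample_ids.tolist())) == 103

    def test_separable_task_supports_linear_classifier(self, small_dataset):
        """Fit-and-score oracle: a linear model exceeds 0.9 held-out accuracy."""
        held_out = make_synthetic_classification(5000, 10, 8, 3.0, seed=99)
        clf = LogisticRegression(max_iter=2000).fit(
            small_dataset.features, small_dataset.labels
        )
        assert clf.score(held_out.features, held_out.labels) > 0.9

    def test_zero_separation_is_chance_level(self):
        """All class means coincide, so held-out accuracy sits near 1/C."""
        train = make_synthetic_classification(10, 10, 2, 0.0, seed=1)
        held_out = make_synthetic_classification(5000, 10, 2, 0.0, seed=2)
        clf = LogisticRegression(max_iter=2000).fit(train.features, train.labels)
        assert clf.score(held_out.features, held_out.labels) < 0.2

    def test_deterministic_from_seed(self):
        a = make_synthetic_classification(50, 5, 4, 2.0, seed=7)
        b = make_synthetic_classification(50, 5, 4, 2.0, seed=7)
        assert (a.features == b.features).all()
        assert (a.labels == b.labels).all()

    def test_n_below_classes_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_classification(5, 10, 2, 1.0, seed=0)


class TestSplitPublicPool:
    def test_fraction_and_disjointness(self, small_dataset):
        private, pool = split_public_pool(small_dataset, 0.2, seed=3)
        assert pool.n_samples == 20
        assert private.n_samples == 80
        private_ids = set(private.sample_ids.tolist())
        pool_ids = set(pool.sample_ids.tolist())
        assert private_ids.isdisjoint(pool_ids)
        assert private_ids | pool_ids == set(small_dataset.sample_ids.tolist())

    def test_smallest_legal_split(self):
        data = make_synthetic_classification(2, 2, 2, 1.0, seed=0)
        private, pool = split_public_pool(data, 0.5, seed=0)
        assert pool.n_samples == 1 and private.n_samples == 1

    def test_deterministic(self, small_dataset):
        _, a = split_public_pool(small_dataset, 0.3, seed=11)
        _, b = split_public_pool(small_dataset, 0.3, seed=11)
        assert (a.sample_ids == b.sample_ids).all()

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 0.001])
    def test_degenerate_fraction_rejected(self, small_dataset, fraction):
        with pytest.raises(ValueError):
            split_public_pool(small_dataset, fraction, seed=0)


class TestPartitionClients:
    def test_iid_conserves_label_histogram(self, small_dataset):
        spec = PartitionSpec("iid", n_clients=4, seed=0)
        shards = partition_clients(small_dataset, spec)
        assert [s.n_samples for s in shards] == [25, 25, 25, 25]
        pooled = np.concatenate([s.labels for s in shards])
        assert (
            np.bincount(pooled, minlength=10)
            == np.bincount(small_dataset.labels, minlength=10)
        ).all()

    def test_dirichlet_concentration_limit(self):
        """alpha -> inf: per-client label proportions approach the global ones."""
        data = make_synthetic_classification(10_000, 5, 2, 1.0, seed=0)
        spec = PartitionSpec("class_noniid", n_clients=5, alpha=1e6, seed=1)
        global_props = np.bincount(data.labels, minlength=5) / data.n_samples
        for shard in partition_clients(data, spec):
            props = np.bincount(shard.labels, minlength=5) / shard.n_samples
            tv = 0.5 * np.abs(props - global_props).sum()
            assert tv < 0.05

    def test_low_alpha_skews_labels(self):
        data = make_synthetic_classification(5000, 5, 2, 1.0, seed=0)
        spec = PartitionSpec("class_noniid", n_clients=5, alpha=0.1, seed=1)
        tvs = []
        global_props = np.bincount(data.labels, minlength=5) / data.n_samples
        for shard in partition_clients(data, spec):
            props = np.bincount(shard.labels, minlength=5) / shard.n_samples
            tvs.append(0.5 * np.abs(props - global_props).sum())
        assert max(tvs) > 0.3  # strong skew somewhere

    def test_sigma_zero_equal_sizes(self, small_dataset):
        spec = PartitionSpec("size_noniid", n_clients=4, sigma=0.0, seed=0)
        sizes = [s.n_samples for s in partition_clients(small_dataset, spec)]
        assert max(sizes) - min(sizes) <= 1

    @given(
        scheme=st.sampled_from(["iid", "class_noniid", "size_noniid", "mixed_noniid"]),
        n_clients=st.integers(2, 6),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_partition_conservation(self, scheme, n_clients, seed):
        """Shards are disjoint and their union is the input, for every scheme."""
        data = make_synthetic_classification(120, 4, 3, 2.0, seed=5)
        spec = PartitionSpec(scheme, n_clients=n_clients, seed=seed)
        shards = partition_clients(data, spec)
        assert len(shards) == n_clients
        all_ids = np.concatenate([s.sample_ids for s in shards])
        assert len(all_ids) == len(set(all_ids.tolist()))
        assert set(all_ids.tolist()) == set(data.sample_ids.tolist())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PartitionSpec("iid", n_clients=1)
        with pytest.raises(ValueError):
            PartitionSpec("class_noniid", n_clients=2, alpha=0.0)
        with pytest.raises(ValueError):
            PartitionSpec("bogus", n_clients=2)


class TestBuildFederation:
    def test_pool_disjoint_from_every_shard(self, small_dataset):
        fed = build_federation(
            small_dataset, 0.2, PartitionSpec("class_noniid", n_clients=3, seed=0), seed=1
        )
        pool_ids = set(fed.pool.sample_ids.tolist())
        for shard in fed.clients:
            assert pool_ids.isdisjoint(shard.sample_ids.tolist())


class TestIO:
    def test_csv_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "data.csv"
        write_csv_dataset(small_dataset, path)
        loaded = read_csv_dataset(path, n_classes=10)
        assert np.allclose(loaded.features, small_dataset.features)
        assert (loaded.labels == small_dataset.labels).all()
        assert (loaded.sample_ids == small_dataset.sample_ids).all()

    def test_manifest_round_trip(self, small_dataset, tmp_path):
        shards = partition_clients(
            small_dataset, PartitionSpec("iid", n_clients=4, seed=0)
        )
        path = tmp_path / "manifest.json"
        write_partition_manifest(shards, path)
        manifest = read_partition_manifest(path)
        for i, shard in enumerate(shards):
            assert manifest[i] == shard.sample_ids.tolist()

    def test_idx_readers(self, tmp_path):
        """Round-trip through hand-constructed big-endian IDX bytes."""
        images = np.arange(2 * 4 * 3, dtype=np.uint8).reshape(2, 12)
        img_path = tmp_path / "images.idx"
        img_path.write_bytes(struct.pack(">IIII", 0x803, 2, 4, 3) + images.tobytes())
        lbl_path = tmp_path / "labels.idx"
        lbl_path.write_bytes(struct.pack(">II", 0x801, 2) + bytes([3, 9]))
        loaded = read_idx_images(img_path)
        assert loaded.shape == (2, 12)
        assert np.allclose(loaded * 255.0, images)
        assert read_idx_labels(lbl_path).tolist() == [3, 9]
        with pytest.raises(ValueError):
            read_idx_images(lbl_path)


class TestLabeledDatasetInvariants:
    def test_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError):
            LabeledDataset(np.zeros((2, 2)), np.array([0, 5]), 3, np.array([0, 1]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            LabeledDataset(np.zeros((2, 2)), np.array([0, 1]), 2, np.array([4, 4]))
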