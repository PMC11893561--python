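"""Bag containers and the HDF5 bag store.

A *bag* is one whole-slide image represented by per-patch embedding
matrices: patch features ``F_p`` (m x d_p), optional cell features ``F_c``
(m x d_c) and text features ``F_t`` (m x d_t), plus — once the anomaly
detector has run — reconstruction features ``F_r`` and per-instance
reconstruction errors.  Only the bag-level label is real supervision;
``instance_labels`` exist only for synthetic data, where the generator
knows which instances are abnormal.

On disk a dataset is a single HDF5 file with one group per bag
(``/bags/<bag_id>/``) and a JSON manifest (embedded as a root attribute and
mirrored to a sidecar ``*.manifest.json``) recording provenance: generator
config, seed, class counts and bag order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import h5py
import numpy as np

SCHEMA_VERSION = 1

_MATRIX_KEYS = ("F_p", "F_c", "F_t", "F_r")


@dataclass
class EmbeddingBag:
    """One slide: aligned per-instance feature matrices and a bag label."""

    bag_id: str
    F_p: np.ndarray
    label: int
    F_c: Optional[np.ndarray] = None
    F_t: Optional[np.ndarray] = None
    F_r: Optional[np.ndarray] = None
    errors: Optional[np.ndarray] = None
    instance_labels: Optional[np.ndarray] = None
    selected_indices: Optional[np.ndarray] = None

    def __post_init__(self):
        self.F_p = np.asarray(self.F_p)
        if self.F_p.ndim != 2 or self.F_p.shape[0] < 1:
            raise ValueError(f"bag {self.bag_id}: F_p must be a non-empty matrix")
        m = self.F_p.shape[0]
        for key in ("F_c", "F_t", "F_r"):
            mat = getattr(self, key)
            if mat is not None and mat.shape[0] != m:
                raise ValueError(
                    f"bag {self.bag_id}: {key} has {mat.shape[0]} rows, expected {m}"
                )
        for key in ("errors", "instance_labels"):
            vec = getattr(self, key)
            if vec is not None and len(vec) != m:
                raise ValueError(
                    f"bag {self.bag_id}: {key} has length {len(vec)}, expected {m}"
                )
        if self.label == 0 and self.instance_labels is not None:
            if np.any(np.asarray(self.instance_labels) != 0):
                raise ValueError(
                    f"bag {self.bag_id}: negative bag with positive instance labels"
                )

    @property
    def n_instances(self) -> int:
        return self.F_p.shape[0]

    def modalities(self) -> dict[str, np.ndarray]:
        """Present feature matrices keyed by short modality name."""
        out = {"p": self.F_p}
        for name, key in (("c", "F_c"), ("t", "F_t"), ("r", "F_r")):
            mat = getattr(self, key)
            if mat is not None:
                out[name] = mat
        return out

    def with_(self, **changes) -> "EmbeddingBag":
        return replace(self, **changes)


@dataclass
class BagDataset:
    """Ordered collection of bags with a provenance manifest."""

    bags: list[EmbeddingBag]
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bags)

    def __iter__(self) -> Iterator[EmbeddingBag]:
        return iter(self.bags)

    def __getitem__(self, i: int) -> EmbeddingBag:
        return self.bags[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.bags], dtype=int)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for b in self.bags:
            counts[b.label] = counts.get(b.label, 0) + 1
        return dict(sorted(counts.items()))

    def subset(self, indices) -> "BagDataset":
        return BagDataset([self.bags[i] for i in indices], manifest=dict(self.manifest))

    def filter_label(self, label: int) -> "BagDataset":
        return BagDataset([b for b in self.bags if b.label == label],
                          manifest=dict(self.manifest))


# ---------------------------------------------------------------------------
# HDF5 store
# ---------------------------------------------------------------------------

def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".manifest.json") if path.suffix != ".h5" \
        else path.with_suffix(".manifest.json")


def write_bag_store(dataset: BagDataset, path) -> None:
    """Write a dataset to one HDF5 file plus a sidecar JSON manifest."""
    path = Path(path)
    manifest = dict(dataset.manifest)
    manifest["schema_version"] = SCHEMA_VERSION
    manifest["bag_ids"] = [b.bag_id for b in dataset.bags]
    manifest["class_counts"] = {str(k): v for k, v in dataset.class_counts.items()}
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        root = f.create_group("bags")
        for bag in dataset.bags:
            g = root.create_group(bag.bag_id)
            g.attrs["label"] = int(bag.label)
            g.attrs["m"] = int(bag.n_instances)
            for key in _MATRIX_KEYS:
                mat = getattr(bag, key)
                if mat is not None:
                    g.create_dataset(key, data=np.asarray(mat, dtype=np.float32))
            if bag.errors is not None:
                g.create_dataset("errors", data=np.asarray(bag.errors, dtype=np.float64))
            if bag.instance_labels is not None:
                g.create_dataset("instance_labels",
                                 data=np.asarray(bag.instance_labels, dtype=np.int8))
            if bag.selected_indices is not None:
                g.create_dataset("selected_indices",
                                 data=np.asarray(bag.selected_indices, dtype=np.int64))
    _manifest_path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _read_bag(g: h5py.Group, bag_id: str) -> EmbeddingBag:
    kwargs = {}
    for key in _MATRIX_KEYS:
        if key in g:
            kwargs[key] = g[key][...]
    if "F_p" not in kwargs:
        raise ValueError(f"bag {bag_id}: missing required dataset F_p")
    for key in ("errors", "instance_labels", "selected_indices"):
        if key in g:
            kwargs[key] = g[key][...]
    try:
        return EmbeddingBag(bag_id=bag_id, label=int(g.attrs["label"]), **kwargs)
    except ValueError as e:
        raise ValueError(f"schema error in stored bag: {e}") from e


def iter_bag_store(path) -> Iterator[EmbeddingBag]:
    """Stream bags one at a time without materializing the whole dataset."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        if manifest.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported bag-store schema version {manifest.get('schema_version')}"
            )
        for bag_id in manifest["bag_ids"]:
            yield _read_bag(f["bags"][bag_id], bag_id)


def read_manifest(path) -> dict:
    with h5py.File(Path(path), "r") as f:
        return json.loads(f.attrs["manifest"])


def read_bag_store(path) -> BagDataset:
    """Load a full dataset; round-trips everything written by write_bag_store."""
    manifest = read_manifest(path)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported bag-store schema version {manifest.get('schema_version')}"
        )
    bags = list(iter_bag_store(path))
    return BagDataset(bags, manifest=manifest)
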