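"""Paired sparse/dense datasets with grouped ("patient"-wise) splits.

The atomic record is an :class:`ImagePair`: a sparse-sampled DAS
reconstruction (network input) and its densely sampled counterpart
(regression target), both H x W in [0, 1], tagged with a group id so
train/validation/test splits never mix items of one synthetic subject.

Bundles round-trip through a single HDF5 archive with groups ``/train``,
``/val``, ``/test`` and per-item ``input`` / ``target`` datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .acoustics import simulate_pair
from .geometry import make_geometry, subsample_elements
from .phantom import group_scene

__all__ = ["ImagePair", "TaskSpec", "DatasetBundle", "build_dataset", "save_bundle", "load_bundle"]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ImagePair:
    sparse_input: np.ndarray = field(repr=False)
    ground_truth: np.ndarray = field(repr=False)
    group_id: int = 0
    geometry: str = "ring"
    n_sparse: int = 32
    n_dense: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.sparse_input, dtype=np.float32)
        b = np.asarray(self.ground_truth, dtype=np.float32)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
        for name, img in (("sparse_input", a), ("ground_truth", b)):
            if img.min() < -1e-6 or img.max() > 1 + 1e-6:
                raise ValueError(f"{name} not normalized to [0, 1]")
        object.__setattr__(self, "sparse_input", a)
        object.__setattr__(self, "ground_truth", b)

    @property
    def meta(self) -> dict:
        return {
            "group_id": self.group_id, "geometry": self.geometry,
            "n_sparse": self.n_sparse, "n_dense": self.n_dense, "seed": self.seed,
        }


@dataclass(frozen=True)
class TaskSpec:
    """One sparse-sampling task: array kind + sparse/dense element counts."""

    geometry: str = "ring"
    n_sparse: int = 32
    n_dense: int = 256
    grid_size: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.0

    def geometries(self):
        dense = make_geometry(self.geometry, self.n_dense)
        sparse = subsample_elements(dense, self.n_sparse)
        return dense, sparse


@dataclass
class DatasetBundle:
    """Ordered image pairs plus a disjoint group-wise split assignment."""

    pairs: list[ImagePair]
    split_of_group: dict[int, str]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.group_id not in self.split_of_group:
                raise ValueError(f"pair group {p.group_id} missing from split assignment")

    def split(self, name: str) -> list[ImagePair]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [p for p in self.pairs if self.split_of_group[p.group_id] == name]

    @property
    def train(self) -> list[ImagePair]:
        return self.split("train")

    @property
    def val(self) -> list[ImagePair]:
        return self.split("val")

    @property
    def test(self) -> list[ImagePair]:
        return self.split("test")

    def groups_in_split(self, name: str) -> list[int]:
        return sorted(g for g, s in self.split_of_group.items() if s == name)


def _partition_groups(group_ids: Sequence[int], fractions: tuple[float, float, float],
                      rng: np.random.Generator) -> dict[int, str]:
    """Partition groups into train/val/test by fraction (largest remainder)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    n = len(group_ids)
    if n < 3:
        raise ValueError("need at least 3 groups to form three nonempty splits")
    quota = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quota]
    rema = [q - c for q, c in zip(quota, counts)]
    while sum(counts) < n:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    # every split nonempty: steal from the largest if needed
    for i in range(3):
        if counts[i] == 0:
            j = int(np.argmax(counts))
            counts[j] -= 1
            counts[i] += 1
    order = list(group_ids)
    rng.shuffle(order)
    out: dict[int, str] = {}
    start = 0
    for split, c in zip(SPLITS, counts):
        for g in order[start:start + c]:
            out[g] = split
        start += c
    return out


def build_dataset(
    n_items: int,
    n_groups: int,
    task: TaskSpec,
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    out_path: str | Path | None = None,
) -> DatasetBundle:
    """Simulate a grouped paired dataset, optionally writing it to HDF5.

    Items are stored subject-blocked, the way scanner archives are: the
    first ``n_items // n_groups`` (plus remainder) consecutive items
    belong to subject 0, the next block to subject 1, and so on, so "the
    first k pairs" of a split reads consecutive acquisitions of one
    subject.  Groups (never items) are partitioned into train/val/test
    by ``split_fractions``.  The whole bundle is a pure function of its
    arguments and ``seed``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if n_groups > n_items:
        raise ValueError("n_groups cannot exceed n_items")
    rng = np.random.default_rng(seed)
    family_seed = int(rng.integers(0, 2**31 - 1))
    group_seeds = rng.integers(0, 2**31 - 1, size=n_groups)
    split_of_group = _partition_groups(range(n_groups), tuple(split_fractions), rng)
    dense, sparse = task.geometries()
    noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    base, rem = divmod(n_items, n_groups)
    block_sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    group_of_item = np.repeat(np.arange(n_groups), block_sizes)

    pairs = []
    for i in range(n_items):
        g = int(group_of_item[i])
        scene = group_scene(family_seed, int(group_seeds[g]), item_seed=i,
                            grid_size=task.grid_size)
        x, y = simulate_pair(scene, dense, sparse, task.grid_size,
                             noise_sigma=task.noise_sigma, rng=noise_rng)
        pairs.append(ImagePair(
            sparse_input=x, ground_truth=y, group_id=g, geometry=task.geometry,
            n_sparse=task.n_sparse, n_dense=task.n_dense, seed=i,
        ))

    config = {"n_items": n_items, "n_groups": n_groups, "task": asdict(task),
              "split_fractions": list(split_fractions), "seed": seed}
    bundle = DatasetBundle(pairs=pairs, split_of_group=split_of_group, config=config)
    if out_path is not None:
        save_bundle(bundle, out_path)
    return bundle


def save_bundle(bundle: DatasetBundle, path: str | Path) -> None:
    """Write a bundle to one HDF5 archive (groups /train /val /test)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(bundle.config, sort_keys=True)
        f.attrs["coordinate_convention"] = (
            "pixel centers; origin at grid center; y-axis up; fov [-1,1]^2"
        )
        f.attrs["split_of_group"] = json.dumps(
            {str(k): v for k, v in sorted(bundle.split_of_group.items())})
        for split in SPLITS:
            grp = f.create_group(split)
            for j, p in enumerate(bundle.split(split)):
                item = grp.create_group(f"item_{j:05d}")
                item.create_dataset("input", data=p.sparse_input.astype(np.float32),
                                    track_times=False)
                item.create_dataset("target", data=p.ground_truth.astype(np.float32),
                                    track_times=False)
                item.attrs.update({"group_id": p.group_id, "geometry": p.geometry,
                                   "n_sparse": p.n_sparse, "n_dense": p.n_dense,
                                   "seed": p.seed})


def load_bundle(path: str | Path) -> DatasetBundle:
    """Read a bundle written by :func:`save_bundle` (order-preserving)."""
    with h5py.File(path, "r") as f:
        config = json.loads(f.attrs["config"])
        split_of_group = {int(k): v for k, v in json.loads(f.attrs["split_of_group"]).items()}
        seen: list[tuple[int, ImagePair]] = []
        for split in SPLITS:
            for name in sorted(f[split]):
                item = f[split][name]
                seen.append((int(item.attrs["seed"]), ImagePair(
                    sparse_input=item["input"][()], ground_truth=item["target"][()],
                    group_id=int(item.attrs["group_id"]), geometry=str(item.attrs["geometry"]),
                    n_sparse=int(item.attrs["n_sparse"]), n_dense=int(item.attrs["n_dense"]),
                    seed=int(item.attrs["seed"]),
                )))
    seen.sort(key=lambda t: t[0])
    return DatasetBundle(pairs=[p for _, p in seen], split_of_group=split_of_group, config=config)
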