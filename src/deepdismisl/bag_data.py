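"""Data model and I/O for bag-of-features survival cohorts.

A *bag* is one patient's matrix of pre-extracted patch feature vectors
(n instances x d features); the survival label lives at the bag level as a
right-censored (time, event) pair.  Cohorts are described by a CSV manifest
``bag_id,path,time,event`` whose paths point either at one shared HDF5
container (one float32 dataset per bag, keyed by bag_id) or at per-bag
headerless CSV matrices for tiny fixtures.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "InstanceFeatureBag",
    "SurvivalRecord",
    "CohortManifest",
    "CohortError",
    "load_cohort",
    "write_cohort",
    "resample_bag",
    "DEFAULT_BAG_SIZE",
]

#: Fixed bag size used for the original whole-slide cohorts (12,000 tiles per
#: slide).  Dataset-specific, not method-specific: synthetic cohorts use much
#: smaller bags.
DEFAULT_BAG_SIZE = 12_000


class CohortError(ValueError):
    """Raised for manifest, schema, or validation failures during cohort I/O."""


@dataclass
class InstanceFeatureBag:
    """One patient's n x d patch-feature matrix (the MIL bag)."""

    bag_id: str
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2:
            raise CohortError(
                f"bag {self.bag_id!r}: features must be 2-D, got shape "
                f"{self.features.shape}"
            )
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise CohortError(f"bag {self.bag_id!r}: empty feature matrix")
        if not np.all(np.isfinite(self.features)):
            raise CohortError(f"bag {self.bag_id!r}: non-finite feature values")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


@dataclass
class SurvivalRecord:
    """Right-censored survival label: observed time and event indicator.

    ``event`` = 1 means death was observed at ``time``; 0 means the subject
    was censored (still alive at last follow-up).
    """

    bag_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if not (self.time > 0 and np.isfinite(self.time)):
            raise CohortError(f"bag {self.bag_id!r}: time must be positive finite")
        if self.event not in (0, 1):
            raise CohortError(
                f"bag {self.bag_id!r}: event must be 0 or 1, got {self.event!r}"
            )
        self.event = int(self.event)


@dataclass
class CohortManifest:
    """Parsed manifest rows plus the cohort-wide feature dimension."""

    records: list = field(default_factory=list)  # (bag_id, path, time, event)
    feature_dim: int | None = None


def _read_manifest(manifest_path: str) -> CohortManifest:
    if not os.path.exists(manifest_path):
        raise CohortError(f"manifest not found: {manifest_path}")
    manifest = CohortManifest()
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"bag_id", "path", "time", "event"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CohortError(
                f"manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        seen: set[str] = set()
        for row in reader:
            bag_id = row["bag_id"]
            if bag_id in seen:
                raise CohortError(f"duplicate bag_id in manifest: {bag_id!r}")
            seen.add(bag_id)
            try:
                time = float(row["time"])
                event = int(row["event"])
            except ValueError as exc:
                raise CohortError(f"bag {bag_id!r}: bad label row: {exc}") from exc
            manifest.records.append((bag_id, row["path"], time, event))
    return manifest


def _load_matrix(path: str, bag_id: str) -> np.ndarray:
    if not os.path.exists(path):
        raise CohortError(f"bag {bag_id!r}: container not found: {path}")
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as h5:
            if bag_id not in h5:
                raise CohortError(f"bag {bag_id!r}: no such dataset in {path}")
            return np.asarray(h5[bag_id], dtype=np.float32)
    # delimited-text fallback: no header, one instance per line
    return np.loadtxt(path, delimiter=",", dtype=np.float32, ndmin=2)


def load_cohort(manifest_path: str) -> list[tuple[InstanceFeatureBag, SurvivalRecord]]:
    """Load a cohort from a manifest CSV, preserving manifest order.

    Raises :class:`CohortError` on missing files, duplicate bag ids,
    inconsistent feature dimensions, invalid labels, or non-finite values.
    """
    manifest = _read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    cohort: list[tuple[InstanceFeatureBag, SurvivalRecord]] = []
    for bag_id, path, time, event in manifest.records:
        full = path if os.path.isabs(path) else os.path.join(base, path)
        mat = _load_matrix(full, bag_id)
        bag = InstanceFeatureBag(bag_id, mat)
        if manifest.feature_dim is None:
            manifest.feature_dim = bag.feature_dim
        elif bag.feature_dim != manifest.feature_dim:
            raise CohortError(
                f"bag {bag_id!r}: feature dim {bag.feature_dim} != cohort "
                f"dim {manifest.feature_dim}"
            )
        cohort.append((bag, SurvivalRecord(bag_id, time, event)))
    return cohort


def write_cohort(
    cohort: list[tuple[InstanceFeatureBag, SurvivalRecord]],
    out_dir: str,
    container: str = "h5",
) -> str:
    """Write a cohort to ``out_dir``; returns the manifest path.

    ``container='h5'`` stores all bags as float32 datasets in one
    ``bags.h5``; ``container='csv'`` writes one headerless matrix per bag.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    rows = []
    if container == "h5":
        h5_path = os.path.join(out_dir, "bags.h5")
        with h5py.File(h5_path, "w") as h5:
            for bag, rec in cohort:
                h5.create_dataset(bag.bag_id, data=bag.features)
                rows.append((bag.bag_id, "bags.h5", rec.time, rec.event))
    elif container == "csv":
        for bag, rec in cohort:
            rel = f"{bag.bag_id}.csv"
            np.savetxt(
                os.path.join(out_dir, rel), bag.features, delimiter=",", fmt="%.9g"
            )
            rows.append((bag.bag_id, rel, rec.time, rec.event))
    else:
        raise ValueError(f"unknown container {container!r}")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bag_id", "path", "time", "event"])
        for row in rows:
            writer.writerow(row)
    return manifest_path


def resample_bag(
    bag: InstanceFeatureBag, n_target: int = DEFAULT_BAG_SIZE, seed: int = 0
) -> InstanceFeatureBag:
    """Resample a bag to exactly ``n_target`` instances, deterministically.

    If the bag is larger, a uniform random subset is drawn without
    replacement; if smaller, every original instance is retained and the
    remainder is drawn uniformly with replacement.  A bag already at
    ``n_target`` is returned unchanged.
    """
    if n_target <= 0:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    n = bag.n_instances
    if n == n_target:
        return bag
    rng = np.random.default_rng(seed)
    if n > n_target:
        idx = rng.choice(n, size=n_target, replace=False)
    else:
        extra = rng.integers(0, n, size=n_target - n)
        idx = np.concatenate([np.arange(n), extra])
    return InstanceFeatureBag(bag.bag_id, bag.features[idx])
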