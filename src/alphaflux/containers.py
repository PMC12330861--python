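"""Core in-memory containers shared across the package.

``RegionTimeSeries`` holds region-level voltage-like signals (regions x
samples at a fixed sampling rate); ``Connectome`` holds a structural graph
as symmetric weight and tract-length matrices with region labels.  Both
round-trip through plain-text formats (delimited matrices, TVB-style
``weights.csv`` / ``lengths.csv`` / ``labels.txt`` bundles) and HDF5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RegionTimeSeries", "Connectome"]


@dataclass
class RegionTimeSeries:
    """Multichannel signal container.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_samples)
        Voltage-like signal per region.
    fs : float
        Sampling rate in Hz.
    labels : list of str, optional
        Region names; defaults to ``r000, r001, ...``.
    meta : dict
        Free-form provenance (generator spec, simulation config, ...).
    """

    data: np.ndarray
    fs: float
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.labels is None:
            self.labels = [f"r{i:03d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match number of regions")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    # ---------------------------------------------------------------- I/O
    def to_text(self, path: str | Path) -> None:
        """Write one row per region; header carries fs and labels."""
        path = Path(path)
        header = f"fs={self.fs}\nlabels={','.join(self.labels)}"
        np.savetxt(path, self.data, header=header)

    @classmethod
    def from_text(cls, path: str | Path) -> "RegionTimeSeries":
        path = Path(path)
        fs, labels = None, None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("labels="):
                    labels = body[7:].split(",")
        if fs is None:
            raise ValueError(f"{path}: missing 'fs=' header line")
        return cls(np.loadtxt(path), fs=fs, labels=labels)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.attrs["fs"] = self.fs
            fh.attrs["labels"] = json.dumps(self.labels)
            fh.attrs["meta"] = json.dumps(self.meta, default=str)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "RegionTimeSeries":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                fh["data"][()],
                fs=float(fh.attrs["fs"]),
                labels=json.loads(fh.attrs["labels"]),
                meta=json.loads(fh.attrs.get("meta", "{}")),
            )


@dataclass
class Connectome:
    """Structural connectome: symmetric weights and tract lengths (mm).

    Conduction delays (ms) derive from the lengths as ``d = L / s`` for a
    conduction speed ``s`` in m/s (equivalently mm/ms).
    """

    weights: np.ndarray
    lengths: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.lengths.shape != (n, n):
            raise ValueError("weights and lengths must be square with equal dims")
        if np.any(self.weights < 0) or np.any(self.lengths < 0):
            raise ValueError("weights and lengths must be non-negative")
        if self.labels is None:
            self.labels = [f"r{i:03d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def delays(self, speed: float) -> np.ndarray:
        """Delay matrix in ms for conduction speed in m/s (= mm/ms)."""
        if speed <= 0:
            raise ValueError("conduction speed must be positive")
        return self.lengths / speed

    # ---------------------------------------------------------------- I/O
    def to_bundle(self, directory: str | Path) -> None:
        """TVB-style bundle: weights.csv, lengths.csv, labels.txt."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "weights.csv", self.weights, delimiter=",")
        np.savetxt(d / "lengths.csv", self.lengths, delimiter=",")
        (d / "labels.txt").write_text("\n".join(self.labels) + "\n")

    @classmethod
    def from_bundle(cls, directory: str | Path) -> "Connectome":
        d = Path(directory)
        weights = np.loadtxt(d / "weights.csv", delimiter=",")
        lengths = np.loadtxt(d / "lengths.csv", delimiter=",")
        labels_file = d / "labels.txt"
        labels = (
            labels_file.read_text().strip().splitlines() if labels_file.exists() else None
        )
        return cls(weights, lengths, labels)
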