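"""Shared containers for multichannel ROI time series.

The pipeline operates on region-of-interest (ROI) BOLD series: per-block
``samples x regions`` matrices tagged with subject/condition metadata, and the
per-condition concatenated series the causal analysis consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The eight nuclei of the basal-ganglia motor circuit studied here: primary
#: motor cortex, primary somatosensory cortex, putamen, external/internal
#: globus pallidum, subthalamic nucleus, substantia nigra and motor thalamus.
DEFAULT_REGION_LABELS = ("M1", "S1", "Put", "GPe", "STN", "GPi", "SN", "Tal")

#: fMRI repetition time (seconds per volume) of the study design emulated here.
DEFAULT_REPETITION_TIME = 1.6


@dataclass(frozen=True)
class RegionSet:
    """An ordered set of uniquely named brain regions."""

    labels: tuple[str, ...] = DEFAULT_REGION_LABELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"region labels must be unique, got {self.labels}")
        if not self.labels:
            raise ValueError("region set must not be empty")

    @property
    def count(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}; known: {self.labels}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    @classmethod
    def default(cls) -> "RegionSet":
        return cls(DEFAULT_REGION_LABELS)


@dataclass
class Block:
    """One contiguous recording block of one subject under one condition."""

    values: np.ndarray  # samples x regions
    regions: RegionSet
    subject: int
    condition: str
    index: int = 0  # block index within this subject x condition

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("block values must be a 2-D samples x regions array")
        if self.values.shape[1] != self.regions.count:
            raise ValueError(
                f"block has {self.values.shape[1]} columns but region set has "
                f"{self.regions.count} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("block contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def copy_with(self, values: np.ndarray) -> "Block":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class MultichannelSeries:
    """A concatenated samples x regions series with block bookkeeping.

    ``block_boundaries`` are the start indices of the concatenated blocks; they
    always partition ``[0, n_samples)``. Permutation tests downstream use them
    so that shuffling never crosses an artificial block junction.
    """

    values: np.ndarray
    regions: RegionSet
    repetition_time: float = DEFAULT_REPETITION_TIME
    block_boundaries: tuple[int, ...] = (0,)
    condition: str | None = None
    subjects: tuple[int, ...] = ()  # subject id per block, optional

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("series values must be a 2-D samples x regions array")
        if self.values.shape[1] != self.regions.count:
            raise ValueError("series column count does not match region set")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        b = tuple(int(x) for x in self.block_boundaries)
        if not b or b[0] != 0:
            raise ValueError("block_boundaries must start at 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("block_boundaries must be strictly increasing")
        if b[-1] >= self.n_samples:
            raise ValueError("block boundary beyond series length")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        self.block_boundaries = b

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def block_slices(self) -> list[tuple[int, int]]:
        edges = list(self.block_boundaries) + [self.n_samples]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.regions.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.regions.labels))
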