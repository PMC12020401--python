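"""Latent-vector layout shared by the autoencoder and the latent statistics.

A latent vector of a region-disentangled model is an ``R x d`` array flattened
region-major: coordinates ``[(r-1)*d, r*d)`` form the subset ``z_r`` that
controls anatomic region ``r`` (regions are 1-based, matching the region
partition convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LatentLayout:
    """Partition of a flat latent vector into per-region subsets."""

    n_regions: int = 15
    width_per_region: int = 5

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.width_per_region < 1:
            raise ValueError("layout dimensions must be positive")

    @property
    def total_width(self) -> int:
        return self.n_regions * self.width_per_region

    def region_slice(self, r: int) -> slice:
        """Slice of the flat vector holding subset ``z_r`` (r is 1-based)."""
        if not 1 <= r <= self.n_regions:
            raise ValueError(f"region id {r} outside 1..{self.n_regions}")
        d = self.width_per_region
        return slice((r - 1) * d, r * d)

    def region_indices(self, r: int) -> np.ndarray:
        s = self.region_slice(r)
        return np.arange(s.start, s.stop)

    def column_names(self, prefix: str = "z") -> list[str]:
        return [f"{prefix}_{i + 1:03d}" for i in range(self.total_width)]


@dataclass
class LatentVector:
    """A single subject's latent representation with its region layout."""

    values: np.ndarray
    layout: LatentLayout = field(default_factory=LatentLayout)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.layout.total_width:
            raise ValueError(
                f"latent length {self.values.size} != layout width "
                f"{self.layout.total_width}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent vector contains non-finite values")

    def subset(self, r: int) -> np.ndarray:
        """Return ``z_r``, the d-dimensional subset for region ``r``."""
        return self.values[self.layout.region_slice(r)]

    def __len__(self) -> int:
        return self.values.size
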