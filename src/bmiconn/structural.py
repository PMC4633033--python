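"""Structural (fiber-density) connectivity networks.

A subject's structural network is built from a set of reconstructed fiber
tracks, each recorded as an unordered pair of atlas regions plus a length in
millimetres.  The edge weight between regions ``u`` and ``v`` is the fiber
density

    FD(u, v) = 2 / (S_u + S_v) * sum_f 1 / l(f)

i.e. an inverse-length-weighted fiber count normalised by the summed cortical
surface areas of the two endpoint regions.  Fibers are pre-filtered to the
anatomically plausible 20-500 mm length range.  Pairs with no surviving fiber
carry density 0 and are marked absent in an explicit presence mask, because
downstream subject-exclusion logic must distinguish "no fiber" from "tiny
density".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ReferentialIntegrityError

DEFAULT_MIN_FIBER_LEN = 20.0
DEFAULT_MAX_FIBER_LEN = 500.0


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    surface_area: float  # mm^2
    reward_flag: bool = False


@dataclass
class Atlas:
    """Parcellation: region ids are contiguous from 0; areas are positive mm^2."""

    regions: list[Region]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if ids != list(range(len(ids))):
            raise InvalidArgumentError("region ids must be contiguous from 0")
        if any(r.surface_area <= 0 for r in self.regions):
            raise InvalidArgumentError("surface areas must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def surface_areas(self) -> np.ndarray:
        return np.array([r.surface_area for r in self.regions], dtype=float)

    @property
    def reward_flags(self) -> np.ndarray:
        return np.array([r.reward_flag for r in self.regions], dtype=bool)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.id for r in self.regions],
                "name": self.names,
                "surface_area_mm2": self.surface_areas,
                "reward_flag": self.reward_flags.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Atlas":
        return cls(
            [
                Region(
                    int(row.region_id),
                    str(row.name_),
                    float(row.surface_area_mm2),
                    bool(int(row.reward_flag)),
                )
                for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
            ]
        )


@dataclass
class FiberSet:
    """Per-subject fiber records: unordered region pairs plus lengths (mm)."""

    subject_id: str
    region_u: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    region_v: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    length_mm: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.region_u = np.asarray(self.region_u, dtype=np.int64)
        self.region_v = np.asarray(self.region_v, dtype=np.int64)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        if not (len(self.region_u) == len(self.region_v) == len(self.length_mm)):
            raise InvalidArgumentError("fiber arrays must have equal length")
        if np.any(self.region_u == self.region_v):
            raise InvalidArgumentError("self-loop fibers are forbidden")
        if np.any(self.length_mm <= 0):
            raise InvalidArgumentError("fiber lengths must be positive")

    def __len__(self) -> int:
        return len(self.length_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "region_u": self.region_u,
                "region_v": self.region_v,
                "length_mm": self.length_mm,
            }
        )


@dataclass
class StructuralNetwork:
    """Symmetric fiber-density matrix plus presence mask for one subject."""

    subject_id: str
    density: np.ndarray  # (n, n) nonnegative, symmetric, zero diagonal
    present: np.ndarray  # (n, n) boolean, symmetric

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.density.shape != self.present.shape or self.density.ndim != 2:
            raise InvalidArgumentError("density/present must be matching square matrices")


def filter_fibers(
    fiber_set: FiberSet,
    min_len: float = DEFAULT_MIN_FIBER_LEN,
    max_len: float = DEFAULT_MAX_FIBER_LEN,
) -> FiberSet:
    """Keep fibers with ``min_len <= length <= max_len`` (inclusive bounds)."""
    if not (0 < min_len < max_len):
        raise InvalidArgumentError(f"need 0 < min_len < max_len, got [{min_len}, {max_len}]")
    keep = (fiber_set.length_mm >= min_len) & (fiber_set.length_mm <= max_len)
    return FiberSet(
        fiber_set.subject_id,
        fiber_set.region_u[keep],
        fiber_set.region_v[keep],
        fiber_set.length_mm[keep],
    )


def fiber_density(lengths_mm, s_u: float, s_v: float) -> float:
    """Fiber density 2/(S_u+S_v) * sum_f 1/l(f); zero for an empty fiber list."""
    lengths = np.asarray(lengths_mm, dtype=float)
    if s_u <= 0 or s_v <= 0:
        raise InvalidArgumentError("surface areas must be positive")
    if lengths.size == 0:
        return 0.0
    if np.any(lengths <= 0):
        raise InvalidArgumentError("fiber lengths must be positive")
    return float(2.0 / (s_u + s_v) * np.sum(1.0 / lengths))


def build_structural_matrix(
    fiber_set: FiberSet,
    atlas: Atlas,
    min_len: float = DEFAULT_MIN_FIBER_LEN,
    max_len: float = DEFAULT_MAX_FIBER_LEN,
) -> StructuralNetwork:
    """Length-filter fibers, pool them by unordered region pair, and fill the
    symmetric density matrix; the presence mask marks pairs with >= 1 surviving
    fiber.
    """
    n = atlas.n_regions
    ids = np.concatenate([fiber_set.region_u, fiber_set.region_v])
    if ids.size and (ids.min() < 0 or ids.max() >= n):
        bad = int(ids[(ids < 0) | (ids >= n)][0])
        raise ReferentialIntegrityError(f"fiber endpoint region {bad} not in atlas (n={n})")
    kept = filter_fibers(fiber_set, min_len, max_len)

    areas = atlas.surface_areas
    density = np.zeros((n, n), dtype=float)
    if len(kept):
        u = np.minimum(kept.region_u, kept.region_v)
        v = np.maximum(kept.region_u, kept.region_v)
        inv_len_sum = np.zeros((n, n), dtype=float)
        np.add.at(inv_len_sum, (u, v), 1.0 / kept.length_mm)
        iu, iv = np.nonzero(inv_len_sum)
        density[iu, iv] = 2.0 / (areas[iu] + areas[iv]) * inv_len_sum[iu, iv]
        density = density + density.T
    present = density > 0
    return StructuralNetwork(fiber_set.subject_id, density, present)
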