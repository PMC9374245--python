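"""Core containers for landmark-based morphometric data.

A specimen is a configuration of k homologous landmarks in d dimensions
(d = 2 for photographs, d = 3 for digitiser data).  Missing landmarks are
carried as NaN coordinates plus an explicit boolean mask and are excluded
from every size/shape computation until estimated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "unknown"


@dataclass
class LandmarkConfiguration:
    """One specimen's k x d landmark coordinate matrix with metadata.

    Missing landmarks hold NaN in ``coords`` and True in ``missing``.
    ``scale`` is physical units per coordinate unit (already applied to
    ``coords`` by the readers; kept for provenance).
    """

    specimen_id: str
    coords: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]
    scale: float = 1.0
    species: str = UNKNOWN
    sex: str = UNKNOWN
    part: str = UNKNOWN

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError(f"{self.specimen_id}: coords must be 2-D (k x d)")
        k, d = self.coords.shape
        if d not in (2, 3):
            raise ValueError(f"{self.specimen_id}: dimension must be 2 or 3, got {d}")
        if k < d:
            raise ValueError(f"{self.specimen_id}: need at least d={d} landmarks, got {k}")
        if self.missing is None:
            self.missing = np.any(np.isnan(self.coords), axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (k,):
            raise ValueError(f"{self.specimen_id}: missing mask must have length k={k}")
        if not np.all(np.isfinite(self.coords[~self.missing])):
            raise ValueError(f"{self.specimen_id}: non-missing coordinates must be finite")
        if not self.scale > 0:
            raise ValueError(f"{self.specimen_id}: scale must be positive")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def copy(self) -> "LandmarkConfiguration":
        return replace(self, coords=self.coords.copy(), missing=self.missing.copy())


@dataclass
class SliderSpec:
    """Semilandmark slider definitions as (before, slider, after) triplets.

    Indices are 0-based internally; file readers convert from the 1-based
    convention of the standard slider-file tools at the boundary.
    """

    triplets: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for t in self.triplets:
            if len(t) != 3:
                raise ValueError(f"slider triplet {t} must have 3 entries")
            before, slider, after = t
            if slider in (before, after):
                raise ValueError(f"slider {slider} coincides with an anchor in {t}")
            if slider in seen:
                raise ValueError(f"slider index {slider} appears in more than one triplet")
            seen.add(slider)

    def validate(self, k: int) -> None:
        for t in self.triplets:
            for idx in t:
                if not 0 <= idx < k:
                    raise ValueError(f"slider index {idx} out of range for k={k}")

    @property
    def slider_indices(self) -> np.ndarray:
        return np.array([t[1] for t in self.triplets], dtype=int)

    def __len__(self) -> int:
        return len(self.triplets)


@dataclass
class LandmarkDataset:
    """A homogeneous collection of landmark configurations (same k, d, scheme)."""

    configurations: list[LandmarkConfiguration]
    landmark_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset must contain at least one configuration")
        k, d = self.configurations[0].coords.shape
        for c in self.configurations:
            if c.coords.shape != (k, d):
                raise ValueError(
                    f"{c.specimen_id}: shape {c.coords.shape} differs from dataset ({k}, {d})"
                )
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        if not self.landmark_labels:
            self.landmark_labels = [f"LM{i + 1}" for i in range(k)]
        if len(self.landmark_labels) != k:
            raise ValueError("landmark_labels length must equal k")

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def d(self) -> int:
        return self.configurations[0].d

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __len__(self) -> int:
        return len(self.configurations)

    def __getitem__(self, specimen_id: str) -> LandmarkConfiguration:
        for c in self.configurations:
            if c.specimen_id == specimen_id:
                return c
        raise KeyError(specimen_id)

    def coords_array(self) -> np.ndarray:
        """Stack configurations into an n x k x d array; errors on missing landmarks."""
        for c in self.configurations:
            if not c.is_complete:
                raise ValueError(
                    f"{c.specimen_id} has missing landmarks; run estimate_missing first"
                )
        return np.stack([c.coords for c in self.configurations])

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": self.specimen_ids,
                "species": [c.species for c in self.configurations],
                "sex": [c.sex for c in self.configurations],
                "part": [c.part for c in self.configurations],
                "scale": [c.scale for c in self.configurations],
                "n_missing": [c.n_missing for c in self.configurations],
            }
        ).set_index("specimen_id")

    def subset(self, specimen_ids: Sequence[str]) -> "LandmarkDataset":
        wanted = list(specimen_ids)
        have = {c.specimen_id: c for c in self.configurations}
        missing = [s for s in wanted if s not in have]
        if missing:
            raise KeyError(f"specimens not in dataset: {missing}")
        return LandmarkDataset([have[s].copy() for s in wanted], list(self.landmark_labels))

    def drop_landmarks(self, indices: Sequence[int]) -> "LandmarkDataset":
        """Return a dataset without the given 0-based landmark indices."""
        drop = sorted(set(int(i) for i in indices))
        for i in drop:
            if not 0 <= i < self.k:
                raise IndexError(f"landmark index {i} out of range for k={self.k}")
        keep = [i for i in range(self.k) if i not in drop]
        configs = [
            replace(c, coords=c.coords[keep].copy(), missing=c.missing[keep].copy())
            for c in self.configurations
        ]
        labels = [self.landmark_labels[i] for i in keep]
        return LandmarkDataset(configs, labels)
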