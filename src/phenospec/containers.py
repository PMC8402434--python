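"""Shared in-memory containers for hyperspectral cubes, leaf masks and spectrum tables.

Conventions used throughout the package:

* cubes are ``(lines, samples, bands)`` float or integer arrays;
* wavelengths are in nanometres, strictly increasing, one per band;
* a :class:`SpectrumTable` holds one mean reflectance spectrum per row
  together with its group label (``BH`` before heat stress, ``AR``
  resistant after stress, ``AS`` susceptible after stress), variety and
  the number of leaf pixels averaged into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["HyperCube", "LeafMask", "SpectrumTable"]


@dataclass
class HyperCube:
    """A hyperspectral raster: two spatial dimensions plus one spectral.

    Parameters
    ----------
    data : ndarray, shape (lines, samples, bands)
        Raw counts or reflectance.
    wavelengths : ndarray, shape (bands,)
        Band centres in nm, strictly increasing.
    units : {"raw", "reflectance"}
        Whether ``data`` is detector counts or calibrated reflectance.
    metadata : dict
        Free-form acquisition metadata carried through I/O.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    units: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (lines, samples, bands), got {self.data.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match band dimension {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.units not in ("raw", "reflectance"):
            raise ValueError(f"units must be 'raw' or 'reflectance', got {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the grid band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class LeafMask:
    """Boolean leaf mask with optional per-leaf connected-component labels.

    ``labels`` uses 0 for background and 1..L for leaves, with no gaps.
    """

    pixels: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D (lines, samples)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.pixels.shape:
                raise ValueError("labels must share the mask's spatial shape")
            present = np.unique(self.labels[self.labels > 0])
            if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
                raise ValueError("leaf labels must be 1..L with no gaps")

    @property
    def n_leaves(self) -> int:
        if self.labels is None:
            return 1 if self.pixels.any() else 0
        return int(self.labels.max(initial=0))

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


class SpectrumTable:
    """Per-sample mean spectra with group/variety labels.

    Rows are samples (one leaf each), columns are bands. Wavelengths (nm)
    are shared by all rows.
    """

    def __init__(
        self,
        spectra: np.ndarray,
        wavelengths: np.ndarray,
        group: Sequence[str],
        variety: Sequence[str] | None = None,
        pixel_count: Sequence[int] | None = None,
        sample_id: Sequence[str] | None = None,
    ) -> None:
        self.spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        n = self.spectra.shape[0]
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra width must match wavelength count")
        if np.isnan(self.spectra).any():
            raise ValueError("spectra contain missing values")
        self.group = np.asarray(group, dtype=object)
        if self.group.size != n:
            raise ValueError("one group label per row required")
        self.variety = (
            np.asarray(variety, dtype=object) if variety is not None else np.full(n, "", dtype=object)
        )
        self.pixel_count = (
            np.asarray(pixel_count, dtype=int) if pixel_count is not None else np.ones(n, dtype=int)
        )
        self.sample_id = (
            np.asarray(sample_id, dtype=object)
            if sample_id is not None
            else np.asarray([f"s{i:04d}" for i in range(n)], dtype=object)
        )
        for name, arr in (("variety", self.variety), ("pixel_count", self.pixel_count), ("sample_id", self.sample_id)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length must equal the number of rows")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def take(self, idx: Iterable[int]) -> "SpectrumTable":
        idx = np.asarray(list(idx), dtype=int)
        return SpectrumTable(
            self.spectra[idx],
            self.wavelengths,
            self.group[idx],
            self.variety[idx],
            self.pixel_count[idx],
            self.sample_id[idx],
        )

    def group_subset(self, label: str) -> "SpectrumTable":
        return self.take(np.nonzero(self.group == label)[0])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra, columns=[f"{w:.3f}" for w in self.wavelengths])
        df.insert(0, "pixel_count", self.pixel_count)
        df.insert(0, "variety", self.variety)
        df.insert(0, "group", self.group)
        df.insert(0, "sample_id", self.sample_id)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        df = pd.read_csv(path)
        meta = ["sample_id", "group", "variety", "pixel_count"]
        wl = np.asarray([float(c) for c in df.columns if c not in meta])
        return cls(
            df[[c for c in df.columns if c not in meta]].to_numpy(float),
            wl,
            df["group"].astype(str).to_numpy(object),
            df["variety"].fillna("").astype(str).to_numpy(object),
            df["pixel_count"].to_numpy(int),
            df["sample_id"].astype(str).to_numpy(object),
        )
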