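"""Leaf segmentation, per-leaf mean spectra and calibration/validation splits.

Each segmented leaf is reduced to a single mean spectrum (one sample row),
mirroring the practice of averaging all pixels of a leaf before modelling.
Splits are stratified by group so calibration and validation preserve the
class balance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import HyperCube, LeafMask, SpectrumTable

__all__ = ["segment_leaf", "mean_spectra", "split_cal_val"]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def segment_leaf(
    cube: HyperCube,
    index_bands: tuple[float, float] = (800.0, 670.0),
    threshold: float = 0.3,
    min_pixels: int = 50,
    method: str = "ndvi",
) -> LeafMask:
    """Segment vegetation pixels and label individual leaves.

    ``method="ndvi"`` keeps pixels with ``(R_nir - R_red)/(R_nir + R_red) >
    threshold`` using the nearest grid bands to ``index_bands`` (defaults
    800/670 nm, suitable for Vis/NIR cubes). ``method="intensity"`` keeps
    pixels whose reflectance at ``index_bands[0]`` exceeds ``threshold``
    (for SWIR cubes, e.g. 1100 nm). Connected components (8-connectivity)
    smaller than ``min_pixels`` are dropped; surviving leaves are labelled
    1..L.
    """
    if method not in ("ndvi", "intensity"):
        raise ValueError("method must be 'ndvi' or 'intensity'")
    wl = cube.wavelengths
    for lam in (index_bands if method == "ndvi" else index_bands[:1]):
        if not (wl[0] <= lam <= wl[-1]):
            raise ValueError(f"index wavelength {lam} nm outside cube range {wl[0]:.0f}-{wl[-1]:.0f} nm")

    if method == "ndvi":
        nir = cube.data[:, :, cube.band_index(index_bands[0])].astype(float)
        red = cube.data[:, :, cube.band_index(index_bands[1])].astype(float)
        denom = nir + red
        with np.errstate(divide="ignore", invalid="ignore"):
            index = np.where(denom > 0, (nir - red) / denom, 0.0)
    else:
        index = cube.data[:, :, cube.band_index(index_bands[0])].astype(float)

    keep = index > threshold
    labels, n_comp = ndimage.label(keep, structure=_EIGHT_CONN)
    if n_comp:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
        small = np.nonzero(sizes < min_pixels)[0] + 1
        for lab in small:
            labels[labels == lab] = 0
        # relabel 1..L without gaps
        survivors = np.unique(labels[labels > 0])
        for new, old in enumerate(survivors, start=1):
            labels[labels == old] = new
        keep = labels > 0
    if not keep.any():
        raise ValueError(
            "segmentation produced an empty mask; lower the threshold or check the index bands"
        )
    return LeafMask(keep, labels)


def mean_spectra(
    cube: HyperCube,
    mask: LeafMask,
    group: str = "",
    variety: str = "",
) -> SpectrumTable:
    """Average each labelled leaf's pixels band-wise into one row per leaf."""
    if mask.pixels.shape != cube.data.shape[:2]:
        raise ValueError("mask spatial shape does not match the cube")
    if not mask.pixels.any():
        raise ValueError("mask is empty")
    labels = mask.labels if mask.labels is not None else mask.pixels.astype(int)
    ids = np.unique(labels[labels > 0])
    rows, counts = [], []
    for leaf in ids:
        sel = labels == leaf
        rows.append(cube.data[sel].mean(axis=0))
        counts.append(int(sel.sum()))
    n = len(rows)
    return SpectrumTable(
        np.vstack(rows),
        cube.wavelengths,
        [group] * n,
        [variety] * n,
        pixel_count=counts,
    )


def split_cal_val(
    table: SpectrumTable,
    cal_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    stratify_by: str = "group",
) -> tuple[SpectrumTable, SpectrumTable]:
    """Stratified random calibration/validation split.

    Per stratum the calibration count is ``round(cal_fraction * n)``
    (half-up); the remainder goes to validation. The two tables are
    disjoint and exhaustive, and the split is reproducible under ``seed``.
    """
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    strata = getattr(table, stratify_by)
    rng = np.random.default_rng(seed)
    cal_idx: list[int] = []
    val_idx: list[int] = []
    for label in dict.fromkeys(strata):  # first-appearance order, deterministic
        members = np.nonzero(strata == label)[0]
        if members.size < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 samples; cannot split")
        n_cal = int(np.floor(cal_fraction * members.size + 0.5))
        n_cal = min(max(n_cal, 1), members.size - 1)
        perm = rng.permutation(members)
        cal_idx.extend(perm[:n_cal].tolist())
        val_idx.extend(perm[n_cal:].tolist())
    return table.take(sorted(cal_idx)), table.take(sorted(val_idx))
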