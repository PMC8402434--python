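"""Continuous class codes for multi-group PLS-DA.

With three or more groups and no measurable response variable, PLS-DA
needs scalar reference codes (Y values) per group. Two schemes are
implemented:

* **BPV** (best projection value): fit a linear discriminant analysis,
  project all samples onto the leading discriminant axis, take each
  group's centre (the mean of a Gaussian fit to its projection histogram)
  and rescale so that the reference group sits at 0 and the farthest
  group at 100.
* **SPRI** (sequential placement at regular intervals): keep only the
  *order* of the group centres and place codes at equal spacing
  (0, 50, 100 for three groups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .containers import SpectrumTable

__all__ = [
    "LDAModel",
    "GroupEncoding",
    "fit_lda",
    "best_projection_values",
    "encode_groups_bpv",
    "encode_groups_spri",
]


@dataclass
class LDAModel:
    """Fitted linear discriminant directions for group-structured spectra.

    ``discriminant_axes`` columns are unit-norm generalized eigenvectors of
    the between- vs (shrunk) within-class scatter, sorted by decreasing
    eigenvalue. Signs are fixed so the reference group's centre is the
    minimum along each axis.
    """

    discriminant_axes: np.ndarray  # (n_bands, n_axes)
    eigenvalues: np.ndarray
    group_centers_1d: dict[str, float]
    chosen_axis: int
    centering_vector: np.ndarray
    shrinkage: float
    groups: tuple[str, ...]
    reference_group: str


@dataclass
class GroupEncoding:
    """Mapping of group labels to scalar class codes in [0, 100]."""

    scheme: str  # {"BPV", "SPRI"}
    codes: dict[str, float]
    reference_group: str
    group_order: tuple[str, ...] = ()
    centers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in ("BPV", "SPRI"):
            raise ValueError("scheme must be 'BPV' or 'SPRI'")
        if not self.group_order:
            self.group_order = tuple(sorted(self.codes, key=self.codes.get))
        vals = list(self.codes.values())
        if len(set(vals)) != len(vals):
            raise ValueError("class codes must be distinct")

    @property
    def code_array(self) -> np.ndarray:
        return np.asarray([self.codes[g] for g in self.group_order], dtype=float)

    def codes_for(self, groups: Sequence[str]) -> np.ndarray:
        return np.asarray([self.codes[g] for g in groups], dtype=float)

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme,
            "reference_group": self.reference_group,
            "codes": {g: float(c) for g, c in self.codes.items()},
            "group_order": list(self.group_order),
            "centers": {g: float(c) for g, c in self.centers.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def fit_lda(table: SpectrumTable, shrinkage: float = 0.1, reference_group: str = "BH") -> LDAModel:
    """Fit LDA discriminant axes to a labelled spectrum table.

    The within-class scatter is regularized as ``(1 - shrinkage) * S_W +
    shrinkage * diag(S_W)`` — with ~128 highly correlated bands the raw
    scatter is ill-conditioned. Axes solve the generalized eigenproblem
    for between- vs within-class scatter.
    """
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    X = table.spectra
    groups = table.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if int((table.group == g).sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if len(table) <= len(groups):
        raise ValueError("need more samples than groups")
    if reference_group not in groups:
        reference_group = groups[0]

    n_bands = X.shape[1]
    mu = X.mean(axis=0)
    s_w = np.zeros((n_bands, n_bands))
    s_b = np.zeros((n_bands, n_bands))
    for g in groups:
        Xg = X[table.group == g]
        mg = Xg.mean(axis=0)
        dev = Xg - mg
        s_w += dev.T @ dev
        dm = (mg - mu)[:, None]
        s_b += Xg.shape[0] * (dm @ dm.T)

    s_w_reg = (1.0 - shrinkage) * s_w + shrinkage * np.diag(np.diag(s_w))
    try:
        evals, evecs = scipy.linalg.eigh(s_b, s_w_reg)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; increase shrinkage above 0"
        ) from err

    order = np.argsort(evals)[::-1]
    n_axes = min(len(groups) - 1, n_bands)
    evals = evals[order][:n_axes]
    axes = evecs[:, order][:, :n_axes]
    axes = axes / np.linalg.norm(axes, axis=0, keepdims=True)

    # sign-fix each axis so the reference group's centre is the axis minimum
    centers_by_axis = {}
    for g in groups:
        centers_by_axis[g] = (X[table.group == g].mean(axis=0) - mu) @ axes
    for k in range(n_axes):
        cvals = np.asarray([centers_by_axis[g][k] for g in groups])
        ref_val = centers_by_axis[reference_group][k]
        if ref_val > cvals.mean():
            axes[:, k] *= -1.0
            for g in groups:
                centers_by_axis[g][k] *= -1.0

    chosen = 0  # largest eigenvalue
    centers_1d = {g: float(centers_by_axis[g][chosen]) for g in groups}
    return LDAModel(
        discriminant_axes=axes,
        eigenvalues=evals,
        group_centers_1d=centers_1d,
        chosen_axis=chosen,
        centering_vector=mu,
        shrinkage=shrinkage,
        groups=tuple(groups),
        reference_group=reference_group,
    )


def best_projection_values(model: LDAModel, data) -> np.ndarray:
    """Project centered spectra onto the chosen discriminant axis (BPV)."""
    X = data.spectra if isinstance(data, SpectrumTable) else np.atleast_2d(np.asarray(data, float))
    if X.shape[1] != model.centering_vector.size:
        raise ValueError(
            f"band mismatch: model expects {model.centering_vector.size} bands, got {X.shape[1]}"
        )
    return (X - model.centering_vector) @ model.discriminant_axes[:, model.chosen_axis]


def encode_groups_bpv(
    bpv_values: np.ndarray,
    groups: Sequence[str],
    reference_group: str = "BH",
) -> GroupEncoding:
    """Class codes from group centres on the BPV axis, rescaled to [0, 100].

    Each group's centre is the mean of a Gaussian fit to its BPV histogram
    (identical to the sample mean). The reference group maps to 0 and the
    group farthest from it to 100; intermediate groups scale linearly and
    codes are rounded to the nearest integer.
    """
    bpv_values = np.asarray(bpv_values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = list(dict.fromkeys(groups))
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not present")
    centers: dict[str, float] = {}
    for g in labels:
        vals = bpv_values[groups == g]
        if vals.size < 3:
            raise ValueError(f"group {g!r} needs at least 3 samples for a centre estimate")
        centers[g] = float(vals.mean())

    cvals = np.asarray(list(centers.values()))
    if np.min(np.abs(np.subtract.outer(cvals, cvals))[~np.eye(len(cvals), dtype=bool)]) < 1e-9:
        raise ValueError("two group centres coincide; BPV encoding is degenerate")

    c_ref = centers[reference_group]
    far = max(labels, key=lambda g: abs(centers[g] - c_ref))
    span = centers[far] - c_ref
    codes = {g: float(round(100.0 * (centers[g] - c_ref) / span)) for g in labels}
    return GroupEncoding(
        scheme="BPV",
        codes=codes,
        reference_group=reference_group,
        group_order=tuple(sorted(labels, key=codes.get)),
        centers=centers,
    )


def encode_groups_spri(group_order: Sequence[str]) -> GroupEncoding:
    """Codes at equal intervals 0, 100/(G-1), ..., 100 in the given order."""
    order = list(group_order)
    if len(order) != len(set(order)):
        raise ValueError("duplicate group labels in group_order")
    if len(order) < 2:
        raise ValueError("need at least 2 groups")
    step = 100.0 / (len(order) - 1)
    codes = {g: round(i * step, 10) for i, g in enumerate(order)}
    return GroupEncoding(
        scheme="SPRI",
        codes=codes,
        reference_group=order[0],
        group_order=tuple(order),
    )
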