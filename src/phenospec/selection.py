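"""Ensemble waveband selection: VIP threshold filter followed by SPA.

The full-spectrum PLS-DA model's VIP scores first screen the bands
(keep VIP >= threshold; 1.0 is the conventional cut because the mean
squared VIP is exactly 1). The successive projections algorithm (SPA)
then walks the surviving candidates: starting from each candidate it
greedily appends the band whose column is least collinear with the span
of the bands already chosen (maximal norm after projection onto the
orthogonal complement), producing candidate chains of every length.
Each chain is scored by refitting PLS1 on its bands and measuring the
misclassification rate on the validation split; the best (fewest errors,
then shortest, then lowest start) chain wins, capped below 20 bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import GroupEncoding
from .pls import choose_n_lv, classify, fit_pls1, predict

__all__ = ["BandSelection", "SPAChain", "vip_filter", "spa_chain", "spa_select", "ensemble_select"]


@dataclass
class SPAChain:
    """Ordered SPA selection; ``exhausted`` flags an early rank-limited stop."""

    indices: list[int]
    exhausted: bool = False

    def __iter__(self):
        return iter(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class BandSelection:
    """Outcome of (VIP ->) SPA selection.

    ``selected_indices`` index the original band grid and are in chain
    order; ``criterion_trace`` records ``(start, size, val_errors)`` for
    every candidate chain evaluated.
    """

    selected_indices: list[int]
    selected_wavelengths: np.ndarray | None
    vip_scores: np.ndarray | None
    criterion_trace: list[tuple[int, int, int]]
    scheme: str
    candidate_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected band indices must be unique")
        if len(self.selected_indices) > 20:
            raise ValueError("selection exceeds the 20-band cap")

    def __len__(self) -> int:
        return len(self.selected_indices)

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme,
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_wavelengths_nm": (
                None if self.selected_wavelengths is None
                else [float(w) for w in self.selected_wavelengths]
            ),
            "candidate_indices": [int(i) for i in self.candidate_indices],
            "vip_scores": None if self.vip_scores is None else [float(v) for v in self.vip_scores],
            "criterion_trace": [[int(a), int(b), int(c)] for a, b, c in self.criterion_trace],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_wavelengths(self, path) -> None:
        """Plain text list of the selected wavelengths, one per line (nm)."""
        if self.selected_wavelengths is None:
            raise ValueError("selection has no wavelength grid attached")
        with open(path, "w") as fh:
            for w in self.selected_wavelengths:
                fh.write(f"{float(w):.3f}\n")


def vip_filter(vip_scores: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Indices of bands with VIP >= threshold, in wavelength order."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vip_scores = np.asarray(vip_scores, dtype=float)
    keep = np.nonzero(vip_scores >= threshold)[0]
    if keep.size == 0:
        raise ValueError(
            f"no band reaches VIP {threshold}; lower the threshold (max VIP = {vip_scores.max():.3f})"
        )
    return keep


def spa_chain(X: np.ndarray, start_index: int, m_max: int) -> SPAChain:
    """Greedy successive-projections chain over the columns of ``X``.

    Beginning at ``start_index``, each step projects all unselected
    columns onto the orthogonal complement of the span of the selected
    ones and appends the column of maximal projected norm. Stops at
    ``m_max`` or when all residual norms fall below 1e-12 (rank
    exhausted; flagged).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_index < p:
        raise ValueError("start_index out of range")
    if m_max < 1 or m_max > min(n, p):
        raise ValueError(f"m_max must be in [1, {min(n, p)}]")

    R = X.copy()
    chain = [start_index]
    for _ in range(m_max - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            return SPAChain(chain, exhausted=True)
        u = v / nv
        R = R - np.outer(u, u @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 1e-12:
            return SPAChain(chain, exhausted=True)
        chain.append(j)
    return SPAChain(chain, exhausted=False)


def _n_lv_for(m: int, n_samples: int) -> int:
    # deterministic per-chain component count: bounded by chain length and data
    return max(1, min(m, 10, n_samples - 1))


def spa_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    m_min: int = 8,
    m_max: int = 20,
    encoding: GroupEncoding | None = None,
    groups_val: np.ndarray | None = None,
) -> BandSelection:
    """Best SPA chain over all start columns and sizes in [m_min, m_max].

    Chains are scored by validation misclassification under ``encoding``
    (predicted scores mapped to the nearest class code). Ties break
    toward the smaller size, then the smaller start index. ``yval`` must
    hold exact class codes unless ``groups_val`` labels are supplied.
    """
    if encoding is None:
        raise ValueError("an encoding is required to score chains by classification")
    Xcal = np.asarray(Xcal, float)
    Xval = np.asarray(Xval, float)
    ycal = np.asarray(ycal, float).ravel()
    yval = np.asarray(yval, float).ravel()
    n, p = Xcal.shape
    m_max = min(m_max, 20, n - 1, p)
    m_min = max(2, min(m_min, m_max))

    if groups_val is None:
        groups_val = classify(yval, encoding)  # exact codes map back to their own label
    groups_val = np.asarray(groups_val, dtype=object)

    Xc = Xcal - Xcal.mean(axis=0)
    best: tuple[int, int, int] | None = None  # (errors, m, start)
    best_chain: list[int] = []
    trace: list[tuple[int, int, int]] = []
    for start in range(p):
        chain = spa_chain(Xc, start, m_max)
        for m in range(m_min, len(chain.indices) + 1):
            bands = chain.indices[:m]
            model = fit_pls1(Xcal[:, bands], ycal, _n_lv_for(m, n))
            pred = classify(predict(model, Xval[:, bands]), encoding)
            errors = int((pred != groups_val).sum())
            trace.append((start, m, errors))
            key = (errors, m, start)
            if best is None or key < best:
                best, best_chain = key, list(bands)
    if best is None:
        raise ValueError("no candidate chain satisfied the size constraints")

    return BandSelection(
        selected_indices=best_chain,
        selected_wavelengths=None,
        vip_scores=None,
        criterion_trace=trace,
        scheme=encoding.scheme,
        candidate_indices=list(range(p)),
    )


def ensemble_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    encoding: GroupEncoding,
    wavelengths: np.ndarray | None = None,
    vip_threshold: float = 1.0,
    m_min: int = 8,
    m_max: int = 20,
    n_lv: int | None = None,
    max_lv: int = 15,
    folds: int = 5,
    seed: int = 0,
    groups_val: np.ndarray | None = None,
) -> BandSelection:
    """Full-spectrum PLS1 -> VIP filter -> SPA search on the candidates.

    Returns the winning chain mapped back to original band indices, with
    the full-spectrum VIP scores and the candidate set attached.
    """
    from .pls import vip as vip_scores_fn  # local import avoids cycle at module load

    Xcal = np.asarray(Xcal, float)
    ycal = np.asarray(ycal, float).ravel()
    if n_lv is None:
        n_lv = choose_n_lv(Xcal, ycal, max_lv=max_lv, folds=folds, seed=seed)
    full = fit_pls1(Xcal, ycal, n_lv)
    scores = vip_scores_fn(full)
    candidates = vip_filter(scores, vip_threshold)

    sel = spa_select(
        Xcal[:, candidates], ycal, np.asarray(Xval, float)[:, candidates], yval,
        m_min=m_min, m_max=m_max, encoding=encoding, groups_val=groups_val,
    )
    original = [int(candidates[i]) for i in sel.selected_indices]
    return BandSelection(
        selected_indices=original,
        selected_wavelengths=None if wavelengths is None else np.asarray(wavelengths, float)[original],
        vip_scores=scores,
        criterion_trace=[(int(candidates[s]), m, e) for s, m, e in sel.criterion_trace],
        scheme=encoding.scheme,
        candidate_indices=[int(c) for c in candidates],
    )
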