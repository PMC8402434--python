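"""PLS1 discriminant analysis against continuous class codes.

The model is single-response partial least squares (NIPALS/PLS1) fitted to
mean-centered spectra X and scalar class codes y (the BPV or SPRI
encoding). Classification assigns a predicted score to the group with the
nearest code. Variable importance in projection (VIP) scores summarize
each band's contribution:

    VIP_j = sqrt( J * sum_f [ (w_jf / ||w_f||)^2 * SSY_f ] / sum_f SSY_f )

where w_f are the component weights, SSY_f the response sum of squares
explained by component f, and J the number of bands; mean(VIP^2) = 1.

Two API levels are provided: plain functions (:func:`fit_pls1`,
:func:`vip`, :func:`classify`, ...) and a model/results pair
(:class:`PLSDiscriminant` / :class:`PLSDAResults`) in the style of
statsmodels, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import SpectrumTable
from .encoding import GroupEncoding

__all__ = [
    "PLSModel",
    "AccuracyTable",
    "fit_pls1",
    "beta_for_components",
    "choose_n_lv",
    "predict",
    "classify",
    "accuracy_table",
    "vip",
    "PLSDiscriminant",
    "PLSDAResults",
]


@dataclass
class PLSModel:
    """Centered PLS1 factorization and derived regression vector.

    ``weights`` (W), ``loadings`` (P) are (n_bands, F); ``y_loadings`` (q)
    has one entry per component; ``scores`` (T) is (n_samples, F).
    ``ssy_f[f]`` is the centered-response sum of squares explained by
    component f and ``ssy_total`` the total centered sum of squares.
    """

    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    beta: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    ssy_f: np.ndarray
    ssy_total: float
    n_lv: int
    wavelengths: np.ndarray | None = None

    @property
    def n_bands(self) -> int:
        return self.weights.shape[0]


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int, wavelengths: np.ndarray | None = None) -> PLSModel:
    """Fit PLS1 by NIPALS deflation on mean-centered X and y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    if np.ptp(y) == 0:
        raise ValueError("response y is constant; PLS1 undefined")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    ssy_total = float(yc @ yc)

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    ssy = np.zeros(n_lv)

    Xf, yf = Xc.copy(), yc.copy()
    used = n_lv
    for f in range(n_lv):
        w = Xf.T @ yf
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            used = f
            break
        w /= nw
        t = Xf @ w
        tt = float(t @ t)
        if tt < 1e-14:
            used = f
            break
        p_f = Xf.T @ t / tt
        q_f = float(yf @ t) / tt
        W[:, f], P[:, f], q[f], T[:, f] = w, p_f, q_f, t
        ssy[f] = q_f**2 * tt
        Xf -= np.outer(t, p_f)
        yf -= q_f * t
    if used == 0:
        raise ValueError("X carries no covariance with y; cannot extract a component")
    W, P, q, T, ssy = W[:, :used], P[:, :used], q[:used], T[:, :used], ssy[:used]

    beta = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(W, P, q, T, beta, x_mean, y_mean, ssy, ssy_total, used,
                    None if wavelengths is None else np.asarray(wavelengths, float))


def beta_for_components(model: PLSModel, k: int) -> np.ndarray:
    """Regression vector using only the first ``k`` components."""
    if not 1 <= k <= model.n_lv:
        raise ValueError(f"k must be in [1, {model.n_lv}]")
    W, P, q = model.weights[:, :k], model.loadings[:, :k], model.y_loadings[:k]
    return W @ np.linalg.solve(P.T @ W, q)


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Continuous class-code predictions: (x - x_mean) . beta + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_bands:
        raise ValueError(f"band mismatch: model has {model.n_bands} bands, data has {X.shape[1]}")
    return (X - model.x_mean) @ model.beta + model.y_mean


def choose_n_lv(X: np.ndarray, y: np.ndarray, max_lv: int = 15, folds: int = 5, seed: int = 0) -> int:
    """Parsimonious latent-variable count by k-fold cross-validation.

    Returns the smallest component count whose cross-validated RMSEP is
    within 2% of the global minimum over 1..max_lv.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, n)
    max_lv = min(max_lv, n - int(np.ceil(n / folds)) - 1, X.shape[1])
    max_lv = max(max_lv, 1)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds

    press = np.zeros(max_lv)
    for f in range(folds):
        test = fold_of == f
        model = fit_pls1(X[~test], y[~test], max_lv)
        Xt = X[test] - model.x_mean
        for k in range(1, model.n_lv + 1):
            resid = y[test] - (Xt @ beta_for_components(model, k) + model.y_mean)
            press[k - 1] += float(resid @ resid)
        for k in range(model.n_lv + 1, max_lv + 1):  # rank-exhausted folds reuse the last beta
            resid = y[test] - (Xt @ model.beta + model.y_mean)
            press[k - 1] += float(resid @ resid)

    rmsep = np.sqrt(press / n)
    best = float(rmsep.min())
    # absolute slack keeps the rule stable when RMSEP is at machine-noise level
    tol = 1.02 * best + 1e-12 * max(1.0, float(np.abs(y).max()))
    for k in range(1, max_lv + 1):
        if rmsep[k - 1] <= tol:
            return k
    return max_lv


def classify(scores: np.ndarray, encoding: GroupEncoding) -> np.ndarray:
    """Assign each predicted score to the group with the nearest code.

    Ties break toward the lower code (the less-stressed end of the scale).
    """
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    order = sorted(encoding.codes, key=encoding.codes.get)
    codes = np.asarray([encoding.codes[g] for g in order])
    dist = np.abs(scores[:, None] - codes[None, :])
    idx = np.argmin(dist, axis=1)  # first (lowest-code) minimum wins ties
    return np.asarray([order[i] for i in idx], dtype=object)


def _round_half_up(x: float, decimals: int = 1) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(f"1e-{decimals}"), rounding=ROUND_HALF_UP))


@dataclass
class AccuracyTable:
    """Per-group and macro-averaged classification accuracy accounting.

    ``overall`` is the unweighted (macro) mean of the per-group accuracies,
    computed on unrounded values; display rounds half-up to one decimal.
    """

    group_order: tuple[str, ...]
    total: dict[str, int]
    correct: dict[str, int]

    def accuracy(self, group: str) -> float:
        return 100.0 * self.correct[group] / self.total[group]

    @property
    def overall(self) -> float:
        return float(np.mean([self.accuracy(g) for g in self.group_order]))

    def accuracy_display(self, group: str) -> float:
        return _round_half_up(self.accuracy(group))

    @property
    def overall_display(self) -> float:
        return _round_half_up(self.overall)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "total": self.total[g],
                "correct": self.correct[g],
                "accuracy_pct": self.accuracy_display(g),
            }
            for g in self.group_order
        ]
        rows.append({"group": "Overall", "total": sum(self.total.values()),
                     "correct": sum(self.correct.values()), "accuracy_pct": self.overall_display})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "group_order": list(self.group_order),
            "total": dict(self.total),
            "correct": dict(self.correct),
            "accuracy_pct": {g: self.accuracy_display(g) for g in self.group_order},
            "overall_pct": self.overall_display,
        }


def accuracy_table(predicted: Sequence[str], truth: Sequence[str], group_order: Sequence[str]) -> AccuracyTable:
    """Tally per-group correct counts and accuracies for a prediction run."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.size != truth.size:
        raise ValueError("predicted and truth lengths differ")
    extra = set(truth) - set(group_order)
    if extra:
        raise ValueError(f"truth contains labels outside group_order: {sorted(extra)}")
    total, correct = {}, {}
    for g in group_order:
        sel = truth == g
        if not sel.any():
            raise ValueError(f"group {g!r} has no samples in truth")
        total[g] = int(sel.sum())
        correct[g] = int((predicted[sel] == g).sum())
    return AccuracyTable(tuple(group_order), total, correct)


def vip(model: PLSModel) -> np.ndarray:
    """Variable-importance-in-projection score per band (mean square = 1)."""
    W = model.weights
    norms = np.linalg.norm(W, axis=0)
    if np.all(model.ssy_f == 0):
        raise ValueError("no explained response variance; VIP undefined")
    Wn = W / norms[None, :]
    J = model.n_bands
    scores = np.sqrt(J * (Wn**2 @ model.ssy_f) / model.ssy_f.sum())
    return scores


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class PLSDiscriminant:
    """PLS-DA model: spectra + class codes, fitted by :meth:`fit`.

    Parameters
    ----------
    spectra : ndarray (n_samples, n_bands)
    groups : sequence of str
        Per-sample group labels.
    encoding : GroupEncoding
        BPV or SPRI mapping of labels to scalar codes.
    wavelengths : ndarray, optional

    Examples
    --------
    >>> model = PLSDiscriminant.from_table(cal_table, encoding)   # doctest: +SKIP
    >>> res = model.fit(max_lv=15, folds=5, seed=0)               # doctest: +SKIP
    >>> print(res.summary())                                      # doctest: +SKIP
    """

    def __init__(
        self,
        spectra: np.ndarray,
        groups: Sequence[str],
        encoding: GroupEncoding,
        wavelengths: np.ndarray | None = None,
    ) -> None:
        self.spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        self.groups = np.asarray(groups, dtype=object)
        if self.groups.size != self.spectra.shape[0]:
            raise ValueError("one group label per spectrum required")
        self.encoding = encoding
        self.wavelengths = None if wavelengths is None else np.asarray(wavelengths, float)
        self.y = encoding.codes_for(self.groups)

    @classmethod
    def from_table(cls, table: SpectrumTable, encoding: GroupEncoding) -> "PLSDiscriminant":
        return cls(table.spectra, table.group, encoding, table.wavelengths)

    def fit(self, n_lv: int | None = None, max_lv: int = 15, folds: int = 5, seed: int = 0) -> "PLSDAResults":
        """Fit PLS1; when ``n_lv`` is None it is chosen by cross-validation."""
        if n_lv is None:
            n_lv = choose_n_lv(self.spectra, self.y, max_lv=max_lv, folds=folds, seed=seed)
        pls = fit_pls1(self.spectra, self.y, n_lv, wavelengths=self.wavelengths)
        return PLSDAResults(self, pls)


class PLSDAResults:
    """Fitted PLS-DA results: coefficients, VIP, classification, accuracy."""

    def __init__(self, model: PLSDiscriminant, pls: PLSModel) -> None:
        self.model = model
        self.pls = pls

    @property
    def params(self) -> np.ndarray:
        """Regression coefficients (beta) on centered spectra."""
        return self.pls.beta

    @property
    def n_lv(self) -> int:
        return self.pls.n_lv

    def predict(self, X=None) -> np.ndarray:
        X = self.model.spectra if X is None else X
        if isinstance(X, SpectrumTable):
            X = X.spectra
        return predict(self.pls, X)

    def classify(self, X=None) -> np.ndarray:
        return classify(self.predict(X), self.model.encoding)

    def vip(self) -> np.ndarray:
        return vip(self.pls)

    def accuracy(self, table: SpectrumTable | None = None) -> AccuracyTable:
        if table is None:
            pred, truth = self.classify(), self.model.groups
        else:
            pred, truth = self.classify(table), table.group
        return accuracy_table(pred, truth, self.model.encoding.group_order)

    def explained_y_variance(self) -> np.ndarray:
        """Fraction of centered response variance explained per component."""
        return self.pls.ssy_f / self.pls.ssy_total

    def summary(self, val_table: SpectrumTable | None = None) -> str:
        enc = self.model.encoding
        lines = [
            "PLS discriminant analysis (PLS1 on class codes)",
            "=" * 56,
            f"scheme: {enc.scheme}    latent variables: {self.n_lv}    "
            f"bands: {self.pls.n_bands}",
            "codes:  " + ", ".join(f"{g}={enc.codes[g]:g}" for g in enc.group_order),
            f"explained Y variance: "
            + " ".join(f"{v:.3f}" for v in self.explained_y_variance()),
            "",
            "Calibration accuracy",
            self.accuracy().to_dataframe().to_string(index=False),
        ]
        if val_table is not None:
            lines += ["", "Validation accuracy",
                      self.accuracy(val_table).to_dataframe().to_string(index=False)]
        return "\n".join(lines)
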