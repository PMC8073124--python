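"""Chemometric layer: Kennard–Stone splitting, a PLS core with nested
per-component regression coefficients, LOOCV curves, the latent-variable
selection rules, PLS-DA assignment, and error metrics.

The PLS core is a mean-centered PLS1 NIPALS fit.  A single fit with
``lv_max`` components yields the regression coefficient vector for every
truncation 1..lv_max, so a LOOCV curve over latent variables costs one
fit per fold.  Multi-column responses (the one-vs-all class-membership
matrix of PLS-DA) are fitted as independent PLS1 sub-models sharing a
latent-variable count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import SpectraSet

logger = logging.getLogger(__name__)

#: Fixed class order: benign, primary tumor, then the metastatic lines.
CLASS_ORDER = ("RWPE-1", "22Rv1", "PC3", "Du145", "LNCaP")

#: Ordinal disease-progression coding used as the PLSR response.
PROGRESSION_CODING = {"RWPE-1": -2, "22Rv1": -1, "PC3": 0, "Du145": 1, "LNCaP": 2}


def regression_target(labels, coding: dict | None = None) -> np.ndarray:
    """Map class labels to the ordinal progression coding (−2..2)."""
    coding = PROGRESSION_CODING if coding is None else coding
    try:
        return np.array([coding[l] for l in labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"label {exc} has no regression coding")


def membership_matrix(labels, class_order=None) -> np.ndarray:
    """0/1 class-membership matrix (n_objects × n_classes); rows sum to 1."""
    labels = np.asarray(labels)
    if class_order is None:
        class_order = [c for c in CLASS_ORDER if c in labels]
        if not class_order:
            class_order = sorted(np.unique(labels))
    out = np.zeros((labels.size, len(class_order)))
    for j, c in enumerate(class_order):
        out[labels == c, j] = 1.0
    if not np.allclose(out.sum(axis=1), 1.0):
        raise ValueError("every label must appear in class_order")
    return out


# ---------------------------------------------------------------------------
# Kennard–Stone splitting


@dataclass(frozen=True)
class SplitAssignment:
    model_ids: tuple
    test_ids: tuple
    fraction: float = 0.75


def _kennard_stone_indices(x: np.ndarray, n_select: int) -> list[int]:
    """Classic max-min selection: seed with the most distant pair, then
    repeatedly add the candidate whose minimum distance to the selected
    set is largest.  Fully deterministic (first index wins ties)."""
    n = x.shape[0]
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_select:
        min_dist[selected] = -1.0
        k = int(np.argmax(min_dist))
        selected.append(k)
        min_dist = np.minimum(min_dist, d[k])
    return selected[:n_select]


def kennard_stone_split(spectra: SpectraSet, fraction: float = 0.75) -> SplitAssignment:
    """Per-class Kennard–Stone split: within each class independently,
    select floor(fraction·class size) spectra into the model set by
    max-min Euclidean distance; the remainder form the test set."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    model_ids, test_ids = [], []
    for cls in _class_order_of(spectra.labels):
        rows = np.where(spectra.labels == cls)[0]
        if rows.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_select = int(np.floor(fraction * rows.size))
        if n_select >= rows.size:
            warnings.warn(f"class {cls!r}: all members selected into the model set")
            n_select = rows.size
        if n_select < 1:
            n_select = 1
        chosen = _kennard_stone_indices(spectra.absorbance[rows], n_select)
        chosen_rows = set(rows[chosen])
        model_ids += [spectra.ids[r] for r in rows if r in chosen_rows]
        test_ids += [spectra.ids[r] for r in rows if r not in chosen_rows]
    return SplitAssignment(tuple(model_ids), tuple(test_ids), fraction)


def _class_order_of(labels) -> list:
    known = [c for c in CLASS_ORDER if c in labels]
    rest = [c for c in dict.fromkeys(np.asarray(labels).tolist()) if c not in known]
    return known + rest


# ---------------------------------------------------------------------------
# PLS core


@dataclass(frozen=True)
class PLSModel:
    """PLS1 NIPALS fit with nested coefficients.

    ``betas`` has shape (n_responses, lv_max, n_variables): the regression
    coefficient vector for every truncation to 1..lv_max components.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    betas: np.ndarray
    n_lv: int

    @property
    def beta(self) -> np.ndarray:
        """Coefficients at the fitted component count (n_responses × p)."""
        return self.betas[:, self.n_lv - 1, :]


def _pls1_nested_betas(xc: np.ndarray, yc: np.ndarray, lv_max: int) -> np.ndarray:
    """Return (lv_max × p) betas for truncations 1..lv_max of a PLS1 fit."""
    n, p = xc.shape
    w_mat = np.zeros((p, lv_max))
    p_mat = np.zeros((p, lv_max))
    q = np.zeros(lv_max)
    xk = xc.copy()
    yk = yc.copy()
    betas = np.zeros((lv_max, p))
    last = np.zeros(p)
    for k in range(lv_max):
        w = xk.T @ yk
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # response fully deflated; later LVs add nothing
            betas[k:] = last
            return betas
        w /= norm
        t = xk @ w
        tt = t @ t
        p_load = xk.T @ t / tt
        q[k] = yk @ t / tt
        xk -= np.outer(t, p_load)
        yk -= q[k] * t
        w_mat[:, k] = w
        p_mat[:, k] = p_load
        r = np.linalg.solve(p_mat[:, : k + 1].T @ w_mat[:, : k + 1], q[: k + 1])
        last = w_mat[:, : k + 1] @ r
        betas[k] = last
    return betas


def pls_fit(x: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Mean-centered PLS fit; vector y gives one response, a matrix gives
    independent PLS1 sub-models per column (shared component count)."""
    x = np.asarray(x, dtype=float)
    y2 = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, n_responses)
    n, p = x.shape
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, min(n−1, p)] = [1, {min(n - 1, p)}]")
    x_mean = x.mean(axis=0)
    y_mean = y2.mean(axis=0)
    xc = x - x_mean
    betas = np.stack([_pls1_nested_betas(xc, y2[:, j] - y_mean[j], n_lv) for j in range(y2.shape[1])])
    return PLSModel(x_mean, y_mean, betas, n_lv)


def pls_predict(model: PLSModel, x: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """ŷ = (X − x̄)·β + ȳ at the chosen truncation (default: fitted n_lv).
    Returns (n, n_responses); squeezed to (n,) for a single response."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.x_mean.size:
        raise ValueError("column count does not match the fitted model")
    k = model.n_lv if n_lv is None else n_lv
    if not 1 <= k <= model.betas.shape[1]:
        raise ValueError(f"n_lv must be in [1, {model.betas.shape[1]}]")
    pred = (x - model.x_mean) @ model.betas[:, k - 1, :].T + model.y_mean
    return pred[:, 0] if pred.shape[1] == 1 else pred


# ---------------------------------------------------------------------------
# LOOCV curves and latent-variable selection


def _clamp_lv(lv_max: int, n: int, p: int) -> int:
    cap = min(n - 2, p)  # each LOO fold has n−1 samples, so ≤ n−2 components
    if lv_max > cap:
        warnings.warn(f"lv_max {lv_max} clamped to {cap}")
        return cap
    return lv_max


def loocv_curve_regression(x: np.ndarray, y: np.ndarray, lv_max: int = 8) -> np.ndarray:
    """RMSECV for each latent-variable count 1..lv_max (leave-one-out)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    lv_max = _clamp_lv(lv_max, n, x.shape[1])
    sq_err = np.zeros((lv_max, n))
    for i in range(n):
        mask = np.arange(n) != i
        model = pls_fit(x[mask], y[mask], lv_max)
        for k in range(1, lv_max + 1):
            sq_err[k - 1, i] = float(pls_predict(model, x[i], n_lv=k)[0] - y[i]) ** 2
    return np.sqrt(sq_err.mean(axis=1))


def select_lv_regression(rmsecv: np.ndarray) -> int:
    """Latent-variable rule for regression: the smallest LV whose RMSECV is
    a local minimum followed by two strictly higher values; otherwise the
    global-minimum LV.  Returns a 1-based LV index."""
    r = np.asarray(rmsecv, dtype=float)
    for m in range(len(r) - 2):
        if r[m] < r[m + 1] and r[m] < r[m + 2]:
            return m + 1
    return int(np.argmin(r)) + 1


def loocv_curve_classification(x: np.ndarray, labels, lv_max: int = 8, class_order=None) -> np.ndarray:
    """LOOCV accuracy per latent-variable count: each fold fits the
    one-vs-all membership sub-models and assigns the held-out sample to
    the class with maximum predicted membership."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if class_order is None:
        class_order = _class_order_of(labels)
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    y = membership_matrix(labels, class_order)
    n = x.shape[0]
    lv_max = _clamp_lv(lv_max, n, x.shape[1])
    correct = np.zeros((lv_max, n))
    for i in range(n):
        mask = np.arange(n) != i
        if len(np.unique(labels[mask])) < len(class_order):
            logger.warning("LOOCV fold %d lost an entire class", i)
        model = pls_fit(x[mask], y[mask], lv_max)
        for k in range(1, lv_max + 1):
            pred = pls_predict(model, x[i], n_lv=k)
            correct[k - 1, i] = class_order[int(np.argmax(pred))] == labels[i]
    return correct.mean(axis=1)


def select_lv_classification(acc: np.ndarray) -> int:
    """Highest-accuracy LV; ties broken toward the smallest LV (1-based)."""
    return int(np.argmax(np.asarray(acc))) + 1


def plsda_assign(predicted: np.ndarray, class_order=CLASS_ORDER) -> np.ndarray:
    """Assign each row to the class with highest predicted membership;
    ties go to the lowest class index (logged)."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    best = np.argmax(predicted, axis=1)
    n_max = (predicted == predicted.max(axis=1, keepdims=True)).sum(axis=1)
    for row in np.where(n_max > 1)[0]:
        logger.info("plsda_assign: tie in row %d resolved to lowest class index", row)
    return np.array([class_order[b] for b in best])


def rmsep(y_true, y_pred) -> float:
    """Root-mean-square error of prediction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def accuracy(labels_true, labels_pred) -> float:
    """Fraction of matching labels."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean(labels_true == labels_pred))
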