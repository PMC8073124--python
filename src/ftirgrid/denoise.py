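"""Denoising methods: Whittaker/Eilers (EIL), Savitzky–Golay (SG), and
Fourier low-pass (FT).

All three are linear operators applied row-wise to a SpectraSet.  The
study grids are: EIL λ ∈ {2..24}; SG degree ∈ {2,3} × odd frame ∈
{11..29}; FT retained-window ∈ {100, 320} points.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.signal import savgol_filter

from .core import SpectraSet


def _whittaker_solver(n: int, lam: float):
    """LU factorization of (I + λ·D₂ᵀD₂) for repeated solves."""
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = sp.eye(n, format="csc") + lam * (d2.T @ d2)
    return splu(a.tocsc())


def whittaker_smooth(y: np.ndarray, lam: float) -> np.ndarray:
    """Whittaker smoother: minimize Σ(yᵢ−zᵢ)² + λ·Σ(Δ²zᵢ)², unit weights.

    Solved through a sparse LU factorization of the pentadiagonal normal
    matrix.  λ→0 returns y; λ→∞ tends to the least-squares line.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("whittaker_smooth requires finite input")
    if y.size < 4:
        raise ValueError("whittaker_smooth requires length ≥ 4")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return _whittaker_solver(y.size, lam).solve(y.copy())


def savgol_smooth(y: np.ndarray, poly_degree: int, frame: int) -> np.ndarray:
    """Savitzky–Golay smoothing: local polynomial fit over an odd window;
    endpoints from polynomial extrapolation of the terminal windows."""
    y = np.asarray(y, dtype=float)
    if frame % 2 == 0:
        raise ValueError("frame must be odd")
    if frame <= poly_degree:
        raise ValueError("frame must exceed poly_degree")
    if frame > y.size:
        raise ValueError("frame exceeds spectrum length")
    return savgol_filter(y, frame, poly_degree, mode="interp")


def fourier_denoise(y: np.ndarray, window: int) -> np.ndarray:
    """Fourier low-pass: keep the ``window`` lowest-frequency real-FFT
    coefficients (zero-frequency term plus low cosine/sine pairs), zero
    the rest, inverse-transform."""
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise ValueError("window must be ≥ 1")
    coeffs = np.fft.rfft(y)
    if window > coeffs.size:
        warnings.warn("fourier_denoise: window exceeds coefficient count; clamping")
        window = coeffs.size
    coeffs[window:] = 0.0
    return np.fft.irfft(coeffs, n=y.size)


def apply_rows(spectra: SpectraSet, fn) -> SpectraSet:
    """Apply a 1-D operator to every spectrum row."""
    out = np.vstack([fn(row) for row in spectra.absorbance])
    return spectra.with_absorbance(out)


def denoise_set(spectra: SpectraSet, method: str, **params) -> SpectraSet:
    """Uniform apply contract used by the grid runner.

    method ∈ {"EIL", "SG", "FT"} with parameters lambda / (poly_degree,
    frame) / window respectively.
    """
    method = method.upper()
    if method == "EIL":
        lam = params["lambda"] if "lambda" in params else params["lam"]
        solver = _whittaker_solver(spectra.n_variables, lam)
        out = np.vstack([solver.solve(row.copy()) for row in spectra.absorbance])
        return spectra.with_absorbance(out)
    if method == "SG":
        return apply_rows(spectra, lambda r: savgol_smooth(r, params["poly_degree"], params["frame"]))
    if method == "FT":
        return apply_rows(spectra, lambda r: fourier_denoise(r, params["window"]))
    raise ValueError(f"unknown denoise method {method!r}")
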