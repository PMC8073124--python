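"""Normalization methods: constant-band (CON), total-sum (TSN), and
probabilistic quotient (PQN).

All three are scale-invariant per spectrum.  PQN computes its standard
(mean) spectrum within the given set only, so model and test sets are
normalized independently, matching a pipeline in which preprocessing
never sees the other split.
"""

from __future__ import annotations

import numpy as np

from .core import SpectraSet

AMIDE_I = 1656.0


def constant_normalize(spectra: SpectraSet, target_wavenumber: float = AMIDE_I) -> SpectraSet:
    """Divide each spectrum by its value at the axis point nearest the
    target band (Amide I, 1656 cm⁻¹ by default).

    Derivative spectra (``meta["derivative"]``) are divided by the absolute
    value at the target, so the band point maps to ±1 rather than flipping
    the spectrum's sign.
    """
    x = spectra.axis.values
    if not x[0] <= target_wavenumber <= x[-1]:
        raise ValueError(f"target {target_wavenumber} cm⁻¹ outside the axis range")
    idx = spectra.axis.nearest_index(target_wavenumber)
    vals = spectra.absorbance[:, idx]
    if spectra.meta.get("derivative"):
        vals = np.abs(vals)
    zero = np.where(vals == 0)[0]
    if zero.size:
        raise ValueError(f"zero value at {target_wavenumber} cm⁻¹ for spectrum id {spectra.ids[zero[0]]}")
    return spectra.with_absorbance(spectra.absorbance / vals[:, None])


def total_sum_normalize(spectra: SpectraSet) -> SpectraSet:
    """Divide each spectrum by the sum of its absorbances; absolute values
    are used when any value is negative (derivative or baseline-corrected
    spectra), where the plain sum is ill-defined as a size measure."""
    a = spectra.absorbance
    sums = np.abs(a).sum(axis=1) if np.any(a < 0) else a.sum(axis=1)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise ValueError(f"zero normalizing sum for spectrum id {spectra.ids[zero[0]]}")
    return spectra.with_absorbance(a / sums[:, None])


def pqn_normalize(spectra: SpectraSet, quotient_floor: float = 1e-8) -> SpectraSet:
    """Probabilistic quotient normalization: xₙ = xᵢ / median(xᵢ/x_s).

    The standard x_s is the feature-wise mean of this set; quotients are
    formed only where |x_s| exceeds ``quotient_floor``·max|x_s| to avoid
    blow-ups on baseline-corrected near-zero regions.
    """
    if spectra.n_spectra < 2:
        raise ValueError("PQN needs at least 2 spectra")
    a = spectra.absorbance
    xs = a.mean(axis=0)
    keep = np.abs(xs) > quotient_floor * np.abs(xs).max()
    if keep.sum() < a.shape[1] / 2:
        raise ValueError("standard spectrum near zero on a majority of features")
    factors = np.median(a[:, keep] / xs[keep], axis=1)
    bad = np.where(~np.isfinite(factors) | (factors == 0))[0]
    if bad.size:
        raise ValueError(f"degenerate PQN scaling factor for spectrum id {spectra.ids[bad[0]]}")
    return spectra.with_absorbance(a / factors[:, None])


def normalize_set(spectra: SpectraSet, method: str, **params) -> SpectraSet:
    """Uniform apply contract: method ∈ {"CON", "TSN", "PQN"}."""
    method = method.upper()
    if method == "CON":
        return constant_normalize(spectra, params.get("target", AMIDE_I))
    if method == "TSN":
        return total_sum_normalize(spectra)
    if method == "PQN":
        return pqn_normalize(spectra)
    raise ValueError(f"unknown normalization method {method!r}")
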