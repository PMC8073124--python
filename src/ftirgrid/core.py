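"""Core containers and dataset-level operations for FT-IR cell spectra.

A :class:`SpectraSet` holds one absorbance spectrum per row on a shared,
strictly increasing wavenumber axis (cm⁻¹), together with class labels and
unique spectrum ids.  All pipeline stages consume and return this type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Default atmospheric-artifact regions (cm⁻¹, closed intervals).  The CO₂
# antisymmetric-stretch doublet sits near 2349 cm⁻¹; water-vapor rotational
# lines contaminate the high-wavenumber edge.
CO2_REGION = (2300.0, 2400.0)
WATER_VAPOR_REGION = (3650.0, 3800.0)


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 8:
            raise ValueError("axis must be 1-D with at least 8 points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        return float(np.mean(np.diff(self.values)))

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class SpectralRegion:
    """Closed wavenumber interval [lo, hi] in cm⁻¹."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"region requires lo < hi, got ({self.lo}, {self.hi})")

    def mask(self, axis: WavenumberAxis) -> np.ndarray:
        return (axis.values >= self.lo) & (axis.values <= self.hi)


@dataclass(frozen=True)
class NoiseConfig:
    """Scan-count noise model: co-adding N scans scales noise σ by 1/√N.

    Reducing a ``scans_base``-scan acquisition to ``scans_target`` scans is
    emulated by adding independent Gaussian noise with
    ``σ_add = sigma_base·sqrt(scans_base/scans_target − 1)``.
    """

    scans_base: int = 256
    scans_target: int = 32
    sigma_base: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scans_base < 1 or self.scans_target < 1:
            raise ValueError("scan counts must be positive")
        if self.scans_target > self.scans_base:
            raise ValueError("scans_target must not exceed scans_base")
        if self.sigma_base is not None and self.sigma_base < 0:
            raise ValueError("sigma_base must be non-negative")


@dataclass(frozen=True)
class SpectraSet:
    """Absorbance matrix (n_spectra × n_variables) with labels and ids."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        labels = np.asarray(self.labels)
        ids = np.asarray(self.ids)
        if a.shape[1] != len(self.axis):
            raise ValueError(
                f"absorbance has {a.shape[1]} columns but axis has {len(self.axis)} points"
            )
        if labels.shape != (a.shape[0],) or ids.shape != (a.shape[0],):
            raise ValueError("labels and ids must match the spectrum count")
        if len(np.unique(ids)) != ids.size:
            raise ValueError("spectrum ids must be unique")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance values must be finite")
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", ids)

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, absorbance: np.ndarray, **meta) -> "SpectraSet":
        return replace(self, absorbance=absorbance, meta={**self.meta, **meta})

    def with_axis(self, axis: WavenumberAxis, absorbance: np.ndarray) -> "SpectraSet":
        return replace(self, axis=axis, absorbance=absorbance, meta=dict(self.meta))

    def subset(self, row_index: np.ndarray) -> "SpectraSet":
        row_index = np.asarray(row_index)
        return replace(
            self,
            absorbance=self.absorbance[row_index],
            labels=self.labels[row_index],
            ids=self.ids[row_index],
            meta=dict(self.meta),
        )

    def select_ids(self, ids) -> "SpectraSet":
        order = {i: k for k, i in enumerate(self.ids)}
        return self.subset(np.array([order[i] for i in ids]))


def read_spectra(path, labels_path=None) -> SpectraSet:
    """Read a delimited spectra file (first column ``wavenumber``, one
    spectrum per remaining column, header = spectrum ids).

    Labels come from a companion two-column (id, class) file when given,
    otherwise from a ``label:`` prefix embedded in each column header
    (``id|class``), otherwise default to a single class ``"unlabeled"``.
    A wide orientation (first column named ``id``, remaining headers numeric
    wavenumbers) is auto-detected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"malformed spectra file {path}: need ≥ 2 columns")
    first = str(df.columns[0]).strip().lower()
    if first == "wavenumber":
        wn = df.iloc[:, 0].to_numpy(dtype=float)
        matrix = df.iloc[:, 1:].to_numpy(dtype=float).T
        headers = [str(c) for c in df.columns[1:]]
    elif first == "id":
        headers = [str(v) for v in df.iloc[:, 0]]
        try:
            wn = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise ValueError(f"malformed wide spectra file {path}: non-numeric wavenumber header ({exc})")
        matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        raise ValueError(f"malformed spectra file {path}: first column must be 'wavenumber' or 'id', got {first!r}")

    ids, labels = [], []
    for h in headers:
        if "|" in h:
            i, lab = h.split("|", 1)
        else:
            i, lab = h, "unlabeled"
        ids.append(i)
        labels.append(lab)
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep=None, engine="python")
        lmap = dict(zip(ldf.iloc[:, 0].astype(str), ldf.iloc[:, 1].astype(str)))
        labels = [lmap.get(i, lab) for i, lab in zip(ids, labels)]

    order = np.argsort(wn, kind="stable")
    wn = wn[order]
    if np.any(np.diff(wn) <= 0):
        raise ValueError(f"axis in {path} contains duplicate wavenumbers")
    matrix = matrix[:, order]
    return SpectraSet(WavenumberAxis(wn), matrix, np.array(labels), np.array(ids, dtype=object))


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as TSV; header embeds labels as ``id|class``.

    ``read_spectra(write_spectra(s))`` reproduces values to 1e-12.
    """
    cols = {"wavenumber": spectra.axis.values}
    for k in range(spectra.n_spectra):
        cols[f"{spectra.ids[k]}|{spectra.labels[k]}"] = spectra.absorbance[k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def remove_region(spectra: SpectraSet, region: SpectralRegion) -> SpectraSet:
    """Drop every axis point with lo ≤ ν ≤ hi; remaining columns untouched."""
    mask = region.mask(spectra.axis)
    if not mask.any():
        logger.warning("remove_region: region %s does not overlap the axis; no-op", region)
        return spectra
    keep = ~mask
    return spectra.with_axis(WavenumberAxis(spectra.axis.values[keep]), spectra.absorbance[:, keep])


def trim_region(spectra: SpectraSet, region: SpectralRegion) -> SpectraSet:
    """Alias of :func:`remove_region`, applied after baseline correction."""
    return remove_region(spectra, region)


def interpolate_region(spectra: SpectraSet, region: SpectralRegion) -> SpectraSet:
    """Replace values inside the region by linear interpolation between the
    nearest flanking axis points, per spectrum.  Axis unchanged."""
    mask = region.mask(spectra.axis)
    if not mask.any():
        return spectra
    idx = np.where(mask)[0]
    lo_i, hi_i = idx[0] - 1, idx[-1] + 1
    if lo_i < 0 or hi_i >= len(spectra.axis):
        raise ValueError("interpolate_region: region touches the axis boundary, no flanking point")
    x = spectra.axis.values
    t = (x[idx] - x[lo_i]) / (x[hi_i] - x[lo_i])
    a = spectra.absorbance.copy()
    a[:, idx] = a[:, [lo_i]] * (1 - t) + a[:, [hi_i]] * t
    return spectra.with_absorbance(a)


def estimate_sigma_base(spectra: SpectraSet, window: SpectralRegion = SpectralRegion(1750.0, 1800.0)) -> float:
    """Estimate base acquisition noise σ as the mean per-spectrum residual
    std in a signal-free window after removing a linear trend."""
    mask = window.mask(spectra.axis)
    if mask.sum() < 4:
        raise ValueError("sigma estimation window covers fewer than 4 axis points")
    x = spectra.axis.values[mask]
    y = spectra.absorbance[:, mask]
    design = np.vstack([x - x.mean(), np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    resid = y.T - design @ coef
    return float(np.mean(resid.std(axis=0, ddof=2)))


def add_scan_noise(spectra: SpectraSet, cfg: NoiseConfig) -> SpectraSet:
    """Add i.i.d. Gaussian noise emulating a reduced scan count.

    σ_add = sigma_base·sqrt(scans_base/scans_target − 1), so the combined
    noise matches a ``scans_target``-scan acquisition.  When
    ``cfg.sigma_base`` is None it is estimated from the 1750–1800 cm⁻¹
    signal-free window.
    """
    sigma_base = cfg.sigma_base
    if sigma_base is None:
        sigma_base = estimate_sigma_base(spectra)
    sigma_add = sigma_base * np.sqrt(cfg.scans_base / cfg.scans_target - 1.0)
    if sigma_add == 0.0:
        return spectra.with_absorbance(spectra.absorbance.copy(), noise_seed=cfg.seed, sigma_add=0.0)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(0.0, sigma_add, size=spectra.absorbance.shape)
    return spectra.with_absorbance(
        spectra.absorbance + noise,
        noise_seed=cfg.seed,
        sigma_add=float(sigma_add),
        scans_target=cfg.scans_target,
    )


def max_normalize_dataset(spectra: SpectraSet) -> SpectraSet:
    """Divide the whole set by its single global maximum (used before PCA
    exploration so variants share a common scale)."""
    m = float(spectra.absorbance.max())
    if m <= 0:
        raise ValueError("dataset maximum must be positive for max-normalization")
    return spectra.with_absorbance(spectra.absorbance / m)
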