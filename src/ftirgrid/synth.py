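"""Synthetic FT-IR cell-spectrum generator.

Emulates the study design the pipeline is benchmarked on: 48 averaged
single-cell spectra from five prostate cell lines (14/7/7/10/10) on a
1582-point axis over 900–3800 cm⁻¹, with shared protein bands (Amide I/II,
Amide A/B), class-specific amplitude offsets in the nucleic-acid
(944–1140 cm⁻¹) and CH₂/CH₃ stretch (2800–3000 cm⁻¹) regions, and the
distortions the preprocessing methods target: polynomial baseline drift,
Mie-type oscillatory scatter, multiplicative scaling, CO₂/water-vapor
artifact bands, and homoscedastic detector noise parameterized by scan
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NoiseConfig, SpectraSet, WavenumberAxis


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center/width in cm⁻¹, peak amplitude in AU."""

    center: float
    width: float  # FWHM
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, x: np.ndarray, center=None, amplitude=None) -> np.ndarray:
        c = self.center if center is None else center
        a = self.amplitude if amplitude is None else amplitude
        if self.shape == "gaussian":
            s = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return a * np.exp(-0.5 * ((x - c) / s) ** 2)
        g = self.width / 2.0
        return a * g**2 / ((x - c) ** 2 + g**2)


@dataclass(frozen=True)
class ClassProfile:
    """Band recipe for one cell line plus between-cell variability."""

    name: str
    bands: tuple
    n_spectra: int
    amplitude_jitter: float = 0.05  # relative (log-normal σ)
    center_jitter: float = 1.0  # cm⁻¹ (normal σ)

    def __post_init__(self):
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be ≥ 1")
        if self.amplitude_jitter < 0 or self.center_jitter < 0:
            raise ValueError("jitters must be non-negative")


@dataclass(frozen=True)
class DistortionConfig:
    """Per-spectrum distortions applied to clean spectra.

    Each spectrum becomes ``scale·(clean + fringe) + baseline + artifacts
    + noise`` with parameters drawn per spectrum from the stated ranges.
    """

    baseline_poly_coeffs_std: tuple = (0.05, 0.04, 0.02, 0.01)
    mie_diameter_um: tuple = (2.0, 8.0)
    mie_index: tuple = (1.1, 1.4)
    mie_amplitude: float = 0.08
    multiplicative_scale_range: tuple = (0.8, 1.2)
    artifact_bands: tuple = (
        BandSpec(2349.0, 18.0, 0.02),  # CO₂ antisymmetric stretch doublet region
        BandSpec(2335.0, 12.0, 0.012),
        BandSpec(3710.0, 10.0, 0.004),  # water-vapor rotational comb (coarse)
        BandSpec(3740.0, 10.0, 0.004),
        BandSpec(3770.0, 10.0, 0.004),
    )
    noise: NoiseConfig = field(default_factory=lambda: NoiseConfig(sigma_base=0.006))

    def __post_init__(self):
        lo, hi = self.multiplicative_scale_range
        if lo <= 0 or hi <= 0:
            raise ValueError("multiplicative scale range must be positive")
        if self.mie_amplitude < 0:
            raise ValueError("mie amplitude must be non-negative")


def identity_distortions() -> DistortionConfig:
    """A config under which apply_distortions is the identity."""
    return DistortionConfig(
        baseline_poly_coeffs_std=(0.0,),
        mie_amplitude=0.0,
        multiplicative_scale_range=(1.0, 1.0),
        artifact_bands=(),
        noise=NoiseConfig(sigma_base=0.0),
    )


def make_axis(lo: float = 900.0, hi: float = 3800.0, n_points: int = 1582) -> WavenumberAxis:
    """Evenly spaced wavenumber axis from lo to hi inclusive."""
    if not lo < hi:
        raise ValueError("make_axis requires lo < hi")
    if n_points < 8:
        raise ValueError("make_axis requires n_points ≥ 8")
    return WavenumberAxis(np.linspace(lo, hi, n_points))


# Shared protein bands: the Amide I/II backbone bands and the N–H
# stretch/overtone pair every cell spectrum shows.
_PROTEIN_BANDS = (
    BandSpec(1656.0, 45.0, 1.00),   # Amide I
    BandSpec(1545.0, 50.0, 0.55),   # Amide II
    BandSpec(3290.0, 140.0, 0.45),  # Amide A
    BandSpec(3070.0, 80.0, 0.12),   # Amide B
    BandSpec(1240.0, 60.0, 0.18),   # Amide III / PO₂⁻ antisym.
    BandSpec(1455.0, 40.0, 0.15),   # CH₂/CH₃ bending
    BandSpec(1400.0, 35.0, 0.10),   # COO⁻ symmetric stretch
)


def _line_bands(nucleic: float, ch2: float, ch3: float, glyco: float) -> tuple:
    """Class-specific bands: nucleic-acid region (944–1140 cm⁻¹) and
    CH-stretch region (2800–3000 cm⁻¹) amplitudes carry the class signal."""
    return (
        BandSpec(966.0, 30.0, 0.12 * nucleic),    # DNA backbone
        BandSpec(1055.0, 45.0, 0.26 * nucleic),   # C–O / PO₂⁻ sym.
        BandSpec(1085.0, 35.0, 0.21 * nucleic),
        BandSpec(1121.0, 30.0, 0.10 * nucleic),   # RNA ribose
        BandSpec(2852.0, 22.0, 0.18 * ch2),       # CH₂ sym. stretch
        BandSpec(2923.0, 28.0, 0.34 * ch2),       # CH₂ antisym. stretch
        BandSpec(2874.0, 20.0, 0.10 * ch3),       # CH₃ sym. stretch
        BandSpec(2958.0, 22.0, 0.16 * ch3),       # CH₃ antisym. stretch
        BandSpec(1171.0, 28.0, 0.07 * glyco),     # C–O stretch (glycogen-like)
    )


def default_profiles() -> list[ClassProfile]:
    """Five class profiles mirroring the study's cell lines and counts.

    All classes share the protein bands; they differ in nucleic-acid and
    CH-stretch amplitudes so that classes are separable yet overlapping.
    """
    recipe = [
        # name, n, nucleic, ch2, ch3, glyco
        ("RWPE-1", 14, 0.65, 1.00, 0.78, 1.30),
        ("22Rv1", 7, 0.89, 0.85, 0.96, 0.78),
        ("PC3", 7, 1.38, 1.15, 0.67, 0.67),
        ("Du145", 10, 1.15, 1.38, 1.12, 0.85),
        ("LNCaP", 10, 0.85, 0.63, 1.34, 1.08),
    ]
    return [
        ClassProfile(name, _PROTEIN_BANDS + _line_bands(nuc, ch2, ch3, gly), n)
        for name, n, nuc, ch2, ch3, gly in recipe
    ]


def render_clean(profile: ClassProfile, axis: WavenumberAxis, seed: int = 0) -> np.ndarray:
    """Render ``profile.n_spectra`` clean rows: each a sum of jittered band
    shapes (log-normal amplitude jitter, normal center jitter)."""
    rng = np.random.default_rng(seed)
    x = axis.values
    out = np.zeros((profile.n_spectra, x.size))
    for i in range(profile.n_spectra):
        for band in profile.bands:
            amp = band.amplitude * rng.lognormal(0.0, profile.amplitude_jitter)
            center = band.center + rng.normal(0.0, profile.center_jitter)
            out[i] += band.evaluate(x, center=center, amplitude=amp)
    return out


def mie_fringe_curve(axis: WavenumberAxis, diameter_um: float, index: float, amplitude: float) -> np.ndarray:
    """Oscillatory scatter distortion from the van-de-Hulst extinction of a
    homogeneous sphere: ρ(ν) = 2π·ν·d·(n−1), Q mean-removed and scaled."""
    from .baseline import vandehulst_qext

    d_cm = diameter_um * 1e-4
    rho = 2.0 * np.pi * axis.values * d_cm * (index - 1.0)
    q = vandehulst_qext(rho)
    q = q - q.mean()
    peak = np.abs(q).max()
    return amplitude * q / peak if peak > 0 else q


def apply_distortions(clean: SpectraSet, cfg: DistortionConfig, seed: int = 0) -> SpectraSet:
    """Distort each spectrum as scale·(clean + fringe) + baseline +
    artifact bands + noise; ground-truth components are kept in ``meta``
    so tests can reconstruct every distorted row exactly (noise aside).
    """
    rng = np.random.default_rng(seed)
    x = clean.axis.values
    xc = (x - x.mean()) / (x.max() - x.min())  # scaled to ~[-0.5, 0.5]
    n = clean.n_spectra

    scales = rng.uniform(*cfg.multiplicative_scale_range, size=n)
    baselines = np.zeros((n, x.size))
    for deg, std in enumerate(cfg.baseline_poly_coeffs_std):
        coeffs = rng.normal(0.0, std, size=n)
        baselines += coeffs[:, None] * xc[None, :] ** deg

    fringes = np.zeros((n, x.size))
    if cfg.mie_amplitude > 0:
        diameters = rng.uniform(*cfg.mie_diameter_um, size=n)
        indices = rng.uniform(*cfg.mie_index, size=n)
        amps = rng.uniform(0.3, 1.0, size=n) * cfg.mie_amplitude
        for i in range(n):
            fringes[i] = mie_fringe_curve(clean.axis, diameters[i], indices[i], amps[i])

    artifacts = np.zeros((n, x.size))
    for band in cfg.artifact_bands:
        amps = band.amplitude * rng.uniform(0.5, 1.5, size=n)
        artifacts += amps[:, None] * band.evaluate(x, amplitude=1.0)[None, :]

    distorted = scales[:, None] * (clean.absorbance + fringes) + baselines + artifacts

    sigma_add = 0.0
    if cfg.noise.sigma_base:
        sigma_add = cfg.noise.sigma_base
        noise_rng = np.random.default_rng(cfg.noise.seed + seed)
        distorted = distorted + noise_rng.normal(0.0, sigma_add, size=distorted.shape)

    return clean.with_absorbance(
        distorted,
        truth={
            "clean": clean.absorbance,
            "scale": scales,
            "baseline": baselines,
            "fringe": fringes,
            "artifacts": artifacts,
            "sigma": sigma_add,
        },
        distortion_seed=seed,
    )


def generate_reference(axis: WavenumberAxis) -> SpectraSet:
    """Smooth protein-dominated scatter-correction reference (a synthetic
    stand-in for a measured Matrigel spectrum): Amide I/II dominated,
    strictly positive, max 1."""
    x = axis.values
    y = np.zeros_like(x)
    for band in _PROTEIN_BANDS:
        y += band.evaluate(x)
    y += BandSpec(1080.0, 60.0, 0.10).evaluate(x)
    y += 0.02  # strictly positive floor
    y = y / y.max()
    return SpectraSet(
        axis,
        y[None, :],
        np.array(["reference"]),
        np.array(["matrigel-synthetic"], dtype=object),
        meta={"synthetic": True},
    )


def generate_study(seed: int = 0, distortions: DistortionConfig | None = None) -> SpectraSet:
    """Generate the full 48-spectrum, 1582-point study-shaped dataset."""
    axis = make_axis()
    profiles = default_profiles()
    rows, labels, ids = [], [], []
    for k, profile in enumerate(profiles):
        rows.append(render_clean(profile, axis, seed=seed * 1009 + k))
        labels += [profile.name] * profile.n_spectra
        ids += [f"{profile.name}-{i:02d}" for i in range(profile.n_spectra)]
    clean = SpectraSet(
        axis,
        np.vstack(rows),
        np.array(labels),
        np.array(ids, dtype=object),
        meta={"seed": seed},
    )
    cfg = DistortionConfig() if distortions is None else distortions
    return apply_distortions(clean, cfg, seed=seed)


def generate_clean_study(seed: int = 0) -> SpectraSet:
    """The same study without any distortion (separability oracle)."""
    return generate_study(seed=seed, distortions=identity_distortions())
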