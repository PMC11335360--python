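"""Seedable synthetic series with the structure of the three study regimes.

Three generators emulate the statistical structure of the data this method
targets, with full ground truth returned alongside so downstream stages can
be tested for exact parameter and state recovery:

* ``gen_two_state`` — spontaneous two-state interconversion (dark reversion
  of a bacteriophytochrome-like photoreceptor): a series of absorption
  spectra mixing a far-red-absorbing start state into a red-absorbing end
  state along a single exponential, starting from a partially converted
  sample.  Noise-free output has rank exactly 2.
* ``gen_multiphase`` — a biphasic photoreaction (photolyase-like) recorded
  as difference spectra: three signed spectral components coupled to two
  exponential kinetic phases plus a non-kinetic, directionally persistent
  fluctuation channel confined to short wavelengths.
* ``gen_oscillatory_maps`` — a real-space map series mixing static
  structural-event components with an oscillatory quadrature pair sharing a
  damped-sinusoid envelope (femtosecond low-frequency oscillation regime).

Noise is additive white Gaussian scaled to the peak of the clean signal —
the assumption under which rejection of trailing singular components is a
least-squares denoiser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MapGrid, MapSeries, MetadataTable, SpectralSeries, serialize_map

__all__ = [
    "BandSpec",
    "pr_like_bands",
    "pfr_like_bands",
    "difference_bands",
    "gen_two_state",
    "gen_multiphase",
    "gen_oscillatory_maps",
    "inject_artifact",
    "WAVENUMBER_61_CM_RAD_PS",
]

#: Angular frequency (rad/ps) equivalent to the dominant 61 cm⁻¹ oscillation.
WAVENUMBER_61_CM_RAD_PS = 2.0 * math.pi * 2.998e10 * 61.0 * 1e-12


@dataclass(frozen=True)
class BandSpec:
    """A pure-state spectrum as a sum of Gaussian bands on a wavelength grid.

    ``bands`` is a sequence of (center_nm, width_nm, amplitude_au) triples.
    Absorption spectra should stay non-negative; difference spectra may carry
    signed bands.
    """

    bands: tuple

    def __post_init__(self) -> None:
        for center, width, amp in self.bands:
            if width <= 0:
                raise ValueError("band widths must be positive")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for center, width, amp in self.bands:
            out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out


def pr_like_bands() -> BandSpec:
    """Red-absorbing resting state: main band at 707 nm plus a Soret band."""
    return BandSpec(((707.0, 28.0, 1.00), (390.0, 32.0, 0.55), (280.0, 22.0, 0.85)))


def pfr_like_bands() -> BandSpec:
    """Far-red-absorbing photoproduct: main band at 748 nm, weak 690 shoulder."""
    return BandSpec(((748.0, 34.0, 0.90), (690.0, 25.0, 0.20),
                     (402.0, 32.0, 0.50), (280.0, 22.0, 0.85)))


def difference_bands() -> tuple[BandSpec, BandSpec, BandSpec]:
    """Three signed difference-spectrum shapes with overlapping features.

    The first mimics a flavin photoreduction bleach with a sharp negative
    edge near 485 nm, the second a second-chromophore bleach at shorter
    wavelengths, the third a broad mixed response.
    """
    flavin_like = BandSpec(((450.0, 28.0, -1.00), (485.0, 12.0, -0.45), (560.0, 45.0, 0.25)))
    lumazine_like = BandSpec(((410.0, 22.0, -0.80), (470.0, 18.0, -0.20)))
    broad_mixed = BandSpec(((520.0, 55.0, -0.35), (430.0, 25.0, 0.30), (620.0, 40.0, 0.15)))
    return flavin_like, lumazine_like, broad_mixed


def _add_noise(rng: np.random.Generator, clean: np.ndarray, noise: float) -> np.ndarray:
    if noise <= 0:
        return clean.copy()
    scale = noise * float(np.max(np.abs(clean)))
    return clean + rng.normal(0.0, scale, size=clean.shape)


def gen_two_state(
    pure_a: BandSpec | None = None,
    pure_b: BandSpec | None = None,
    tau: float = 58.0,
    t: np.ndarray | None = None,
    start_fraction: float = 1.0 / 3.0,
    noise: float = 0.01,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> tuple[SpectralSeries, dict]:
    """Two-state exponential interconversion A → B with overlapping spectra.

    Column j is (1 − p(t_j))·A + p(t_j)·B + noise with
    p(t) = s₀ + (1 − s₀)(1 − exp(−t/τ)), s₀ the fraction of B already present
    at t = 0.  Defaults follow the dark-reversion regime: 45 observations
    evenly spanning 180 min, τ = 58 min, one third of the sample already
    reverted at the start.  The noise-free matrix has rank exactly 2.

    The end-state spectrum is adjusted (minimally, by adding a multiple of
    the start-state shape to the difference) so that the difference direction
    B − A is orthogonal to A.  This is the geometry the deconvolution
    targets: after verticalization one rotated component is exactly the pure
    start-state spectrum, the trajectory's zero-progress point sits at
    f_k = 0, and the coefficient along the vertical line is directly
    proportional to the reacted fraction.
    """
    if tau <= 0:
        raise ValueError("time constant must be positive")
    if not 0.0 <= start_fraction <= 1.0:
        raise ValueError("start fraction must lie in [0, 1]")
    pure_a = pfr_like_bands() if pure_a is None else pure_a
    pure_b = pr_like_bands() if pure_b is None else pure_b
    t = np.linspace(0.0, 180.0, 45) if t is None else np.asarray(t, dtype=float)
    wavelengths = np.arange(250.0, 901.0, 2.0) if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)

    spec_a = pure_a(wavelengths)
    spec_b = pure_b(wavelengths)
    # Orthogonalize the reaction difference against the start state (see above).
    a_hat = spec_a / np.linalg.norm(spec_a)
    delta = spec_b - spec_a
    delta = delta - (delta @ a_hat) * a_hat
    spec_b = spec_a + delta
    p = start_fraction + (1.0 - start_fraction) * (1.0 - np.exp(-t / tau))
    clean = np.outer(spec_a, 1.0 - p) + np.outer(spec_b, p)
    data = _add_noise(rng, clean, noise)

    metadata = MetadataTable(pd.DataFrame({"time_min": t}), ordering_axis="time_min")
    series = SpectralSeries(wavelengths, data, metadata)
    truth = {
        "pure_a": spec_a, "pure_b": spec_b, "fraction_b": p,
        "tau": tau, "start_fraction": start_fraction,
        "clean": clean, "noise": noise, "seed": seed,
    }
    return series, truth


def gen_multiphase(
    components: tuple[BandSpec, BandSpec, BandSpec] | None = None,
    tau1: float = 0.4,
    tau2: float = 9.0,
    coupling: np.ndarray | None = None,
    fluct_amplitude: float = 0.25,
    fluct_cutoff_nm: float = 450.0,
    t: np.ndarray | None = None,
    noise: float = 0.01,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> tuple[SpectralSeries, dict]:
    """Biphasic three-component photoreaction with a fluctuating channel.

    Three kinetic channels drive the mixing: phase I = 1 − exp(−t/τ₁),
    phase II = 1 − exp(−t/τ₂), and a zero-mean smoothed random walk (the
    fluctuation — non-kinetic but directionally persistent).  Row i of the
    3 × 3 ``coupling`` matrix states how much of each channel drives
    component i, allowing the correlated (non-orthogonal) case; the identity
    coupling gives one channel per component.  The fluctuation's spectrum is
    confined to wavelengths below ``fluct_cutoff_nm``.  Defaults follow the
    photolyase regime: 200 observations over 20 s, τ₁ = 0.4 s, τ₂ = 9 s.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    components = difference_bands() if components is None else components
    if len(components) != 3:
        raise ValueError("exactly three spectral components are expected")
    coupling = np.array([[1.0, 0.25, 0.0],
                         [0.0, 0.0, 1.0],
                         [0.45, 1.0, 0.0]]) if coupling is None else np.asarray(coupling, float)
    if coupling.shape != (3, 3):
        raise ValueError("coupling must be a 3 x 3 matrix (components x channels)")
    t = np.linspace(0.0, 20.0, 200) if t is None else np.asarray(t, dtype=float)
    wavelengths = np.arange(350.0, 701.0, 1.0) if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)

    phase1 = 1.0 - np.exp(-t / tau1)
    phase2 = 1.0 - np.exp(-t / tau2)
    walk = np.cumsum(rng.normal(0.0, 1.0, size=t.size))
    kernel = np.ones(9) / 9.0
    walk = np.convolve(walk, kernel, mode="same")
    walk -= walk.mean()
    peak = np.max(np.abs(walk))
    fluct = fluct_amplitude * walk / peak if peak > 0 else walk
    channels = np.vstack([phase1, phase2, fluct])  # 3 x N

    spectra = np.column_stack([comp(wavelengths) for comp in components])  # M x 3
    # Confine the fluctuation-driven spectral weight to short wavelengths.
    confinement = (wavelengths < fluct_cutoff_nm).astype(float)
    fluct_weight = coupling[:, 2]
    spectra_eff = spectra.copy()
    for i in range(3):
        if fluct_weight[i] != 0.0:
            spectra_eff[:, i] = spectra[:, i] * confinement

    courses = coupling @ channels  # 3 x N component time courses
    clean = spectra_eff @ courses
    data = _add_noise(rng, clean, noise)

    metadata = MetadataTable(pd.DataFrame({"time_s": t}), ordering_axis="time_s")
    series = SpectralSeries(wavelengths, data, metadata)
    truth = {
        "component_spectra": spectra_eff, "channel_courses": channels,
        "component_courses": courses, "coupling": coupling,
        "tau1": tau1, "tau2": tau2, "fluct_course": fluct,
        "fluct_cutoff_nm": fluct_cutoff_nm, "clean": clean,
        "noise": noise, "seed": seed,
    }
    return series, truth


def _random_blob_map(rng: np.random.Generator, shape: tuple[int, int, int],
                     n_blobs: int = 3) -> np.ndarray:
    """A smooth random density: a few Gaussian blobs at random positions."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    out = np.zeros(shape)
    for _ in range(n_blobs):
        center = [rng.uniform(0, s - 1) for s in shape]
        width = rng.uniform(0.8, max(1.5, min(shape) / 3.0))
        amp = rng.normal(0.0, 1.0)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        out += amp * np.exp(-0.5 * r2 / width**2)
    return out


def gen_oscillatory_maps(
    grid: MapGrid | None = None,
    n_static: int = 1,
    static_tau: float = 0.05,
    osc_amplitude: float = 1.0,
    omega: float = WAVENUMBER_61_CM_RAD_PS,
    damping_tau: float = 0.9,
    epsilon: float = 1.0,
    t: np.ndarray | None = None,
    noise: float = 0.01,
    seed: int = 0,
) -> tuple[MapSeries, dict]:
    """Map series mixing static structural events with a damped oscillation.

    Static components follow exponential-rise (step-like) time courses;
    the oscillatory pair follows quadrature damped sinusoids
    cos(ωt)·env and sin(ωt)·env with a shared envelope exp(−(t/τ)^ε), so
    their 2-D coefficient projection traces an inward spiral.  The default
    ω is the rad/ps equivalent of 61 cm⁻¹ and the default time window spans
    roughly two periods before the damping extinguishes the signal.
    Component maps are orthonormalized (QR) before mixing, so the stored
    truth components form an orthonormal set.
    """
    grid = MapGrid((8, 8, 8), (1.0, 1.0, 1.0)) if grid is None else grid
    if min(grid.shape) < 4:
        raise ValueError("grid too small to hold distinct components (< 4 per axis)")
    t = np.linspace(0.0, 1.1, 40) if t is None else np.asarray(t, dtype=float)
    rng = np.random.default_rng(seed)

    n_comp = n_static + 2
    raw = np.column_stack([
        serialize_map(_random_blob_map(rng, grid.shape), grid) for _ in range(n_comp)
    ])
    q, _ = np.linalg.qr(raw)
    comp_vectors = q[:, :n_comp]  # orthonormal truth components

    env = np.exp(-np.power(t / damping_tau, epsilon))
    courses = []
    for i in range(n_static):
        tau_i = static_tau * (1.0 + i)
        courses.append(1.0 - np.exp(-t / tau_i))
    courses.append(osc_amplitude * np.cos(omega * t) * env)
    courses.append(osc_amplitude * np.sin(omega * t) * env)
    courses = np.vstack(courses)  # n_comp x N

    clean = comp_vectors @ courses  # M x N serialized
    data = _add_noise(rng, clean, noise)

    from .core_data import deserialize_map

    maps = np.stack([deserialize_map(data[:, j], grid) for j in range(t.size)])
    metadata = MetadataTable(pd.DataFrame({"time_ps": t}), ordering_axis="time_ps")
    series = MapSeries(grid, maps, metadata)
    truth = {
        "component_vectors": comp_vectors, "component_courses": courses,
        "omega": omega, "damping_tau": damping_tau, "epsilon": epsilon,
        "n_static": n_static, "clean": clean, "noise": noise, "seed": seed,
    }
    return series, truth


def inject_artifact(
    series: SpectralSeries | MapSeries,
    artifact: np.ndarray,
    time_course: np.ndarray,
    amplitude: float = 1.0,
) -> tuple[SpectralSeries | MapSeries, dict]:
    """Add a rank-1 systematic-error term amplitude · artifact ⊗ course.

    For spectral series ``artifact`` is a spectrum on the series' wavelength
    grid; for map series it is a 3-D map on the series' grid.  The returned
    truth records the injected triplet so exclusion tests can verify its
    removal during reconstitution.
    """
    time_course = np.asarray(time_course, dtype=float)
    if time_course.size != series.n_observations:
        raise ValueError("time course length must match the number of observations")
    artifact = np.asarray(artifact, dtype=float)
    if isinstance(series, SpectralSeries):
        if artifact.shape != series.wavelengths.shape:
            raise ValueError("artifact spectrum must live on the series wavelength grid")
        data = series.absorbance + amplitude * np.outer(artifact, time_course)
        out = SpectralSeries(series.wavelengths.copy(), data, series.metadata)
    elif isinstance(series, MapSeries):
        if artifact.shape != series.grid.shape:
            raise ValueError("artifact map must live on the series grid")
        data = series.maps + amplitude * time_course[:, None, None, None] * artifact[None]
        out = MapSeries(series.grid, data, series.metadata,
                        mask=None if series.mask is None else series.mask.copy())
    else:
        raise TypeError(f"unsupported series type {type(series).__name__}")
    truth = {"artifact": artifact, "time_course": time_course, "amplitude": amplitude}
    return out, truth
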