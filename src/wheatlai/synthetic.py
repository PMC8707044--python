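"""Synthetic winter-wheat canopy reflectance with a planted, recoverable LAI signal.

The field campaign this pipeline was designed around measured 48 plots per
growth stage; those spectra are not publicly available, so this module
generates stand-in datasets with the statistical structure the screening and
modeling stages rely on: reflectance negatively correlated with LAI in the
visible (soil brighter than leaves under pigment absorption) and positively
correlated in the NIR (leaves brighter than soil).

The canopy model is a deliberately minimal two-flux Beer-Lambert mixture,

    R(lambda) = R_leaf(lambda) + (R_soil(lambda) - R_leaf(lambda)) * exp(-k * LAI),

not a radiative-transfer simulation: the pipeline only needs a controllable,
monotone LAI -> reflectance link whose recovery can be verified exactly.
The default extinction coefficient is small (k = 0.08) so that the link is
close to linear over the per-stage LAI ranges; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet

#: Per-stage (min, max) LAI ranges used when simulating stage datasets.
STAGE_LAI_RANGES: dict[str, tuple[float, float]] = {
    "jointing": (1.0, 4.0),
    "booting": (2.0, 6.0),
    "flowering": (2.0, 7.0),
    "filling": (1.0, 5.0),
}

#: Default pigment (blue/red) and leaf-water absorption troughs:
#: (center_nm, width_nm, depth).  Widths chosen so leaf reflectance stays
#: below the soil line throughout the visible, reproducing the
#: negative-visible / positive-NIR correlation sign pattern with a
#: soil/leaf crossover on the red edge (~716-733 nm).
DEFAULT_ABSORPTION = (
    (450.0, 100.0, 0.45),
    (670.0, 50.0, 0.42),
    (970.0, 55.0, 0.12),
    (1200.0, 70.0, 0.15),
)


@dataclass
class LeafOpticsParams:
    """Gaussian-trough leaf reflectance model on a NIR plateau."""

    nir_plateau: float = 0.5
    absorption_features: tuple[tuple[float, float, float], ...] = DEFAULT_ABSORPTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.nir_plateau <= 1.0:
            raise ValueError("nir_plateau must lie in [0, 1]")
        for center, width, depth in self.absorption_features:
            if not 350.0 <= center <= 1350.0:
                raise ValueError(f"absorption center {center} nm outside 350-1350 nm")
            if width <= 0 or depth < 0:
                raise ValueError("absorption width must be > 0 and depth >= 0")


@dataclass
class CanopySimConfig:
    """Configuration of one simulated stage dataset (48 plots by default)."""

    n_samples: int = 48
    lai_range: tuple[float, float] = STAGE_LAI_RANGES["jointing"]
    extinction_k: float = 0.08
    soil_albedo: float = 0.25
    soil_slope_per_nm: float = 5e-5
    noise_sd: float = 0.01
    seed: int = 0
    stage: str = "jointing"

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        lo, hi = self.lai_range
        if lo < 0 or hi <= lo:
            raise ValueError("lai_range must satisfy 0 <= min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.extinction_k <= 0:
            raise ValueError("extinction_k must be > 0")


def default_wavelength_grid() -> np.ndarray:
    return np.arange(350.0, 1351.0, 1.0)


def simulate_leaf_spectrum(params: LeafOpticsParams, grid: np.ndarray) -> np.ndarray:
    """Leaf reflectance: NIR plateau minus Gaussian absorption troughs.

    The red edge emerges implicitly from the long-wavelength shoulder of the
    670 nm pigment trough.  Output is clipped to [0, 1].
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] < 350.0 or grid[-1] > 1350.0:
        raise ValueError("grid outside the supported 350-1350 nm range")
    spectrum = np.full_like(grid, params.nir_plateau)
    for center, width, depth in params.absorption_features:
        spectrum -= depth * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return np.clip(spectrum, 0.0, 1.0)


def soil_spectrum(config: CanopySimConfig, grid: np.ndarray) -> np.ndarray:
    """Bright, gently sloping bare-soil reflectance line."""
    return config.soil_albedo + config.soil_slope_per_nm * (np.asarray(grid) - 350.0)


def simulate_canopy_reflectance(
    leaf: np.ndarray, soil: np.ndarray, lai: float, k: float
) -> np.ndarray:
    """Beer-Lambert soil/leaf mixing: leaf + (soil - leaf) * exp(-k * LAI).

    At LAI = 0 the canopy is bare soil; as k*LAI grows the soil contribution
    decays exponentially toward the pure-leaf spectrum.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    leaf = np.asarray(leaf, dtype=float)
    soil = np.asarray(soil, dtype=float)
    if leaf.shape != soil.shape:
        raise ValueError("leaf and soil spectra must share a grid")
    return leaf + (soil - leaf) * np.exp(-k * lai)


def generate_dataset(
    config: CanopySimConfig,
    leaf_params: LeafOpticsParams | None = None,
    grid: np.ndarray | None = None,
) -> SpectraSet:
    """Generate one stage dataset: LAI drawn uniformly from ``lai_range``,
    canopy spectra from the Beer-Lambert mixture plus additive Gaussian
    band noise.  Identical seeds give bit-identical datasets.
    """
    if leaf_params is None:
        leaf_params = LeafOpticsParams()
    if grid is None:
        grid = default_wavelength_grid()
    rng = np.random.default_rng(config.seed)
    lai = rng.uniform(*config.lai_range, size=config.n_samples)
    leaf = simulate_leaf_spectrum(leaf_params, grid)
    soil = soil_spectrum(config, grid)
    refl = leaf[None, :] + (soil - leaf)[None, :] * np.exp(
        -config.extinction_k * lai
    )[:, None]
    if config.noise_sd > 0:
        refl = refl + rng.normal(0.0, config.noise_sd, size=refl.shape)
    return SpectraSet(grid, refl, lai, stage=config.stage)
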