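"""Synthetic NIR spectrum generator.

The study data (powdered *Fritillaria* bulbs measured on a handheld 900-1700 nm
instrument) are not public, so this module generates spectra with the same
statistical structure the analysis pipeline assumes:

* a common absorbance backbone of overtone/combination bands shared by all
  four species (water O-H bands near 970 and 1450 nm, C-H bands near 1190 and
  1650 nm, with the 1450 nm O-H first overtone dominant, as in real plant
  powders);
* one class-specific marker band per species at the wavelength region each
  species' Grad-CAM attribution concentrates on (cirrhosa 1575 nm,
  ussuriensis 1460 nm, pallidiflora 1100 nm, thunbergii 1200 nm);
* batch-to-batch variation as a per-(class, batch) relative band-amplitude
  perturbation;
* multiplicative scatter (particle-size effect) as a lognormal gain on the
  band sum plus an additive offset — exactly the model SNV inverts;
* smooth baseline drift (random polynomial of degree <= 2) and iid Gaussian
  noise.

Adulteration mixtures are linear (Beer-Lambert) combinations of the two pure
band sums, (1-p)*cirrhosa + p*ussuriensis, formed *before* the nuisance
effects are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .grid import CANONICAL_GRID, ORIGIN_NAMES, Spectrum, SpectraSet, WavelengthGrid

__all__ = [
    "BandSpec",
    "ClassProfile",
    "GeneratorConfig",
    "default_origin_profiles",
    "band_sum",
    "simulate_spectrum",
    "simulate_origin_dataset",
    "enumerate_adulteration_levels",
    "simulate_adulteration_dataset",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption band: centre (nm), FWHM (nm), peak amplitude (AU)."""

    center_nm: float
    fwhm_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("band fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        d = wavelengths - self.center_nm
        return self.amplitude * np.exp(-_LN2_4 * (d / self.fwhm_nm) ** 2)


@dataclass(frozen=True)
class ClassProfile:
    """Band composition of one species: shared backbone + discriminative markers."""

    class_id: int
    name: str
    shared_bands: tuple
    marker_bands: tuple

    def __post_init__(self) -> None:
        if not self.marker_bands:
            raise ValueError("a class profile needs at least one marker band")

    @property
    def bands(self) -> tuple:
        return self.shared_bands + self.marker_bands


# Shared backbone: water O-H second overtone (970), C-H second overtone (1190),
# dominant water O-H first overtone (1450), C-H first overtone (1650).
_SHARED_BANDS = (
    BandSpec(970.0, 70.0, 0.45),
    BandSpec(1190.0, 60.0, 0.35),
    BandSpec(1450.0, 90.0, 1.00),
    BandSpec(1650.0, 70.0, 0.40),
)

_MARKER_CENTERS = {0: 1575.0, 1: 1460.0, 2: 1100.0, 3: 1200.0}
MARKER_FWHM_NM = 30.0
MARKER_AMPLITUDE = 0.1


def default_origin_profiles() -> List[ClassProfile]:
    """Four species profiles with markers at each species' attribution region.

    cirrhosa: 1575 nm (C-H stretch/bend region 1550-1600);
    ussuriensis: 1460 nm (C-H / alkaloid region, the key discriminator);
    pallidiflora: 1100 nm (O-H region around 1100);
    thunbergii: 1200 nm (C-H region around 1200).
    """
    profiles = []
    for cid, name in enumerate(ORIGIN_NAMES):
        marker = BandSpec(_MARKER_CENTERS[cid], MARKER_FWHM_NM, MARKER_AMPLITUDE)
        profiles.append(ClassProfile(cid, name, _SHARED_BANDS, (marker,)))
    centers = sorted(_MARKER_CENTERS.values())
    assert min(b - a for a, b in zip(centers, centers[1:])) >= 20.0
    return profiles


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional parameters of the synthetic instrument/sample model.

    All standard deviations are in absorbance units except ``scatter_slope_sd``
    and ``batch_shift_sd``, which are dimensionless (relative).  Baseline drift
    is a per-spectrum random polynomial b(t) = c0 + c1*t + c2*t^2 on
    t = (lambda-900)/800, with coefficients drawn uniformly from
    [0, baseline_offset_max], [0, baseline_slope_max] and
    [-baseline_curvature_max, baseline_curvature_max].
    """

    seed: int = 0
    noise_sd: float = 0.005
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    batch_shift_sd: float = 0.05
    baseline_offset_max: float = 0.05
    baseline_slope_max: float = 0.1
    baseline_curvature_max: float = 0.02

    def __post_init__(self) -> None:
        for name in ("noise_sd", "scatter_slope_sd", "scatter_offset_sd",
                     "batch_shift_sd", "baseline_offset_max",
                     "baseline_slope_max", "baseline_curvature_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def without_effects(self) -> "GeneratorConfig":
        """Copy with all nuisance effects switched off (pure band sums)."""
        return replace(self, noise_sd=0.0, scatter_slope_sd=0.0,
                       scatter_offset_sd=0.0, batch_shift_sd=0.0,
                       baseline_offset_max=0.0, baseline_slope_max=0.0,
                       baseline_curvature_max=0.0)


def band_sum(bands: Sequence[BandSpec], grid: WavelengthGrid = CANONICAL_GRID,
             amplitude_scale: float = 1.0) -> np.ndarray:
    wl = grid.wavelengths
    out = np.zeros_like(wl)
    for b in bands:
        out += b.profile(wl)
    return amplitude_scale * out


def _nuisance(clean: np.ndarray, config: GeneratorConfig, rng: np.random.Generator,
              grid: WavelengthGrid) -> np.ndarray:
    """Apply scatter, baseline, offset and noise to a clean band sum.

    Draw order is fixed so that a given rng state always yields the same
    spectrum regardless of which effects are switched off.
    """
    m = np.exp(rng.normal(0.0, 1.0) * config.scatter_slope_sd)
    offset = rng.normal(0.0, 1.0) * config.scatter_offset_sd
    u = rng.uniform(0.0, 1.0, size=3)
    c0 = u[0] * config.baseline_offset_max
    c1 = u[1] * config.baseline_slope_max
    c2 = (2.0 * u[2] - 1.0) * config.baseline_curvature_max
    t = (grid.wavelengths - grid.start_nm) / (grid.end_nm - grid.start_nm)
    baseline = c0 + c1 * t + c2 * t * t
    eps = rng.standard_normal(grid.n_points) * config.noise_sd
    return m * clean + baseline + offset + eps


def simulate_spectrum(profile: ClassProfile, batch_effect: float,
                      config: GeneratorConfig,
                      rng: Optional[np.random.Generator] = None,
                      grid: WavelengthGrid = CANONICAL_GRID) -> Spectrum:
    """One spectrum: scattered/drifting/noisy copy of the class band sum.

    ``batch_effect`` perturbs every band amplitude relatively
    (amplitude * (1 + batch_effect)); it is drawn once per (class, batch) by
    the dataset generators.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clean = band_sum(profile.bands, grid, amplitude_scale=1.0 + batch_effect)
    return Spectrum(_nuisance(clean, config, rng, grid), grid)


def simulate_origin_dataset(config: GeneratorConfig, n_batches: int = 4,
                            n_per_batch: int = 45,
                            profiles: Optional[Sequence[ClassProfile]] = None,
                            grid: WavelengthGrid = CANONICAL_GRID) -> SpectraSet:
    """Origin-identification dataset: 4 classes x n_batches x n_per_batch.

    Defaults reproduce the study design: 4 batches of 45 acquisitions per
    origin, 180 spectra per origin, 720 in total.
    """
    if n_batches < 1 or n_per_batch < 1:
        raise ValueError("counts must be >= 1")
    if profiles is None:
        profiles = default_origin_profiles()
    rng = np.random.default_rng(config.seed)
    rows, labels, batches = [], [], []
    for profile in profiles:
        for b in range(n_batches):
            batch_effect = rng.normal(0.0, 1.0) * config.batch_shift_sd
            for _ in range(n_per_batch):
                s = simulate_spectrum(profile, batch_effect, config, rng, grid)
                rows.append(s.absorbance)
                labels.append(profile.class_id)
                batches.append(b)
    return SpectraSet(np.array(rows), np.array(labels), label_kind="origin",
                      batch_ids=np.array(batches), grid=grid,
                      class_names=tuple(p.name for p in profiles),
                      meta={"generator": "simulate_origin_dataset",
                            "seed": config.seed})


def enumerate_adulteration_levels() -> List[float]:
    """The 29 gravimetric adulteration fractions of the study design.

    Every 0.5% from 0.1% up to 10%, then every 5% up to 50%:
    0.001, 0.006, ..., 0.096 (20 levels) plus 0.10, 0.15, ..., 0.50 (9 levels).
    """
    fine = [round(0.001 + 0.005 * i, 3) for i in range(20)]
    coarse = [round(0.10 + 0.05 * i, 2) for i in range(9)]
    return fine + coarse


def simulate_adulteration_dataset(config: GeneratorConfig,
                                  levels: Optional[Sequence[float]] = None,
                                  n_per_level: int = 20,
                                  grid: WavelengthGrid = CANONICAL_GRID) -> SpectraSet:
    """Two-component mixture dataset: (1-p)*cirrhosa + p*ussuriensis.

    Mixing is linear in the pure band sums (Beer-Lambert) and happens before
    scatter/baseline/noise.  Defaults give 29 levels x 20 replicates = 580.
    """
    if levels is None:
        levels = enumerate_adulteration_levels()
    levels = [float(p) for p in levels]
    if any(p < 0 or p > 1 for p in levels):
        raise ValueError("adulteration fractions must lie in [0, 1]")
    profiles = default_origin_profiles()
    pure_a = band_sum(profiles[0].bands, grid)   # F. cirrhosa (matrix)
    pure_b = band_sum(profiles[1].bands, grid)   # F. ussuriensis (adulterant)
    rng = np.random.default_rng(config.seed)
    rows, labels = [], []
    for p in levels:
        clean = (1.0 - p) * pure_a + p * pure_b
        for _ in range(n_per_level):
            rows.append(_nuisance(clean, config, rng, grid))
            labels.append(p)
    return SpectraSet(np.array(rows), np.array(labels), label_kind="fraction",
                      grid=grid,
                      meta={"generator": "simulate_adulteration_dataset",
                            "seed": config.seed})
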