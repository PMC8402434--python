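"""Class-structured synthetic leaf reflectance spectra and hyperspectral cubes.

The study groups are ``BH`` (plants before heat stress), ``AR`` (heat-stressed
resistant varieties) and ``AS`` (heat-stressed susceptible variety). No
spectra from the original experiment were released, so this module generates
stand-in data with known ground truth:

* per-group archetype spectra built as a smooth leaf-like baseline (green
  peak near 550 nm and chlorophyll trough near 680 nm in the Vis/NIR,
  water-absorption trough near 1450 nm in the SWIR) plus group-dependent
  absorption features confined to a known set of informative bands;
* per-sample multiplicative/additive scatter and band-correlated noise;
* small cubes whose leaf pixels carry an archetype plus pixel noise on a
  dark background, with the ground-truth mask returned alongside.

Group separations default to the geometry observed in the real data: in
the Vis/NIR the resistant group sits about three quarters of the way from
unstressed to susceptible (levels 0, 0.74, 1.0 for BH, AR, AS); in the
SWIR the resistant group is farthest from unstressed (0, 1.0, 0.89).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import HyperCube, LeafMask, SpectrumTable

__all__ = [
    "GROUPS",
    "REGIONS",
    "ClassArchetype",
    "NoiseConfig",
    "Ellipse",
    "make_archetypes",
    "simulate_spectra",
    "simulate_cube",
]

GROUPS = ("BH", "AR", "AS")

#: wavelength span (nm) per spectral region
REGIONS = {"visnir": (400.0, 1000.0), "swir": (1000.0, 1800.0)}

#: group effect levels (fraction of effect_size) per region; BH is the
#: unstressed reference at 0, the farthest group sits at 1.
GROUP_LEVELS = {
    "visnir": {"BH": 0.0, "AR": 0.74, "AS": 1.0},
    "swir": {"BH": 0.0, "AR": 1.0, "AS": 0.89},
}

#: default centres (nm) of the group-dependent absorption features
FEATURE_CENTERS = {
    "visnir": (521.0, 555.0, 603.0, 641.0, 679.0, 722.0),
    "swir": (1030.0, 1218.0, 1359.0, 1441.0, 1571.0, 1742.0),
}

_VARIETIES = {"BH": ("Chunpoong", "Sunmyoung", "Sunil"), "AR": ("Sunmyoung", "Sunil"), "AS": ("Chunpoong",)}


@dataclass
class ClassArchetype:
    """Noise-free mean spectrum of one group, with the planted signal bands."""

    group_label: str
    wavelengths: np.ndarray
    mean_spectrum: np.ndarray
    informative_bands: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        self.informative_bands = np.asarray(self.informative_bands, dtype=int)
        if self.mean_spectrum.shape != self.wavelengths.shape:
            raise ValueError("mean_spectrum and wavelengths must align")
        if self.mean_spectrum.min() < 0.01 or self.mean_spectrum.max() > 0.99:
            raise ValueError("archetype reflectance must lie in [0.01, 0.99]")


@dataclass
class NoiseConfig:
    """Noise magnitudes for the sample- and pixel-level generators.

    ``scatter_slope_sd``/``scatter_offset_sd`` give multiplicative and
    additive per-sample scatter (a ~ N(1, slope), b ~ N(0, offset));
    ``correlated_noise_sd`` is the marginal SD of Gaussian-smoothed
    spectral noise with kernel width ``correlation_length`` bands;
    ``pixel_noise_sd`` applies independently per pixel and band in cubes.
    """

    scatter_slope_sd: float = 0.04
    scatter_offset_sd: float = 0.008
    correlated_noise_sd: float = 0.006
    correlation_length: float = 5.0
    pixel_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_slope_sd", "scatter_offset_sd", "correlated_noise_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1 band")


@dataclass
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates: leaf geometry primitive."""

    center: tuple[float, float]
    semiaxes: tuple[float, float]

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        cr, cc = self.center
        a, b = self.semiaxes
        return ((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0


def _baseline(region: str, wl: np.ndarray) -> np.ndarray:
    if region == "visnir":
        red_edge = 0.42 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
        green_peak = 0.06 * np.exp(-((wl - 550.0) ** 2) / (2 * 30.0**2))
        chl_trough = -0.02 * np.exp(-((wl - 680.0) ** 2) / (2 * 18.0**2))
        return 0.05 + red_edge + green_peak + chl_trough
    # swir: NIR plateau decaying into the 1450 nm water band and the 1800 nm edge
    water = -0.25 * np.exp(-((wl - 1450.0) ** 2) / (2 * 45.0**2))
    edge = -0.08 * np.exp(-((wl - 1790.0) ** 2) / (2 * 60.0**2))
    return 0.45 + water + edge - 5e-5 * (wl - 1000.0)


def make_archetypes(
    region: str,
    n_bands: int = 128,
    effect_size: float = 0.08,
    seed: int = 0,
    feature_width: float | None = None,
    feature_centers: tuple[float, ...] | None = None,
    group_levels: dict[str, float] | None = None,
) -> tuple[ClassArchetype, ClassArchetype, ClassArchetype]:
    """Build the three group archetypes on a uniform wavelength grid.

    Parameters
    ----------
    region : {"visnir", "swir"}
        400-1000 nm or 1000-1800 nm grid.
    n_bands : int
        Bands on the uniform grid (>= 16).
    effect_size : float
        Reflectance difference between the reference group and the farthest
        group at the feature peaks. Zero yields three identical archetypes.
    feature_width : float or None
        Gaussian feature sigma in nm. ``0`` plants single-band deltas
        (informative_bands is then exactly the feature centres); ``None``
        picks a smooth default (~2.5 grid steps).
    feature_centers, group_levels
        Override the per-region defaults.
    seed : int
        Present for interface symmetry; archetype construction is
        deterministic given the other arguments.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {tuple(REGIONS)}")
    if n_bands < 16:
        raise ValueError("n_bands must be >= 16 to place spectral features")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")

    lo, hi = REGIONS[region]
    wl = np.linspace(lo, hi, n_bands)
    step = wl[1] - wl[0]
    base = _baseline(region, wl)

    centers = FEATURE_CENTERS[region] if feature_centers is None else tuple(feature_centers)
    levels = GROUP_LEVELS[region] if group_levels is None else dict(group_levels)
    if feature_width is None:
        feature_width = 2.5 * step

    template = np.zeros(n_bands)
    if effect_size > 0:
        for c in centers:
            if not (wl[0] <= c <= wl[-1]):
                raise ValueError(f"feature centre {c} nm outside the {region} grid")
            if feature_width == 0:
                template[int(np.argmin(np.abs(wl - c)))] = 1.0
            else:
                template += np.exp(-((wl - c) ** 2) / (2 * feature_width**2))
        template[template < 0.01 * template.max()] = 0.0
        template /= template.max()
    informative = np.nonzero(template)[0]

    archetypes = []
    for g in GROUPS:
        spec = np.clip(base + effect_size * levels[g] * template, 0.01, 0.99)
        archetypes.append(ClassArchetype(g, wl, spec, informative))
    return tuple(archetypes)


def _smooth_noise_scale(n_bands: int, sigma: float) -> float:
    """SD attenuation of a unit-variance white series under Gaussian smoothing."""
    impulse = np.zeros(n_bands)
    impulse[n_bands // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma, mode="constant")
    return float(np.sqrt(np.sum(kernel**2)))


def simulate_spectra(
    archetypes: tuple[ClassArchetype, ...],
    n_per_group: tuple[int, ...] = (377, 192, 144),
    noise: NoiseConfig | None = None,
) -> SpectrumTable:
    """Draw labelled sample spectra: ``a * archetype + b + smooth noise``.

    ``a ~ N(1, scatter_slope_sd)`` and ``b ~ N(0, scatter_offset_sd)`` model
    per-leaf brightness scatter; the smooth term is Gaussian-filtered white
    noise rescaled to marginal SD ``correlated_noise_sd``. Default group
    sizes follow the study accounting (377 BH, 192 AR, 144 AS).
    """
    noise = noise or NoiseConfig()
    if len(n_per_group) != len(archetypes):
        raise ValueError("need one group size per archetype")
    if any(n < 0 for n in n_per_group):
        raise ValueError("group sizes must be non-negative")

    rng = np.random.default_rng(noise.seed)
    n_bands = archetypes[0].wavelengths.size
    scale = _smooth_noise_scale(n_bands, noise.correlation_length)

    rows, groups, varieties = [], [], []
    for arch, n in zip(archetypes, n_per_group):
        pool = _VARIETIES.get(arch.group_label, ("",))
        for i in range(n):
            a = 1.0 + noise.scatter_slope_sd * rng.standard_normal()
            b = noise.scatter_offset_sd * rng.standard_normal()
            smooth = gaussian_filter1d(rng.standard_normal(n_bands), noise.correlation_length, mode="reflect")
            smooth *= noise.correlated_noise_sd / scale if scale > 0 else 0.0
            rows.append(a * arch.mean_spectrum + b + smooth)
            groups.append(arch.group_label)
            varieties.append(pool[i % len(pool)])
    if not rows:
        raise ValueError("no samples requested")
    return SpectrumTable(
        np.vstack(rows), archetypes[0].wavelengths, groups, varieties,
        pixel_count=np.ones(len(rows), dtype=int),
    )


def simulate_cube(
    archetype: ClassArchetype,
    shape: tuple[int, int] = (64, 64),
    leaf_geometry: Ellipse | list[Ellipse] | None = None,
    noise: NoiseConfig | None = None,
    background_level: float = 0.03,
) -> tuple[HyperCube, LeafMask]:
    """Render a small reflectance cube of one leaf with known mask.

    Leaf pixels carry the archetype plus i.i.d. pixel noise; background
    pixels are a flat low-reflectance floor (<= 0.05).
    """
    noise = noise or NoiseConfig()
    lines, samples = shape
    if lines < 16 or samples < 16:
        raise ValueError("cube shape must be at least 16 x 16")
    if leaf_geometry is None:
        leaf_geometry = Ellipse((lines / 2, samples / 2), (0.35 * lines, 0.3 * samples))
    ellipses = [leaf_geometry] if isinstance(leaf_geometry, Ellipse) else list(leaf_geometry)

    for e in ellipses:
        cr, cc = e.center
        a, b = e.semiaxes
        if cr - a < 0 or cr + a > lines - 1 or cc - b < 0 or cc + b > samples - 1:
            raise ValueError("leaf ellipse does not fit inside the cube frame")

    rr, cc = np.mgrid[0:lines, 0:samples]
    mask = np.zeros((lines, samples), dtype=bool)
    labels = np.zeros((lines, samples), dtype=int)
    for k, e in enumerate(ellipses, start=1):
        inside = e.contains(rr, cc)
        labels[inside & ~mask] = k
        mask |= inside
    # merged ellipses may leave label gaps; compact to 1..L
    present = np.unique(labels[labels > 0])
    remap = {old: new for new, old in enumerate(present, start=1)}
    for old, new in remap.items():
        labels[labels == old] = new

    rng = np.random.default_rng(noise.seed)
    n_bands = archetype.wavelengths.size
    data = np.full((lines, samples, n_bands), background_level, dtype=float)
    n_leaf = int(mask.sum())
    leaf_px = archetype.mean_spectrum + noise.pixel_noise_sd * rng.standard_normal((n_leaf, n_bands))
    data[mask] = np.clip(leaf_px, 0.0, 1.0)

    cube = HyperCube(data, archetype.wavelengths, units="reflectance",
                     metadata={"description": f"synthetic {archetype.group_label} leaf"})
    return cube, LeafMask(mask, labels)
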