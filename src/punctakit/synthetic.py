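"""Synthetic fluorescence scenes emulating genotype phenotype classes.

The study system is a fluorescent synaptic-vesicle reporter (e.g. GFP-tagged
RAB-3 or synaptobrevin) imaged along the *C. elegans* dorsal nerve cord.
Four qualitative phenotype classes are emulated:

* ``wild_type`` — discrete bright puncta on a dim axonal baseline;
* ``diffuse_mutant`` — punctate localization lost, reporter spread evenly
  along the axon (elevated baseline, no puncta), as in vesicle-trafficking
  mutants such as *snt-1*, *aex-3* or *rep-1*;
* ``enlarged_puncta`` — puncta larger and brighter than wild type, as in
  mutants with enhanced synaptic enrichment (*rbg-1*, *unc-2*, *unc-13*);
* ``soma_retention`` — the reporter trapped in neuronal cell bodies with
  the cord nearly empty, as in kinesin (*unc-104*) mutants.

Each scene carries a ground-truth punctum table so detection and
quantification can be scored exactly. Intensities are arbitrary units (AU);
the absolute scale is a simulation choice, not a measured quantity — the
downstream ratio statistics are scale-free.

The camera model is Poisson shot noise scaled by a gain, plus an additive
offset and Gaussian read noise:

``out = Poisson(signal * gain) / gain + offset + N(0, read_noise_sd)``

clipped at zero. Puncta are isotropic Gaussians (an effective point-spread
blur); no optics-accurate PSF, 3D stacks or photobleaching are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import IntensityProfile, Polyline

__all__ = ["GenotypePreset", "SceneTruth", "preset_library", "get_preset", "make_profile", "make_image"]

#: margin (µm) kept between puncta and, from each cord end, the scene border
MIN_PUNCTUM_SEPARATION_UM = 2.0
#: arc distance (µm) of soma blob centers from each cord end
SOMA_OFFSET_UM = 5.0


@dataclass(frozen=True)
class GenotypePreset:
    """Generative parameters of one phenotype class.

    punctum_density
        Expected puncta per µm of cord.
    amplitude_mean, amplitude_sd
        Punctum peak height above the axonal baseline (AU).
    punctum_sigma_um
        Gaussian punctum width (µm).
    diffuse_level
        Baseline axonal intensity above the camera offset (AU).
    camera_offset
        Additive camera constant (AU), present even off-specimen.
    noise_gain
        Poisson scaling: photon counts per AU; larger = less shot noise.
    read_noise_sd
        Gaussian read noise (AU).
    soma_fraction
        Fraction of total above-offset signal placed in cell-body blobs.
    soma_sigma_um
        Gaussian width of each soma blob (µm).
    """

    name: str
    punctum_density: float
    amplitude_mean: float
    amplitude_sd: float
    punctum_sigma_um: float
    diffuse_level: float
    camera_offset: float = 5.0
    noise_gain: float = 4.0
    read_noise_sd: float = 1.0
    soma_fraction: float = 0.0
    soma_sigma_um: float = 3.0

    def __post_init__(self) -> None:
        nonneg = {
            "punctum_density": self.punctum_density,
            "amplitude_mean": self.amplitude_mean,
            "amplitude_sd": self.amplitude_sd,
            "punctum_sigma_um": self.punctum_sigma_um,
            "diffuse_level": self.diffuse_level,
            "camera_offset": self.camera_offset,
            "noise_gain": self.noise_gain,
            "read_noise_sd": self.read_noise_sd,
            "soma_sigma_um": self.soma_sigma_um,
        }
        for key, val in nonneg.items():
            if val < 0:
                raise ValueError(f"{key} must be >= 0, got {val}")
        if not 0.0 <= self.soma_fraction <= 1.0:
            raise ValueError("soma_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of one generated scene (for scoring, not analysis)."""

    punctum_positions_um: np.ndarray
    punctum_amplitudes: np.ndarray
    preset: GenotypePreset
    seed: int
    soma_centers_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_puncta(self) -> int:
        return int(np.asarray(self.punctum_positions_um).size)


def preset_library() -> list[GenotypePreset]:
    """The four built-in phenotype presets.

    All magnitudes are documented simulation defaults chosen so that
    wild-type puncta stay mutually resolved and clear the ratio-2 calling
    rule with margin (peak ≈ 145 AU against an inter-punctal average that
    the Gaussian tails raise to ≈ 50 AU) and the class contrasts (diffuse,
    enlarged, soma-retained) are unambiguous. Enlarged puncta are placed
    more sparsely than wild type: at wild-type density their doubled width
    would merge neighbours into a quasi-diffuse ridge instead of the
    resolved oversized puncta the phenotype shows.
    """
    return [
        GenotypePreset(
            name="wild_type",
            punctum_density=0.3,
            amplitude_mean=120.0,
            amplitude_sd=12.0,
            punctum_sigma_um=0.5,
            diffuse_level=20.0,
        ),
        GenotypePreset(
            name="diffuse_mutant",
            punctum_density=0.0,
            amplitude_mean=0.0,
            amplitude_sd=0.0,
            punctum_sigma_um=0.5,
            diffuse_level=60.0,
        ),
        GenotypePreset(
            name="enlarged_puncta",
            punctum_density=0.15,
            amplitude_mean=200.0,
            amplitude_sd=25.0,
            punctum_sigma_um=0.8,
            diffuse_level=20.0,
        ),
        GenotypePreset(
            name="soma_retention",
            punctum_density=0.05,
            amplitude_mean=30.0,
            amplitude_sd=5.0,
            punctum_sigma_um=0.5,
            diffuse_level=2.0,
            soma_fraction=0.95,
        ),
    ]


def get_preset(name: str) -> GenotypePreset:
    for preset in preset_library():
        if preset.name == name:
            return preset
    known = ", ".join(p.name for p in preset_library())
    raise KeyError(f"unknown preset {name!r}; available: {known}")


def _scene_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    # independent sub-streams so a placement is reusable across noise draws
    place_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(place_ss), np.random.default_rng(noise_ss)


def _place_puncta(
    rng: np.random.Generator, preset: GenotypePreset, length_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw punctum positions and amplitudes.

    The count is Poisson with mean ``density * length``; positions are
    uniform with a hard minimum separation, placed by sequential rejection
    (a point failing 1000 draws is dropped — practically never at default
    densities). Amplitudes are Gaussian, clipped at zero.
    """
    n = int(rng.poisson(preset.punctum_density * length_um))
    sep = MIN_PUNCTUM_SEPARATION_UM
    lo, hi = min(sep, length_um / 2), max(length_um - sep, length_um / 2)
    positions: list[float] = []
    for _ in range(n):
        for _ in range(1000):
            x = float(rng.uniform(lo, hi))
            if all(abs(x - q) >= sep for q in positions):
                positions.append(x)
                break
    pos = np.sort(np.asarray(positions))
    amps = np.clip(rng.normal(preset.amplitude_mean, preset.amplitude_sd, pos.size), 0.0, None)
    return pos, amps


def _apply_camera(
    rng: np.random.Generator, signal: np.ndarray, preset: GenotypePreset
) -> np.ndarray:
    if preset.noise_gain > 0:
        counts = rng.poisson(signal * preset.noise_gain) / preset.noise_gain
    else:  # noiseless configuration
        counts = signal.copy()
    out = counts + preset.camera_offset
    if preset.read_noise_sd > 0:
        out = out + rng.normal(0.0, preset.read_noise_sd, signal.shape)
    return np.clip(out, 0.0, None)


def _gaussian_bumps(x: np.ndarray, centers: np.ndarray, amps: np.ndarray, sigma: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for c, a in zip(centers, amps):
        out += a * np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    return out


def make_profile(
    preset: GenotypePreset, length_um: float, pixel_size_um: float, seed: int
) -> tuple[IntensityProfile, SceneTruth]:
    """Generate a 1D cord profile with ground truth.

    The noiseless signal is ``diffuse_level`` plus one Gaussian bump per
    punctum (plus soma blobs near the cord ends when ``soma_fraction > 0``),
    passed through the camera model. Identical arguments give bit-identical
    output.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    place_rng, noise_rng = _scene_rngs(seed)

    positions, amps = _place_puncta(place_rng, preset, length_um)
    n_samples = int(round(length_um / pixel_size_um)) + 1
    x = np.arange(n_samples) * pixel_size_um
    signal = preset.diffuse_level + _gaussian_bumps(x, positions, amps, preset.punctum_sigma_um)

    soma_centers = np.empty(0)
    if preset.soma_fraction > 0:
        if preset.soma_fraction >= 1.0:
            raise ValueError("soma_fraction must be < 1 when generating scenes")
        soma_centers = np.array([SOMA_OFFSET_UM, length_um - SOMA_OFFSET_UM])
        unit = _gaussian_bumps(x, soma_centers, np.ones(soma_centers.size), preset.soma_sigma_um)
        cord_total = signal.sum()
        sf = preset.soma_fraction
        if unit.sum() > 0 and cord_total > 0:
            signal = signal + unit * (sf / (1.0 - sf) * cord_total / unit.sum())

    intensities = _apply_camera(noise_rng, signal, preset)
    profile = IntensityProfile(positions_um=x, intensities=intensities, pixel_size_um=pixel_size_um)
    truth = SceneTruth(
        punctum_positions_um=positions,
        punctum_amplitudes=amps,
        preset=preset,
        seed=seed,
        soma_centers_um=soma_centers,
    )
    return profile, truth


def _point_segment_distance(
    px: np.ndarray, py: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    d = b - a
    t = ((px - a[0]) * d[0] + (py - a[1]) * d[1]) / (d @ d)
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * d[0]), py - (a[1] + t * d[1]))


def make_image(
    preset: GenotypePreset,
    shape_px: tuple[int, int],
    trace: Polyline,
    pixel_size_um: float,
    seed: int,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a 2D scene whose line scan along ``trace`` matches the preset.

    The diffuse axonal signal is a Gaussian-cross-section ridge along the
    trace (width = ``punctum_sigma_um``) whose on-cord value is
    ``diffuse_level``; puncta are isotropic 2D Gaussians centered on the
    trace at their ground-truth arc positions; soma blobs are wide Gaussians
    near the trace endpoints, scaled so that ``soma_fraction`` of the total
    above-offset signal lies in them. The camera model matches
    :func:`make_profile`. Returns a float image; use
    :func:`punctakit.io.write_image` for 16-bit TIFF output.
    """
    rows, cols = shape_px
    if rows <= 0 or cols <= 0:
        raise ValueError("shape_px must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not trace.bounds_ok((rows, cols)):
        raise ValueError("trace vertices fall outside the image bounds")
    place_rng, noise_rng = _scene_rngs(seed)

    length_um = trace.length_px * pixel_size_um
    positions, amps = _place_puncta(place_rng, preset, length_um)

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    px, py = xx.ravel(), yy.ravel()
    dist = np.full(px.size, np.inf)
    verts = trace.vertices
    for a, b in zip(verts[:-1], verts[1:]):
        dist = np.minimum(dist, _point_segment_distance(px, py, a, b))
    sigma_px = preset.punctum_sigma_um / pixel_size_um
    signal = preset.diffuse_level * np.exp(-(dist**2) / (2.0 * sigma_px**2))
    signal = signal.reshape(rows, cols)

    pts, _ = trace.point_at(positions / pixel_size_um)
    for (cx, cy), a in zip(pts, amps):
        signal += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma_px**2))

    soma_centers = np.empty(0)
    if preset.soma_fraction > 0:
        if preset.soma_fraction >= 1.0:
            raise ValueError("soma_fraction must be < 1 when generating scenes")
        soma_centers = np.array([SOMA_OFFSET_UM, length_um - SOMA_OFFSET_UM])
        soma_pts, _ = trace.point_at(soma_centers / pixel_size_um)
        s_px = preset.soma_sigma_um / pixel_size_um
        unit = np.zeros_like(signal)
        for cx, cy in soma_pts:
            unit += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * s_px**2))
        cord_total = signal.sum()
        sf = preset.soma_fraction
        if unit.sum() > 0 and cord_total > 0:
            signal = signal + unit * (sf / (1.0 - sf) * cord_total / unit.sum())

    image = _apply_camera(noise_rng, signal, preset)
    truth = SceneTruth(
        punctum_positions_um=positions,
        punctum_amplitudes=amps,
        preset=preset,
        seed=seed,
        soma_centers_um=soma_centers,
    )
    return image, truth
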