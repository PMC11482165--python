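"""Synthetic dynamic-speckle phantom with per-pixel ground truth.

Fully developed OCT speckle is modelled per pixel as a circular complex
Gaussian field whose intensity |E|² is exponentially distributed.  The
frame-to-frame field dynamics follow a stationary AR(1) process

    E_{t+1} = ρ·E_t + sqrt(1 − ρ²)·ε_t,   ε_t ~ CN(0, 1) i.i.d.,

where ρ is the temporal field correlation: ρ near 1 in static tissue
(speckle pattern stable over time), ρ low inside vessels (moving blood
decorrelates the field; ρ maps monotonically to flow, but is the
phantom's ground-truth parameter, not a velocity).  Mean intensity
decays exponentially with depth below the tissue surface, and pixels
above the surface carry only the additive (half-normal) noise floor —
emulating the depth-dependent SNR loss of real skin OCT.  Pixels are
spatially independent by default; an optional complex-field blur adds
a speckle grain size.

Every generated volume ships with its ground truth: the per-pixel ρ
map, the vessel mask, and (on request) a Monte-Carlo estimate of the
expected pairwise L1 decorrelation, used as an independent oracle for
the downstream methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BScanBlock, OCTVolume

__all__ = ["Vessel", "PhantomSpec", "PhantomVolume", "generate_phantom", "expected_l1_map"]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class Vessel:
    """A circular vessel cross-section in the X-Z plane.

    ``center_z``/``center_x`` are absolute pixel coordinates, ``radius_px``
    the disk radius, and ``rho`` the temporal field correlation inside
    the vessel (0 = fully decorrelating flow).  ``meander_amp_px`` /
    ``meander_period`` optionally let the x-centre drift sinusoidally
    along the slow axis so en-face projections show curved tracks.
    """

    center_z: int
    center_x: int
    radius_px: float
    rho: float
    meander_amp_px: float = 0.0
    meander_period: float = 16.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError(f"vessel rho must be in [0, 1), got {self.rho}")


def _default_vessels() -> tuple[Vessel, ...]:
    # three dermal vessels at increasing depth below the default surface row
    return (
        Vessel(center_z=8 + 25, center_x=20, radius_px=5, rho=0.15),
        Vessel(center_z=8 + 45, center_x=60, radius_px=6, rho=0.30),
        Vessel(center_z=8 + 70, center_x=40, radius_px=5, rho=0.10),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic C-scan.

    Defaults describe a desk-scale analogue of a skin acquisition: a
    160 px deep × 96 px wide B-scan, 10 repeats per slow-axis location,
    16 locations, near-static dermis (ρ = 0.95), three vasodilated
    vessels in the top 90 px below the surface, mild exponential
    attenuation and a small half-normal noise floor.
    """

    height_px: int = 160
    width_px: int = 96
    n_frames: int = 10
    n_y_locations: int = 16
    vessel_list: tuple[Vessel, ...] = field(default_factory=_default_vessels)
    static_rho: float = 0.95
    attenuation_per_px: float = 0.015
    noise_floor: float = 0.05
    surface_z: int = 8
    speckle_blur_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1 or self.n_frames < 1 or self.n_y_locations < 1:
            raise ParameterError("phantom dimensions must be positive")
        if not (0.0 < self.static_rho <= 1.0):
            raise ParameterError("static_rho must be in (0, 1]")
        if self.attenuation_per_px < 0 or self.noise_floor < 0:
            raise ParameterError("attenuation and noise_floor must be non-negative")
        if not (0 <= self.surface_z < self.height_px):
            raise ParameterError("surface_z must lie inside the image")
        for v in self.vessel_list:
            if not (
                v.radius_px <= v.center_z <= self.height_px - 1 - v.radius_px
                and v.radius_px <= v.center_x <= self.width_px - 1 - v.radius_px
            ):
                raise ParameterError(f"vessel {v} does not lie within the image")


@dataclass
class PhantomVolume:
    """A generated phantom plus its ground truth, per y-location."""

    volume: OCTVolume
    truth_rho: np.ndarray  # (n_y, H, W)
    vessel_mask: np.ndarray  # (n_y, H, W) bool
    spec: PhantomSpec


def _rho_maps(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-y ρ map and vessel mask from the vessel geometry."""
    h, w, n_y = spec.height_px, spec.width_px, spec.n_y_locations
    zz, xx = np.mgrid[0:h, 0:w]
    rho = np.full((n_y, h, w), spec.static_rho)
    mask = np.zeros((n_y, h, w), dtype=bool)
    for y in range(n_y):
        for v in spec.vessel_list:
            cx = v.center_x + v.meander_amp_px * np.sin(2 * np.pi * y / v.meander_period)
            disk = (zz - v.center_z) ** 2 + (xx - cx) ** 2 <= v.radius_px**2
            rho[y][disk] = v.rho
            mask[y] |= disk
    return rho, mask


def _depth_gain(spec: PhantomSpec) -> np.ndarray:
    """Mean-intensity profile A(z): exp decay below the surface, ~0 above."""
    z = np.arange(spec.height_px)
    gain = np.exp(-spec.attenuation_per_px * (z - spec.surface_z))
    gain[z < spec.surface_z] = 0.0
    return gain


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Simulate the phantom volume; deterministic given ``spec.seed``.

    Each pixel's complex field evolves by the AR(1) recursion with the
    pixel's ground-truth ρ; intensity is A(z)·|E_t|² plus the additive
    half-normal noise floor.
    """
    rng = np.random.default_rng(spec.seed)
    h, w, n, n_y = spec.height_px, spec.width_px, spec.n_frames, spec.n_y_locations
    rho, mask = _rho_maps(spec)
    gain = _depth_gain(spec)[None, :, None]  # broadcast over (y?, z, x)

    blocks = []
    for y in range(n_y):
        e = (rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))) / np.sqrt(2)
        r = rho[y]
        innov = np.sqrt(1.0 - r**2)
        frames = np.empty((n, h, w))
        for t in range(n):
            if t > 0:
                eps = (rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))) / np.sqrt(2)
                e = r * e + innov * eps
            ef = e
            if spec.speckle_blur_px > 0:
                ef = ndimage.gaussian_filter(e.real, spec.speckle_blur_px) + 1j * ndimage.gaussian_filter(
                    e.imag, spec.speckle_blur_px
                )
            noise = spec.noise_floor * np.abs(rng.standard_normal((h, w)))
            frames[t] = gain[0] * np.abs(ef) ** 2 + noise
        blocks.append(BScanBlock(frames=frames, y_index=y))

    vol = OCTVolume(
        blocks=blocks,
        metadata={
            "phantom_seed": spec.seed,
            "intensity_scale": "linear",
            "surface_z": spec.surface_z,
        },
    )
    return PhantomVolume(volume=vol, truth_rho=rho, vessel_mask=mask, spec=spec)


def expected_l1_map(spec: PhantomSpec, mc_samples: int = 20_000, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo expectation of the adjacent-pair L1 decorrelation.

    Returns ``(expected, stderr)``, each ``(H, W)`` (identical across y
    for non-meandering vessels; computed from the y=0 ρ map).  The
    expectation E|I_t − I_{t+1}| depends on a pixel only through
    (ρ, A(z)), so one simulation per distinct (ρ, depth) cell suffices.

    Closed-form anchor: at ρ = 0, A = 1 and zero noise the intensities
    are i.i.d. unit-mean exponentials, whose difference is Laplace with
    E|X − Y| = 1.
    """
    if mc_samples < 10_000:
        raise ParameterError("mc_samples must be >= 1e4 for a usable oracle")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    rho_map = _rho_maps(spec)[0][0]
    gain = _depth_gain(spec)

    expected = np.zeros_like(rho_map)
    stderr = np.zeros_like(rho_map)
    cache: dict[tuple[float, float], tuple[float, float]] = {}
    for z in range(spec.height_px):
        for r in np.unique(rho_map[z]):
            key = (float(r), float(gain[z]))
            if key not in cache:
                cache[key] = _mc_expected_l1(
                    rng, float(r), float(gain[z]), spec.noise_floor, mc_samples
                )
            mu, se = cache[key]
            sel = rho_map[z] == r
            expected[z, sel] = mu
            stderr[z, sel] = se
    return expected, stderr


def _mc_expected_l1(
    rng: np.random.Generator, rho: float, gain: float, noise_floor: float, mc_samples: int
) -> tuple[float, float]:
    e1 = (rng.standard_normal(mc_samples) + 1j * rng.standard_normal(mc_samples)) / np.sqrt(2)
    eps = (rng.standard_normal(mc_samples) + 1j * rng.standard_normal(mc_samples)) / np.sqrt(2)
    e2 = rho * e1 + np.sqrt(1.0 - rho**2) * eps
    i1 = gain * np.abs(e1) ** 2 + noise_floor * np.abs(rng.standard_normal(mc_samples))
    i2 = gain * np.abs(e2) ** 2 + noise_floor * np.abs(rng.standard_normal(mc_samples))
    d = np.abs(i1 - i2)
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(mc_samples))
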