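"""Randomized digital training volumes and deterministic layout twins.

The training-volume sampler draws scenes that emulate the in-silico
training distribution: two sets of tubes with per-set counts from a
discrete uniform U{3,9}, tube saturation from U(0,1), a background
chromophore volume fraction from U(0,3)% (background saturation also
U(0,1)), and a tube radius of 0.4 mm.  Tubes are circles in the imaging
plane (the physical tubes run perpendicular to it); the scene is a
single elevation slice, which contains all labels and the full
spectral-coloring structure at desk scale.

Deterministic "digital twin" layouts mirror the physical phantom sets:

* layout A — five single tubes (validation-style geometry),
* layout B — five four-tube arrays, two shallow / two deep tubes each,
* layout C — layout-B geometry with the imaging plane rotated by 90
  degrees, i.e. tubes oriented along the plane (longitudinal scans);
  one scene holds the in-plane shallow/deep tube pair of one array.

Coordinates: x is lateral, z is depth from the illuminated surface
(increasing downward); voxel values refer to voxel centers; 0-based
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import (
    ChromophoreMixture,
    ScatteringModelParams,
    WavelengthGrid,
    bundled_endmembers,
    mixture_mu_a,
    reduced_scattering,
    water_mu_a,
)

__all__ = [
    "TubeSpec",
    "SamplerConfig",
    "VoxelPhantom",
    "sample_training_volume",
    "build_layout",
    "rasterize_optics",
]

#: Inner radius (mm) of the polythene tubing used in the layout twins
#: (0.58 mm inner diameter).
LAYOUT_TUBE_RADIUS_MM = 0.29

_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class TubeSpec:
    """One tube in the imaging plane.

    ``orientation='transverse'`` rasterizes as a disk of the given
    radius; ``'longitudinal'`` as an in-plane capsule of half-length
    ``half_length_mm`` at the tube depth.
    """

    center: tuple[float, float]  # (x, z) in mm
    radius: float  # mm
    saturation: float
    orientation: str = "transverse"
    half_length_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("tube saturation must be in [0, 1]")
        if self.orientation not in ("transverse", "longitudinal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration of the randomized training-volume sampler."""

    n_sets: int = 2
    tubes_per_set: tuple[int, int] = (3, 9)
    saturation_bounds: tuple[float, float] = (0.0, 1.0)
    background_vf_bounds: tuple[float, float] = (0.0, 0.03)
    background_saturation_bounds: tuple[float, float] = (0.0, 1.0)
    tube_radius_mm: float = 0.4
    extent_mm: tuple[float, float] = (40.0, 30.0)  # (lateral, depth)
    depth_bounds_mm: tuple[float, float] = (2.0, 20.0)
    lateral_bounds_mm: tuple[float, float] | None = None  # None: full extent
    pitch_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        for name in ("tubes_per_set", "saturation_bounds", "background_vf_bounds",
                     "background_saturation_bounds", "depth_bounds_mm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds must be ordered")
        if self.tube_radius_mm <= 0 or self.pitch_mm <= 0:
            raise ValueError("tube_radius_mm and pitch_mm must be positive")
        if min(self.extent_mm) <= 0:
            raise ValueError("extent must be positive")


@dataclass
class VoxelPhantom:
    """Voxelized optical scene: per-wavelength mu_a / mu_s' maps (1/cm),
    a tube label map (0 = background), and per-tube ground truth."""

    grid: WavelengthGrid
    pitch_mm: float
    extent_mm: tuple[float, float]
    mu_a: np.ndarray  # (n_wavelengths, nz, nx)
    mu_s_prime: np.ndarray  # (n_wavelengths, nz, nx)
    labels: np.ndarray  # (nz, nx) int32, 0 = background, k = tube id
    tube_saturations: np.ndarray  # (n_tubes,)
    background: ChromophoreMixture
    tubes: list[TubeSpec] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_tubes(self) -> int:
        return len(self.tube_saturations)

    def validate(self) -> None:
        if np.any(self.mu_a < 0) or np.any(self.mu_s_prime < 0):
            raise ValueError("optical maps must be nonnegative")
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        # tube ids are assigned contiguously 1..n_tubes; at coarse pitch a
        # tube may cover no voxel center, so the map may omit some ids
        if ids.size and (ids.min() < 1 or ids.max() > self.n_tubes):
            raise ValueError("label map references unknown tube ids")


def _grid_centers(extent: float, pitch: float) -> np.ndarray:
    n = int(round(extent / pitch))
    return (np.arange(n) + 0.5) * pitch


def _rasterize_labels(tubes: Sequence[TubeSpec], extent_mm, pitch_mm) -> np.ndarray:
    xs = _grid_centers(extent_mm[0], pitch_mm)
    zs = _grid_centers(extent_mm[1], pitch_mm)
    xx, zz = np.meshgrid(xs, zs)
    labels = np.zeros((zs.size, xs.size), dtype=np.int32)
    for k, tube in enumerate(tubes, start=1):
        x0, z0 = tube.center
        if tube.orientation == "transverse":
            mask = (xx - x0) ** 2 + (zz - z0) ** 2 <= tube.radius ** 2
        else:
            # capsule: distance to the horizontal axis segment
            dx = np.clip(np.abs(xx - x0) - tube.half_length_mm, 0.0, None)
            mask = dx ** 2 + (zz - z0) ** 2 <= tube.radius ** 2
        if labels[mask].any():
            raise ValueError(f"tube {k} overlaps an earlier tube after rasterization")
        labels[mask] = k
    return labels


def rasterize_optics(
    tubes: Sequence[TubeSpec],
    background: ChromophoreMixture,
    grid: WavelengthGrid | None = None,
    scattering: ScatteringModelParams | None = None,
    extent_mm: tuple[float, float] = (40.0, 30.0),
    pitch_mm: float = 0.3,
    meta: dict | None = None,
) -> VoxelPhantom:
    """Rasterize tube geometry plus a background mixture to optical maps.

    Background absorption is water plus the background mixture; tube
    absorption is the pure mixture at 100% volume fraction (whole-blood
    equivalent).  Background reduced scattering follows the power-law
    tissue model; the tube solutions carry no scattering agent, so tube
    mu_s' = 0.
    """
    grid = grid or WavelengthGrid()
    scattering = scattering or ScatteringModelParams()
    for tube in tubes:
        x0, z0 = tube.center
        if not (0 < x0 < extent_mm[0] and 0 < z0 < extent_mm[1]):
            raise ValueError(f"tube center {tube.center} outside volume {extent_mm}")

    labels = _rasterize_labels(tubes, extent_mm, pitch_mm)
    nz, nx = labels.shape
    n_wl = len(grid)

    endmembers = bundled_endmembers(background.family, grid)
    bg_mu_a = water_mu_a(grid) + mixture_mu_a(background, grid, endmembers)
    bg_mu_sp = reduced_scattering(scattering, grid)

    mu_a = np.broadcast_to(bg_mu_a[:, None, None], (n_wl, nz, nx)).copy()
    mu_sp = np.broadcast_to(bg_mu_sp[:, None, None], (n_wl, nz, nx)).copy()

    sats = np.array([t.saturation for t in tubes], dtype=float)
    if tubes:
        e_oxy, e_deoxy = (e.asarray() for e in endmembers)
        tube_mask = labels > 0
        sat_map = sats[labels[tube_mask] - 1]
        # whole-blood-equivalent volume fraction inside the tubing (100%)
        mu_a[:, tube_mask] = (
            np.outer(e_oxy, sat_map) + np.outer(e_deoxy, 1.0 - sat_map)
        )
        mu_sp[:, tube_mask] = 0.0

    phantom = VoxelPhantom(
        grid=grid,
        pitch_mm=pitch_mm,
        extent_mm=tuple(extent_mm),
        mu_a=mu_a,
        mu_s_prime=mu_sp,
        labels=labels,
        tube_saturations=sats,
        background=background,
        tubes=list(tubes),
        meta=dict(meta or {}),
    )
    phantom.validate()
    return phantom


def sample_training_volume(
    cfg: SamplerConfig,
    rng: np.random.Generator | int,
    family: str = "sulfate",
    grid: WavelengthGrid | None = None,
    scattering: ScatteringModelParams | None = None,
) -> VoxelPhantom:
    """Draw one randomized training volume (reproducible given the seed).

    Tubes are placed uniformly in the lateral/depth placement window
    with at least one tube diameter of clearance from the volume
    boundaries; tubes that would intersect an already placed tube are
    rejection-resampled up to a bounded retry count.
    """
    rng = np.random.default_rng(rng)
    r = cfg.tube_radius_mm
    margin = 2.0 * r  # one tube diameter from the boundary
    if cfg.lateral_bounds_mm is not None:
        x_lo = max(cfg.lateral_bounds_mm[0], margin)
        x_hi = min(cfg.lateral_bounds_mm[1], cfg.extent_mm[0] - margin)
    else:
        x_lo, x_hi = margin, cfg.extent_mm[0] - margin
    z_lo = max(cfg.depth_bounds_mm[0], margin)
    z_hi = min(cfg.depth_bounds_mm[1], cfg.extent_mm[1] - margin)
    if x_lo >= x_hi or z_lo >= z_hi:
        raise ValueError("volume too small for the configured tube radius")

    counts = [int(rng.integers(cfg.tubes_per_set[0], cfg.tubes_per_set[1] + 1))
              for _ in range(cfg.n_sets)]
    centers: list[tuple[float, float]] = []
    tubes: list[TubeSpec] = []
    for n in counts:
        for _ in range(n):
            for _attempt in range(_PLACEMENT_RETRIES):
                x = rng.uniform(x_lo, x_hi)
                z = rng.uniform(z_lo, z_hi)
                if all((x - cx) ** 2 + (z - cz) ** 2 >= (2 * r) ** 2
                       for cx, cz in centers):
                    break
            else:
                raise ValueError(
                    f"could not place tube after {_PLACEMENT_RETRIES} retries; "
                    "volume too crowded")
            centers.append((x, z))
            sat = rng.uniform(*cfg.saturation_bounds)
            tubes.append(TubeSpec(center=(x, z), radius=r, saturation=sat))

    background = ChromophoreMixture(
        saturation=rng.uniform(*cfg.background_saturation_bounds),
        volume_fraction=rng.uniform(*cfg.background_vf_bounds),
        family=family,
    )
    return rasterize_optics(
        tubes, background, grid=grid, scattering=scattering,
        extent_mm=cfg.extent_mm, pitch_mm=cfg.pitch_mm,
        meta={"sampler": "training_volume", "tube_set_counts": counts},
    )


# In-plane layout coordinates (mm) of the digital twins.  The physical
# layouts place five lateral positions 8 mm apart; layout B stacks a
# shallow pair at 3 mm and a deep pair at 8 mm depth per position.
_ARRAY_OFFSETS = (-16.0, -8.0, 0.0, 8.0, 16.0)
_PAIR_HALF_SPACING = 0.75
_SHALLOW_DEPTH = 3.0
_DEEP_DEPTH = 8.0
_SINGLE_TUBE_DEPTH = 5.0
_LONGITUDINAL_HALF_LENGTH = 7.5


def build_layout(
    layout: str,
    tube_saturations: Sequence[float],
    background: ChromophoreMixture,
    grid: WavelengthGrid | None = None,
    scattering: ScatteringModelParams | None = None,
    extent_mm: tuple[float, float] = (40.0, 30.0),
    pitch_mm: float = 0.3,
    tube_radius_mm: float = LAYOUT_TUBE_RADIUS_MM,
) -> VoxelPhantom:
    """Deterministic digital twin of one phantom layout (A, B, or C).

    Expected saturation counts: A -> 5 (one per single tube), B -> 20
    (five arrays x four tubes, ordered array-major as shallow-left,
    shallow-right, deep-left, deep-right), C -> 2 (the in-plane shallow
    and deep longitudinal tubes of one array).
    """
    cx = extent_mm[0] / 2.0
    sats = list(tube_saturations)
    tubes: list[TubeSpec] = []
    if layout == "A":
        if len(sats) != 5:
            raise ValueError("layout A needs 5 tube saturations")
        for off, s in zip(_ARRAY_OFFSETS, sats):
            tubes.append(TubeSpec((cx + off, _SINGLE_TUBE_DEPTH), tube_radius_mm, s))
    elif layout == "B":
        if len(sats) != 20:
            raise ValueError("layout B needs 20 tube saturations")
        it = iter(sats)
        for off in _ARRAY_OFFSETS:
            for depth in (_SHALLOW_DEPTH, _DEEP_DEPTH):
                for side in (-_PAIR_HALF_SPACING, _PAIR_HALF_SPACING):
                    tubes.append(
                        TubeSpec((cx + off + side, depth), tube_radius_mm, next(it)))
    elif layout == "C":
        if len(sats) != 2:
            raise ValueError("layout C needs 2 tube saturations (shallow, deep)")
        for depth, s in zip((_SHALLOW_DEPTH, _DEEP_DEPTH), sats):
            tubes.append(TubeSpec((cx, depth), tube_radius_mm, s,
                                  orientation="longitudinal",
                                  half_length_mm=_LONGITUDINAL_HALF_LENGTH))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return rasterize_optics(
        tubes, background, grid=grid, scattering=scattering,
        extent_mm=extent_mm, pitch_mm=pitch_mm,
        meta={"layout": layout},
    )
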