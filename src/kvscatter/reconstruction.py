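"""Algebraic reconstruction (Kaczmarz / ART) of fan-beam projections.

Line integrals are formed as -ln(pixel / i0) and solved against a system
matrix built with the same exact Siddon tracer used by the forward
projector; the reconstructed quantity is the effective linear attenuation
coefficient (1/cm). An affine rule anchored on two reference materials
(air and water by default) converts attenuation to CBCT numbers, the
scanner-scale analogue of Hounsfield units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .projector import ProjectionStack
from .raytrace import ray_row


@dataclass
class ARTConfig:
    """Kaczmarz sweep settings."""

    n_sweeps: int = 10
    relaxation: float = 0.8
    ray_order: str = "sequential"  # or 'randomized'
    seed: int | None = None
    nonnegativity: bool = True

    def __post_init__(self):
        if not (0 < self.relaxation < 2):
            raise ValueError("relaxation must lie in (0, 2)")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.ray_order not in ("sequential", "randomized"):
            raise ValueError("ray_order must be 'sequential' or 'randomized'")
        if self.ray_order == "randomized" and self.seed is None:
            raise ValueError("randomized ray order requires a seed")


@dataclass
class CBCTNumberRule:
    """Affine map from attenuation (1/cm) to CBCT number."""

    slope: float
    offset: float

    @classmethod
    def from_anchors(cls, mu_air: float, mu_water: float,
                     value_air: float = -1000.0,
                     value_water: float = 0.0) -> "CBCTNumberRule":
        if abs(mu_water - mu_air) < 1e-12:
            raise ValueError("degenerate anchors: air and water attenuation equal")
        slope = (value_water - value_air) / (mu_water - mu_air)
        return cls(slope=slope, offset=value_water - slope * mu_water)

    def apply(self, mu):
        return self.slope * np.asarray(mu, float) + self.offset


@dataclass
class ReconVolume:
    """Reconstructed attenuation grid plus its CBCT-number convention."""

    mu_grid: np.ndarray  # (n, n), 1/cm
    voxel_size: tuple[float, float]  # mm
    origin: tuple[float, float]  # mm, grid corner
    cbct_number_rule: CBCTNumberRule | None = None

    @property
    def shape(self):
        return self.mu_grid.shape


def build_system(stack: ProjectionStack, shape, voxel_size, origin):
    """System rows (flat voxel indices, lengths in cm) and the line
    integrals -ln(I/i0); nonpositive-fluence pixels are excluded."""
    geometry = stack.geometry
    rows = []
    n_excluded = 0
    for proj in stack:
        src = geometry.source_position(proj.angle_deg)
        pix = geometry.pixel_positions(proj.angle_deg)
        for k in range(geometry.detector_size):
            val, i0 = proj.pixel_fluence[k], proj.i0[k]
            if val <= 0 or i0 <= 0:
                n_excluded += 1
                continue
            idx, lengths = ray_row(src, pix[k], origin, voxel_size, shape)
            if idx.size == 0:
                continue
            rows.append((idx, lengths / 10.0, float(-np.log(val / i0))))
    if n_excluded:
        warnings.warn(f"{n_excluded} nonpositive fluence pixels excluded from ART")
    return rows


def kaczmarz(rows, shape, config: ARTConfig) -> np.ndarray:
    """Relaxed Kaczmarz sweeps over the ray equations."""
    x = np.zeros(shape[0] * shape[1])
    norms = np.array([float(l @ l) for _, l, _ in rows])
    order = np.arange(len(rows))
    rng = (np.random.Generator(np.random.PCG64(config.seed))
           if config.ray_order == "randomized" else None)
    lam = config.relaxation
    for _ in range(config.n_sweeps):
        if rng is not None:
            rng.shuffle(order)
        for i in order:
            idx, lengths, p = rows[i]
            if norms[i] <= 0:
                continue
            r = p - x[idx] @ lengths
            x[idx] += lam * r / norms[i] * lengths
        if config.nonnegativity:
            np.maximum(x, 0.0, out=x)
    return x.reshape(shape)


def reconstruct_art(
    stack: ProjectionStack,
    config: ARTConfig | None = None,
    n_voxels: int = 64,
    fov_mm: float | None = None,
    cbct_rule: CBCTNumberRule | None = None,
) -> ReconVolume:
    """Reconstruct effective attenuation on a centered square grid.

    ``fov_mm`` defaults to the detector extent scaled back to the
    isocenter.
    """
    config = config or ARTConfig()
    geometry = stack.geometry
    if fov_mm is None:
        mag = geometry.source_detector_distance / geometry.source_axis_distance
        fov_mm = geometry.detector_size * geometry.detector_pixel_pitch / mag
    voxel = fov_mm / n_voxels
    shape = (n_voxels, n_voxels)
    origin = (-fov_mm / 2.0, -fov_mm / 2.0)
    rows = build_system(stack, shape, (voxel, voxel), origin)
    mu = kaczmarz(rows, shape, config)
    return ReconVolume(mu, (voxel, voxel), origin, cbct_rule)


def art_residual(rows, mu_grid: np.ndarray) -> float:
    """L2 residual ||A x - p|| of a reconstruction against its system."""
    x = mu_grid.ravel()
    return float(np.sqrt(sum((p - x[idx] @ lengths) ** 2
                             for idx, lengths, p in rows)))


def to_cbct_number(volume: ReconVolume,
                   rule: CBCTNumberRule | None = None) -> np.ndarray:
    """CBCT-number grid of a reconstruction under an affine rule."""
    rule = rule or volume.cbct_number_rule
    if rule is None:
        raise ValueError("no CBCT-number rule configured")
    return rule.apply(volume.mu_grid)
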