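"""Primary-fluence forward projection for a rotating fan-beam system.

Models a point source and a flat 1-D detector rotating about the
isocenter. Primary fluence follows Beer–Lambert attenuation along exact
Siddon ray integrals, mono- or polychromatic, with optional bowtie-filter
pre-attenuation per detector column and an antiscatter-grid transform.

Geometry convention: at gantry angle 0 the source sits at (+SAD, 0) in
world (y, x) mm, the detector line at y = -ADD with the pixel coordinate u
increasing with +x; positive angles rotate the gantry counterclockwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .phantoms import Material, VoxelPhantom, load_material
from .raytrace import material_path_lengths


@dataclass
class Spectrum:
    """Discrete photon spectrum: fluence weights per energy bin (keV)."""

    energies_kev: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.energies_kev = np.atleast_1d(np.asarray(self.energies_kev, float))
        w = np.atleast_1d(np.asarray(self.weights, float))
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("spectrum weights must be nonnegative with positive sum")
        self.weights = w / w.sum()
        if self.energies_kev.shape != self.weights.shape:
            raise ValueError("energies and weights must align")

    @classmethod
    def mono(cls, energy_kev: float) -> "Spectrum":
        return cls(np.array([float(energy_kev)]), np.array([1.0]))

    @classmethod
    def kvp120(cls) -> "Spectrum":
        """Packaged coarse 120 kVp-like spectrum for polychromatic tests."""
        with resources.files("kvscatter._data").joinpath("spectrum_120kvp.csv").open() as fh:
            tab = pd.read_csv(fh)
        return cls(tab["energy_kev"].to_numpy(), tab["weight"].to_numpy())

    @property
    def is_mono(self) -> bool:
        return self.energies_kev.size == 1

    def mean_energy(self) -> float:
        return float(np.sum(self.energies_kev * self.weights))


def detector_response(energies_kev, mode: str = "energy") -> np.ndarray:
    """Detector weighting per photon: ``energy``-integrating (weight = E,
    normalized to 1 at 100 keV for convenient magnitudes) or ``counts``."""
    e = np.atleast_1d(np.asarray(energies_kev, float))
    if mode == "energy":
        return e / 100.0
    if mode == "counts":
        return np.ones_like(e)
    raise ValueError("detector response must be 'energy' or 'counts'")


@dataclass
class ScanGeometry:
    """Rotating fan-beam acquisition geometry (distances in mm)."""

    source_axis_distance: float = 1000.0
    axis_detector_distance: float = 500.0
    detector_pixel_pitch: float = 2.4
    detector_size: int = 128
    angles_deg: np.ndarray = field(default_factory=lambda: np.arange(0.0, 360.0, 7.5))
    beam: str = "fan"

    def __post_init__(self):
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, float))
        if self.source_axis_distance <= 0 or self.axis_detector_distance <= 0:
            raise ValueError("distances must be positive")
        if self.angles_deg.size < 1:
            raise ValueError("at least one gantry angle required")
        if self.detector_size < 1 or self.detector_pixel_pitch <= 0:
            raise ValueError("detector must have >=1 pixel of positive pitch")

    @property
    def source_detector_distance(self) -> float:
        return self.source_axis_distance + self.axis_detector_distance

    @staticmethod
    def _rot(angle_deg: float) -> np.ndarray:
        a = np.deg2rad(angle_deg)
        # rotation acting on (y, x) vectors
        return np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])

    def source_position(self, angle_deg: float) -> np.ndarray:
        return self._rot(angle_deg) @ np.array([self.source_axis_distance, 0.0])

    def detector_center(self, angle_deg: float) -> np.ndarray:
        return self._rot(angle_deg) @ np.array([-self.axis_detector_distance, 0.0])

    def detector_u_vec(self, angle_deg: float) -> np.ndarray:
        return self._rot(angle_deg) @ np.array([0.0, 1.0])

    def detector_normal(self, angle_deg: float) -> np.ndarray:
        """Unit normal of the detector line, pointing back at the source."""
        return self._rot(angle_deg) @ np.array([1.0, 0.0])

    def pixel_u(self) -> np.ndarray:
        n = self.detector_size
        return (np.arange(n) - (n - 1) / 2.0) * self.detector_pixel_pitch

    def pixel_positions(self, angle_deg: float) -> np.ndarray:
        """World (y, x) centers of all detector pixels, shape (n, 2)."""
        return (self.detector_center(angle_deg)[None, :]
                + self.pixel_u()[:, None] * self.detector_u_vec(angle_deg)[None, :])

    def pixel_angular_widths(self, points, angle_deg: float) -> np.ndarray:
        """In-plane angle (rad) each pixel subtends at the given point(s).

        ``points`` may be a single (y, x) or an array (m, 2); returns
        shape (n,) or (m, n). Uses the flat-detector obliquity factor
        pitch * cos(beta) / r.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        pix = self.pixel_positions(angle_deg)  # (n, 2)
        d = pix[None, :, :] - pts[:, None, :]  # (m, n, 2)
        r = np.linalg.norm(d, axis=-1)
        cosb = np.abs(d @ self.detector_normal(angle_deg)) / np.maximum(r, 1e-12)
        w = self.detector_pixel_pitch * cosb / np.maximum(r, 1e-12)
        return w[0] if np.asarray(points).ndim == 1 else w


@dataclass
class BowtieFilter:
    """Beam-shaping filter: mm of filter material per detector column."""

    thickness_profile_mm: np.ndarray
    material: Material

    def __post_init__(self):
        self.thickness_profile_mm = np.asarray(self.thickness_profile_mm, float)
        if np.any(self.thickness_profile_mm < 0):
            raise ValueError("bowtie thickness must be >= 0")

    @classmethod
    def parabolic(cls, n_columns: int, max_thickness_mm: float = 15.0,
                  material: Material | None = None) -> "BowtieFilter":
        """Thin at the center, ``max_thickness_mm`` at the fan edges."""
        u = np.linspace(-1.0, 1.0, n_columns)
        return cls(max_thickness_mm * u**2, material or load_material("aluminum"))

    def transmission(self, energies_kev) -> np.ndarray:
        """Fractional transmission, shape (n_columns, n_energies)."""
        mu = np.atleast_1d(self.material.mu(np.atleast_1d(energies_kev)))
        return np.exp(-self.thickness_profile_mm[:, None] / 10.0 * mu[None, :])


@dataclass
class AntiscatterGrid:
    """Grid as two bulk transmission fractions (primary and scatter)."""

    primary_transmission: float = 0.7
    scatter_transmission: float = 0.1
    grid_ratio: str = "10:1"

    def __post_init__(self):
        tp, ts = self.primary_transmission, self.scatter_transmission
        if not (0 < tp <= 1) or not (0 < ts <= 1):
            raise ValueError("grid transmissions must lie in (0, 1]")
        if ts > tp:
            raise ValueError("scatter transmission cannot exceed primary transmission")


@dataclass
class Projection:
    """One detector reading: per-pixel fluence plus its open-field i0."""

    pixel_fluence: np.ndarray
    angle_deg: float
    i0: np.ndarray

    def __post_init__(self):
        self.pixel_fluence = np.asarray(self.pixel_fluence, float)
        self.i0 = np.broadcast_to(np.asarray(self.i0, float),
                                  self.pixel_fluence.shape).copy()
        if np.any(self.pixel_fluence < 0):
            raise ValueError("pixel fluence must be >= 0")


@dataclass
class ProjectionStack:
    """Ordered projections with the geometry and spectrum that formed them."""

    projections: list[Projection]
    geometry: ScanGeometry
    spectrum: Spectrum
    detector_response_mode: str = "energy"
    truncated: bool = False

    def __post_init__(self):
        if len(self.projections) != self.geometry.angles_deg.size:
            raise ValueError("one projection per geometry angle required")
        shapes = {p.pixel_fluence.shape for p in self.projections}
        if len(shapes) > 1:
            raise ValueError("inconsistent detector shapes in stack")

    def __len__(self):
        return len(self.projections)

    def __iter__(self):
        return iter(self.projections)

    def __getitem__(self, i) -> Projection:
        return self.projections[i]

    def as_array(self) -> np.ndarray:
        return np.stack([p.pixel_fluence for p in self.projections])

    def i0_array(self) -> np.ndarray:
        return np.stack([p.i0 for p in self.projections])

    def with_fluence(self, arr: np.ndarray, i0: np.ndarray | None = None) -> "ProjectionStack":
        """Same metadata, new pixel data (and optionally new i0)."""
        i0 = self.i0_array() if i0 is None else np.asarray(i0, float)
        projs = [Projection(np.maximum(arr[k], 0.0), p.angle_deg, i0[k])
                 for k, p in enumerate(self.projections)]
        return ProjectionStack(projs, self.geometry, self.spectrum,
                               self.detector_response_mode, self.truncated)


def open_field_counts(geometry: ScanGeometry, spectrum: Spectrum,
                      bowtie: BowtieFilter | None, i0_photons: float) -> np.ndarray:
    """Photon counts per (column, energy bin) reaching the detector with no
    object in the beam."""
    counts = i0_photons * spectrum.weights[None, :] * np.ones((geometry.detector_size, 1))
    if bowtie is not None:
        if bowtie.thickness_profile_mm.size != geometry.detector_size:
            raise ValueError("bowtie profile length must match detector size")
        counts = counts * bowtie.transmission(spectrum.energies_kev)
    return counts


def forward_project_primary(
    phantom: VoxelPhantom,
    geometry: ScanGeometry,
    spectrum: Spectrum,
    bowtie: BowtieFilter | None = None,
    i0_photons: float = 1.0e5,
    response: str = "energy",
) -> ProjectionStack:
    """Scatter-free projections of a phantom: the ground-truth primary P.

    Each pixel reads sum_E N(col, E) * resp(E) * exp(-integral mu(E) dl)
    where N is the (bowtie-attenuated) open-field photon count per bin and
    the line integral runs source -> pixel through the phantom (Siddon).
    Rays through the first/last detector column that still intersect the
    object raise a truncation warning and set ``stack.truncated``.
    """
    energies = spectrum.energies_kev
    resp = detector_response(energies, response)
    counts = open_field_counts(geometry, spectrum, bowtie, i0_photons)  # (n, nE)
    i0 = counts @ resp
    mu_tab = phantom.mu_table(energies)  # (n_mat, nE)

    truncated = False
    projections = []
    for angle in geometry.angles_deg:
        src = geometry.source_position(angle)
        pix = geometry.pixel_positions(angle)
        vals = np.empty(geometry.detector_size)
        for k in range(geometry.detector_size):
            lengths_cm = material_path_lengths(phantom, src, pix[k]) / 10.0
            # object = anything that is not the background label 0
            if k in (0, geometry.detector_size - 1) and lengths_cm[1:].sum() > 1e-9:
                truncated = True
            trans = np.exp(-(lengths_cm @ mu_tab))
            vals[k] = np.sum(counts[k] * resp * trans)
        projections.append(Projection(vals, float(angle), i0))

    if truncated:
        warnings.warn("object extends past the detector fan: truncated rays "
                      "present at the detector edges", stacklevel=2)
    stack = ProjectionStack(projections, geometry, spectrum, response)
    stack.truncated = truncated
    return stack


def apply_poisson_noise(stack: ProjectionStack, rng_seed: int) -> ProjectionStack:
    """Quantum noise: Poisson-sample each pixel's photon count.

    Pixel values are converted to counts with the detector response at the
    spectrum mean energy, sampled, and converted back; reproducible for a
    fixed seed. With the energy-integrating response this is an effective
    (mean-energy) noise model.
    """
    resp = float(detector_response(stack.spectrum.mean_energy(),
                                   stack.detector_response_mode)[0])
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    counts = stack.as_array() / resp
    noisy = rng.poisson(np.maximum(counts, 0.0)).astype(float) * resp
    return stack.with_fluence(noisy)


def apply_grid(stack_primary: ProjectionStack, stack_scatter: ProjectionStack,
               grid: AntiscatterGrid) -> ProjectionStack:
    """Combine primary and scatter through an antiscatter grid:
    pixel = Tp * P + Ts * S. The open field scales by Tp."""
    p = stack_primary.as_array()
    s = stack_scatter.as_array()
    if p.shape != s.shape:
        raise ValueError("primary and scatter stacks must have matching shapes")
    out = grid.primary_transmission * p + grid.scatter_transmission * s
    return stack_primary.with_fluence(out, grid.primary_transmission * stack_primary.i0_array())


def beam_hardening_free_mu(spectrum: Spectrum, material: Material,
                           thickness_mm: float) -> float:
    """Effective attenuation -ln(T)/t (1/cm) of a slab of given thickness.

    For a polychromatic spectrum this decreases with thickness (beam
    hardening); at zero thickness it equals the fluence-weighted mean mu.
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be >= 0")
    mu = material.mu(spectrum.energies_kev)
    if thickness_mm == 0:
        return float(np.sum(spectrum.weights * mu))
    t_cm = thickness_mm / 10.0
    trans = np.sum(spectrum.weights * np.exp(-mu * t_cm))
    return float(-np.log(trans) / t_cm)
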