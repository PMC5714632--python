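"""Digital test phantoms for fan-beam CBCT simulation.

Provides tabulated materials (linear attenuation vs energy), labeled voxel
phantoms (insert cylinders in a water body, water cylinders, bolus slabs)
and circular ROI specifications, so that every downstream stage — forward
projection, scatter simulation, correction, reconstruction and metrics —
can be exercised without any physical acquisition.

Conventions: world coordinates in mm with the rotation isocenter at the
origin; grids are indexed (row, column) = (+y, +x); attenuation
coefficients are linear (1/cm) tabulated on a keV grid with linear
interpolation in energy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: electron density of water, electrons per cm^3
WATER_ELECTRON_DENSITY = 3.343e23

# physical density (g/cm^3) and electron density relative to water for the
# base materials whose mass attenuation coefficients ship with the package
_BASE_MATERIALS = {
    # name: (physical_density, electron_density_rel_water)
    "air": (0.0012, 0.0011),
    "water": (1.000, 1.000),
    "lung": (0.260, 0.260),
    "adipose": (0.950, 0.951),
    "bone": (1.920, 1.780),
    "aluminum": (2.699, 2.340),
}


@dataclass(frozen=True)
class Material:
    """A scan material: density plus tabulated linear attenuation.

    ``mu_energies_kev`` / ``mu_values_per_cm`` form a lookup table of the
    total linear attenuation coefficient (1/cm); queries interpolate
    linearly in energy and clamp at the table ends.
    """

    name: str
    physical_density: float  # g/cm^3
    electron_density_rel_water: float
    mu_energies_kev: np.ndarray
    mu_values_per_cm: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.mu_energies_kev, dtype=float)
        m = np.asarray(self.mu_values_per_cm, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("attenuation table must be two matching 1-D arrays")
        if np.any(m < 0):
            raise ValueError(f"negative attenuation in table for {self.name!r}")
        if self.physical_density < 0:
            raise ValueError("physical_density must be >= 0")
        object.__setattr__(self, "mu_energies_kev", e)
        object.__setattr__(self, "mu_values_per_cm", m)

    def mu(self, energy_kev):
        """Linear attenuation coefficient (1/cm) at the given energy (keV)."""
        return np.interp(energy_kev, self.mu_energies_kev, self.mu_values_per_cm)

    @property
    def electron_density(self) -> float:
        """Absolute electron density, electrons per cm^3."""
        return self.electron_density_rel_water * WATER_ELECTRON_DENSITY


def _mass_attenuation_table() -> pd.DataFrame:
    with resources.files("kvscatter._data").joinpath("mass_attenuation.csv").open() as fh:
        return pd.read_csv(fh)


def load_material(name: str) -> Material:
    """Look up one of the packaged base materials by name."""
    if name not in _BASE_MATERIALS:
        raise KeyError(f"unknown material {name!r}; known: {sorted(_BASE_MATERIALS)}")
    tab = _mass_attenuation_table()
    rho, ed = _BASE_MATERIALS[name]
    return Material(
        name=name,
        physical_density=rho,
        electron_density_rel_water=ed,
        mu_energies_kev=tab["energy_kev"].to_numpy(),
        mu_values_per_cm=tab[name].to_numpy() * rho,
    )


def water_equivalent_material(name: str, electron_density_rel_water: float) -> Material:
    """Build a water-like material with a prescribed relative electron density.

    Tissue-substitute inserts are modeled as water whose attenuation scales
    with relative electron density — adequate in the Compton-dominated kV
    range this harness targets.
    """
    if electron_density_rel_water <= 0:
        raise ValueError("electron density must be positive")
    water = load_material("water")
    return Material(
        name=name,
        physical_density=electron_density_rel_water,
        electron_density_rel_water=electron_density_rel_water,
        mu_energies_kev=water.mu_energies_kev,
        mu_values_per_cm=water.mu_values_per_cm * electron_density_rel_water,
    )


def tissue_insert_table() -> pd.DataFrame:
    """Packaged table of 16 tissue-characterization inserts.

    Columns: insert name, relative electron density, and gray-value ROI
    readings (mean and std) from bolused/non-bolused scans before and after
    scatter-correction processing.
    """
    with resources.files("kvscatter._data").joinpath("gammex_table1.csv").open() as fh:
        return pd.read_csv(fh)


def tissue_insert_materials() -> list[Material]:
    """The 16 packaged insert materials as water-equivalent ``Material``s."""
    tab = tissue_insert_table()
    return [
        water_equivalent_material(row["insert"], float(row["electron_density"]))
        for _, row in tab.iterrows()
    ]


@dataclass
class ROISpec:
    """Circular region of interest, in world mm."""

    label: str
    center: tuple[float, float]
    radius: float
    slice_index: int | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass
class VoxelPhantom:
    """Labeled 2-D voxel grid plus an ordered material table.

    ``label_grid[j, i]`` indexes ``materials``; the voxel center of (j, i)
    sits at ``origin + (i + 0.5, j + 0.5) * voxel_size`` in world mm.
    """

    label_grid: np.ndarray  # int, shape (ny, nx)
    voxel_size: tuple[float, float]  # mm (dy, dx)
    origin: tuple[float, float]  # mm, world position of grid corner (y0, x0)
    materials: list[Material]
    rois: list[ROISpec] = field(default_factory=list)

    def __post_init__(self):
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.size == 0:
            raise ValueError("label grid must be non-empty")
        if self.label_grid.min() < 0 or self.label_grid.max() >= len(self.materials):
            raise ValueError("label grid indexes outside the material table")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size), float(self.voxel_size))
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centers, returned as (y, x) grids."""
        ny, nx = self.shape
        dy, dx = self.voxel_size
        y = self.origin[0] + (np.arange(ny) + 0.5) * dy
        x = self.origin[1] + (np.arange(nx) + 0.5) * dx
        return np.meshgrid(y, x, indexing="ij")

    def mu_map(self, energy_kev: float) -> np.ndarray:
        """Per-voxel linear attenuation (1/cm) at the given energy."""
        mus = np.array([m.mu(energy_kev) for m in self.materials])
        return mus[self.label_grid]

    def electron_density_map(self) -> np.ndarray:
        """Per-voxel absolute electron density (e/cm^3)."""
        ne = np.array([m.electron_density for m in self.materials])
        return ne[self.label_grid]

    def mu_table(self, energies_kev) -> np.ndarray:
        """Attenuation (1/cm) for every material at the given energies.

        Shape (n_materials, n_energies); used by ray tracers that
        accumulate per-material path lengths.
        """
        energies_kev = np.atleast_1d(energies_kev)
        return np.array([[m.mu(e) for e in energies_kev] for m in self.materials])

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            label_grid=self.label_grid.copy(),
            voxel_size=self.voxel_size,
            origin=self.origin,
            materials=list(self.materials),
            rois=copy.deepcopy(self.rois),
        )


def _centered_origin(grid_shape, voxel_size) -> tuple[float, float]:
    ny, nx = grid_shape
    dy, dx = voxel_size
    return (-ny * dy / 2.0, -nx * dx / 2.0)


def make_cylinder_phantom(
    radius_mm: float,
    grid_shape: tuple[int, int] = (96, 96),
    voxel_size_mm: float | tuple[float, float] = 2.0,
    material: Material | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> VoxelPhantom:
    """Homogeneous cylinder (disk in-slice) in air, centered by default."""
    material = material or load_material("water")
    return make_insert_phantom(radius_mm, [], grid_shape, voxel_size_mm,
                               body_material=material, body_center=center)


def make_insert_phantom(
    body_radius_mm: float,
    inserts: list[tuple[Material, tuple[float, float], float]],
    grid_shape: tuple[int, int] = (96, 96),
    voxel_size_mm: float | tuple[float, float] = 2.0,
    body_material: Material | None = None,
    background_material: Material | None = None,
    body_center: tuple[float, float] = (0.0, 0.0),
    roi_radius_mm: float | None = None,
) -> VoxelPhantom:
    """Cylindrical body with cylindrical inserts, the classic QA layout.

    Parameters
    ----------
    body_radius_mm : outer radius of the (water by default) body.
    inserts : list of ``(material, (y, x) center mm, radius mm)``; inserts
        must lie fully inside the body and must not overlap each other.
    roi_radius_mm : radius of the ROI attached per insert (default 2/3 of
        the insert radius).

    Returns a phantom whose ``rois`` list contains one ROI per insert.
    """
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm), float(voxel_size_mm))
    body_material = body_material or load_material("water")
    background_material = background_material or load_material("air")
    if body_radius_mm <= 0:
        raise ValueError("body radius must be positive")

    for (m1, c1, r1), (m2, c2, r2) in _pairs(inserts):
        d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
        if d < r1 + r2:
            raise ValueError(
                f"inserts {m1.name!r} and {m2.name!r} overlap "
                f"(center distance {d:.1f} mm < {r1 + r2:.1f} mm)"
            )
    for m, c, r in inserts:
        if np.hypot(c[0] - body_center[0], c[1] - body_center[1]) + r > body_radius_mm:
            raise ValueError(f"insert {m.name!r} extends outside the body")

    origin = _centered_origin(grid_shape, voxel_size_mm)
    materials = [background_material, body_material]
    grid = np.zeros(grid_shape, dtype=np.int32)
    yy, xx = np.meshgrid(
        origin[0] + (np.arange(grid_shape[0]) + 0.5) * voxel_size_mm[0],
        origin[1] + (np.arange(grid_shape[1]) + 0.5) * voxel_size_mm[1],
        indexing="ij",
    )
    grid[(yy - body_center[0]) ** 2 + (xx - body_center[1]) ** 2 <= body_radius_mm**2] = 1

    rois = []
    for m, c, r in inserts:
        materials.append(m)
        label = len(materials) - 1
        grid[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r**2] = label
        rois.append(ROISpec(label=m.name, center=tuple(c),
                            radius=roi_radius_mm or (2.0 * r / 3.0)))

    return VoxelPhantom(grid, voxel_size_mm, origin, materials, rois)


def _pairs(seq):
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            yield seq[i], seq[j]


_SIDE_AXES = {"top": (0, +1), "bottom": (0, -1), "right": (1, +1), "left": (1, -1)}


def add_bolus(
    phantom: VoxelPhantom,
    thickness_mm: float,
    side: str = "top",
    material: Material | None = None,
) -> VoxelPhantom:
    """Append a water-equivalent slab of the stated thickness to one side.

    The slab spans the lateral extent of the phantom body (non-background
    voxels) and stacks on top of any bolus already present, so applying
    two slabs sequentially matches one slab of the summed thickness.
    Thickness 0 returns an unchanged copy.
    """
    if thickness_mm < 0:
        raise ValueError("bolus thickness must be >= 0")
    if side not in _SIDE_AXES:
        raise ValueError(f"side must be one of {sorted(_SIDE_AXES)}")
    out = phantom.copy()
    axis, direction = _SIDE_AXES[side]
    n_layers = int(round(thickness_mm / out.voxel_size[axis]))
    if n_layers == 0:
        return out

    material = material or load_material("water")
    names = [m.name for m in out.materials]
    if "bolus" in names:
        bolus_label = names.index("bolus")
    else:
        bolus = Material("bolus", material.physical_density,
                         material.electron_density_rel_water,
                         material.mu_energies_kev, material.mu_values_per_cm)
        out.materials.append(bolus)
        bolus_label = len(out.materials) - 1

    grid = out.label_grid
    occupied = grid != 0  # anything non-background, incl. existing bolus
    if not occupied.any():
        raise ValueError("phantom has no body to attach a bolus to")
    # work with the slab axis as axis 0
    g = grid if axis == 0 else grid.T
    occ = occupied if axis == 0 else occupied.T
    lateral = occ.any(axis=0)  # columns (along slab axis) that contain body
    edge = np.where(occ[:, lateral].any(axis=1))[0]
    j0 = edge[-1] + 1 if direction > 0 else edge[0] - n_layers
    if j0 < 0 or j0 + n_layers > g.shape[0]:
        raise ValueError(
            "bolus slab exceeds the grid extent; enlarge the grid "
            f"(needs rows {j0}..{j0 + n_layers - 1} on a {g.shape[0]}-row axis)"
        )
    band = g[j0:j0 + n_layers, :]
    band[:, lateral] = np.where(band[:, lateral] == 0, bolus_label, band[:, lateral])
    if axis == 1:
        out.label_grid = g.T
    return out
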