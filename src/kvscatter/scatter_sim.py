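"""Brute-force Compton scatter oracle for the fan-beam harness.

Two independent realizations of the scatter physics live here:

* a deterministic first-order estimator that sums, over an explicit grid
  of scatter sites, primary fluence x Compton interaction density x
  Klein-Nishina angular weight x detector acceptance x post-scatter
  attenuation — the calibration ground truth;
* a Monte Carlo photon-transport simulator (delta tracking, Klein-Nishina
  angular sampling) that scores primary, first-order and higher-order
  scatter separately, used both to generate higher-order ground truth and
  to cross-validate the deterministic sum.

The harness world is a 2-D fan-beam slice: directions live in the plane
and angular densities are defined per in-plane radian, with the
Klein-Nishina differential cross section supplying the angular shape.
Both realizations share this convention exactly, so they are comparable
pixel by pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelPhantom, WATER_ELECTRON_DENSITY
from .projector import (
    BowtieFilter,
    Projection,
    ProjectionStack,
    ScanGeometry,
    Spectrum,
    detector_response,
    forward_project_primary,
    open_field_counts,
)

#: classical electron radius, cm
R_E_CM = 2.8179403e-13
#: electron rest energy, keV
MEC2_KEV = 510.999


def kn_differential_cross_section(energy_kev, theta):
    """Klein-Nishina dsigma/dOmega (cm^2/sr per electron).

    ``theta`` is the scattering angle in radians, [0, pi]. Vectorized in
    both arguments. At theta = 0 the value is r_e^2 for any energy; in the
    low-energy limit the Thomson form (r_e^2/2)(1 + cos^2 theta) emerges.
    """
    energy_kev = np.asarray(energy_kev, float)
    theta = np.asarray(theta, float)
    if np.any(energy_kev <= 0):
        raise ValueError("photon energy must be positive")
    if np.any((theta < -1e-12) | (theta > np.pi + 1e-12)):
        raise ValueError("scattering angle must lie in [0, pi]")
    alpha = energy_kev / MEC2_KEV
    ratio = 1.0 / (1.0 + alpha * (1.0 - np.cos(theta)))  # E'/E
    return 0.5 * R_E_CM**2 * ratio**2 * (ratio + 1.0 / ratio - np.sin(theta) ** 2)


def scattered_energy(energy_kev, theta):
    """Compton-scattered photon energy E' (keV) at angle theta."""
    alpha = np.asarray(energy_kev, float) / MEC2_KEV
    return energy_kev / (1.0 + alpha * (1.0 - np.cos(theta)))


def kn_total_cross_section(energy_kev):
    """Total Klein-Nishina cross section (cm^2 per electron), closed form."""
    a = np.asarray(energy_kev, float) / MEC2_KEV
    sigma_t = 8.0 * np.pi * R_E_CM**2 / 3.0
    small = a < 1e-4
    a_safe = np.where(small, 1.0, a)
    term = (
        (1 + a_safe) / a_safe**2
        * (2 * (1 + a_safe) / (1 + 2 * a_safe) - np.log(1 + 2 * a_safe) / a_safe)
        + np.log(1 + 2 * a_safe) / (2 * a_safe)
        - (1 + 3 * a_safe) / (1 + 2 * a_safe) ** 2
    )
    full = 2 * np.pi * R_E_CM**2 * term
    return np.where(small, sigma_t * (1 - 2 * a), full)


_PLANAR_NORM_CACHE: dict[float, float] = {}


def planar_kn_norm(energy_kev: float) -> float:
    """Normalization 2 * int_0^pi KN(theta) dtheta of the in-plane angular
    density used throughout this harness."""
    key = round(float(energy_kev), 6)
    if key not in _PLANAR_NORM_CACHE:
        th = np.linspace(0.0, np.pi, 2049)
        _PLANAR_NORM_CACHE[key] = float(
            2.0 * np.trapezoid(kn_differential_cross_section(energy_kev, th), th)
        )
    return _PLANAR_NORM_CACHE[key]


def planar_kn_pdf(energy_kev: float, theta) -> np.ndarray:
    """In-plane scattering-angle density p(theta), normalized over
    (-pi, pi]; evaluated at |theta|."""
    return kn_differential_cross_section(energy_kev, np.abs(theta)) / planar_kn_norm(energy_kev)


def compton_mu(electron_density_rel_water, energy_kev):
    """Compton linear attenuation coefficient (1/cm)."""
    return (np.asarray(electron_density_rel_water, float) * WATER_ELECTRON_DENSITY
            * kn_total_cross_section(energy_kev))


# ---------------------------------------------------------------------------
# deterministic first-order sum


def _segment_material_lengths(phantom, starts, ends, n_samples=96):
    """Per-material path lengths (cm) of many segments, by midpoint sampling.

    starts/ends: (..., 2) world mm. Returns (n_materials, ...) lengths.
    Samples outside the grid count as no material (vacuum).
    """
    starts = np.asarray(starts, float)
    ends = np.asarray(ends, float)
    d = ends - starts
    seg_len_cm = np.linalg.norm(d, axis=-1) / 10.0
    frac = (np.arange(n_samples) + 0.5) / n_samples
    pts = starts[..., None, :] + frac[:, None] * d[..., None, :]  # (..., S, 2)
    dy, dx = phantom.voxel_size
    rows = np.floor((pts[..., 0] - phantom.origin[0]) / dy).astype(np.int64)
    cols = np.floor((pts[..., 1] - phantom.origin[1]) / dx).astype(np.int64)
    ny, nx = phantom.shape
    inside = (rows >= 0) & (rows < ny) & (cols >= 0) & (cols < nx)
    labels = phantom.label_grid[np.clip(rows, 0, ny - 1), np.clip(cols, 0, nx - 1)]
    labels = np.where(inside, labels, -1)
    step = seg_len_cm / n_samples
    out = np.empty((len(phantom.materials),) + starts.shape[:-1])
    for m in range(len(phantom.materials)):
        out[m] = (labels == m).sum(axis=-1) * step
    return out


def _scatter_sites(phantom: VoxelPhantom, downsample: int, min_rel_ed: float = 0.01):
    """Coarse scatter-site grid: block-averaged electron density and block
    centers, keeping only blocks with non-negligible electron content."""
    f = int(downsample)
    ny, nx = phantom.shape
    ed = phantom.electron_density_map() / WATER_ELECTRON_DENSITY
    my, mx = ny // f, nx // f
    blocks = ed[: my * f, : mx * f].reshape(my, f, mx, f).mean(axis=(1, 3))
    dy, dx = phantom.voxel_size
    yc = phantom.origin[0] + (np.arange(my) + 0.5) * f * dy
    xc = phantom.origin[1] + (np.arange(mx) + 0.5) * f * dx
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    keep = blocks > min_rel_ed
    centers = np.stack([yy[keep], xx[keep]], axis=-1)
    area_cm2 = (f * dy / 10.0) * (f * dx / 10.0)
    return centers, blocks[keep] * WATER_ELECTRON_DENSITY, area_cm2


def simulate_first_order_scatter(
    phantom: VoxelPhantom,
    geometry: ScanGeometry,
    spectrum: Spectrum,
    site_downsample: int = 2,
    bowtie: BowtieFilter | None = None,
    i0_photons: float = 1.0e5,
    response: str = "energy",
    n_path_samples: int = 96,
) -> ProjectionStack:
    """First-order Compton scatter at the detector by explicit summation.

    For every scatter site the primary fluence reaching it, its electron
    content, the Klein-Nishina angular weight toward each pixel, the
    in-plane angle the pixel subtends at the site, and the attenuation of
    the scattered ray (at the Compton-shifted energy) are multiplied and
    summed. Deterministic for a given site resolution.
    """
    import warnings as _w

    if site_downsample < 1:
        raise ValueError("site_downsample must be >= 1")
    centers, ne_sites, area_cm2 = _scatter_sites(phantom, site_downsample)
    counts = open_field_counts(geometry, spectrum, bowtie, i0_photons)
    i0 = counts @ detector_response(spectrum.energies_kev, response)
    n_pix = geometry.detector_size
    mu_tab = phantom.mu_table(spectrum.energies_kev)  # for in-path
    if centers.size == 0:
        _w.warn("phantom has no electron-bearing sites; scatter is zero")

    projections = []
    for angle in geometry.angles_deg:
        s1 = np.zeros(n_pix)
        if centers.size:
            s1 = _first_order_one_angle(
                phantom, geometry, spectrum, float(angle), centers, ne_sites,
                area_cm2, counts, mu_tab, response, n_path_samples)
        projections.append(Projection(s1, float(angle), i0))
    return ProjectionStack(projections, geometry, spectrum, response)


def _first_order_one_angle(phantom, geometry, spectrum, angle, centers, ne_sites,
                           area_cm2, counts, mu_tab, response, n_path_samples):
    src = geometry.source_position(angle)
    pix = geometry.pixel_positions(angle)
    n_pix = geometry.detector_size

    d_in = centers - src[None, :]
    r_in_cm = np.linalg.norm(d_in, axis=1) / 10.0
    d_in_unit = d_in / np.linalg.norm(d_in, axis=1, keepdims=True)

    # source emission per radian along each site direction, from the column
    # the direction maps to on the detector
    normal = geometry.detector_normal(angle)
    u_vec = geometry.detector_u_vec(angle)
    det_c = geometry.detector_center(angle)
    t = ((det_c - src) @ normal) / (d_in_unit @ normal)
    hit = src[None, :] + t[:, None] * d_in_unit
    u = (hit - det_c) @ u_vec
    col = np.clip(np.round(u / geometry.detector_pixel_pitch
                           + (n_pix - 1) / 2.0).astype(int), 0, n_pix - 1)
    # the source is collimated to the detector fan: sites outside it see
    # no primary (matches the Monte Carlo emission exactly)
    in_fan = np.abs(u) <= n_pix * geometry.detector_pixel_pitch / 2.0
    dtheta_src = geometry.pixel_angular_widths(src, angle)  # (n_pix,)

    # path lengths, geometry factors shared across energy bins
    L_in = _segment_material_lengths(phantom, np.broadcast_to(src, centers.shape),
                                     centers, n_path_samples)  # (n_mat, n_sites)
    d_out = pix[None, :, :] - centers[:, None, :]  # (n_sites, n_pix, 2)
    r_out = np.linalg.norm(d_out, axis=-1)
    d_out_unit = d_out / r_out[..., None]
    cos_theta = np.einsum("sj,skj->sk", d_in_unit, d_out_unit)
    cos_theta = np.clip(cos_theta, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    dtheta_pix = geometry.pixel_angular_widths(centers, angle)  # (n_sites, n_pix)
    L_out = _segment_material_lengths(
        phantom,
        np.broadcast_to(centers[:, None, :], d_out.shape),
        np.broadcast_to(pix[None, :, :], d_out.shape),
        n_path_samples,
    )  # (n_mat, n_sites, n_pix)

    s1 = np.zeros(n_pix)
    for b, energy in enumerate(spectrum.energies_kev):
        i_ang = np.where(in_fan, counts[col, b] / dtheta_src[col], 0.0)
        t_in = np.exp(-np.einsum("ms,m->s", L_in, mu_tab[:, b]))
        phi = i_ang * t_in / np.maximum(r_in_cm, 1e-9)  # photons per cm
        events = phi * compton_mu(ne_sites / WATER_ELECTRON_DENSITY, energy) * area_cm2
        e_out = scattered_energy(energy, theta)  # (n_sites, n_pix)
        mu_out = np.zeros_like(e_out)
        for m, mat in enumerate(phantom.materials):
            Lm = L_out[m]
            if Lm.any():
                mu_out += Lm * np.interp(e_out, mat.mu_energies_kev, mat.mu_values_per_cm)
        t_out = np.exp(-mu_out)
        pdf = planar_kn_pdf(energy, theta)
        resp_out = detector_response(e_out.ravel(), response).reshape(e_out.shape)
        s1 += np.einsum("s,sk->k", events, pdf * dtheta_pix * t_out * resp_out)
    return s1


# ---------------------------------------------------------------------------
# Monte Carlo transport


@dataclass
class MCScatterResult:
    """Per-order detector scores from the Monte Carlo transport."""

    primary: np.ndarray      # (n_angles, n_pix) order-0 photons
    first_order: np.ndarray  # exactly one Compton interaction
    higher_order: np.ndarray  # two or more interactions
    first_order_stderr: np.ndarray
    higher_order_stderr: np.ndarray
    rng_seed: int
    n_photons: int


def run_photon_mc(
    phantom: VoxelPhantom,
    geometry: ScanGeometry,
    spectrum: Spectrum,
    n_photons: int = 100_000,
    rng_seed: int = 0,
    bowtie: BowtieFilter | None = None,
    i0_photons: float = 1.0e5,
    response: str = "energy",
    max_interactions: int = 10,
    min_energy_kev: float = 10.0,
) -> MCScatterResult:
    """Monte Carlo photon histories through the phantom, per gantry angle.

    Photons are emitted from the source toward a uniformly sampled detector
    position (which reproduces the projector's flat open field), transported
    by delta tracking, Compton-scattered with Klein-Nishina angular sampling
    or photoelectrically absorbed, and scored at the detector by number of
    Compton interactions. Reproducible for a fixed seed.
    """
    n_pix = geometry.detector_size
    n_ang = geometry.angles_deg.size
    scores = np.zeros((3, n_ang, n_pix))
    sumsq = np.zeros((2, n_ang, n_pix))

    energies = spectrum.energies_kev
    ed_rel = np.array([m.electron_density_rel_water for m in phantom.materials])
    mu_tab_e = np.geomspace(max(min_energy_kev * 0.9, 1.0), energies.max(), 64)
    mu_tab = phantom.mu_table(mu_tab_e)  # (n_mat, 64)
    mu_max_tab = mu_tab.max(axis=0)

    ss = np.random.SeedSequence(entropy=rng_seed)
    for ai, angle in enumerate(geometry.angles_deg):
        rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        _mc_one_angle(phantom, geometry, spectrum, float(angle), n_photons, rng,
                      bowtie, i0_photons, response, max_interactions,
                      min_energy_kev, ed_rel, mu_tab_e, mu_tab, mu_max_tab,
                      scores[:, ai], sumsq[:, ai])
    return MCScatterResult(
        primary=scores[0], first_order=scores[1], higher_order=scores[2],
        first_order_stderr=np.sqrt(sumsq[0]), higher_order_stderr=np.sqrt(sumsq[1]),
        rng_seed=rng_seed, n_photons=n_photons,
    )


def _mc_one_angle(phantom, geometry, spectrum, angle, n_photons, rng, bowtie,
                  i0_photons, response, max_interactions, min_energy, ed_rel,
                  mu_tab_e, mu_tab, mu_max_tab, scores, sumsq):
    n_pix = geometry.detector_size
    pitch = geometry.detector_pixel_pitch
    src = geometry.source_position(angle)
    det_c = geometry.detector_center(angle)
    u_vec = geometry.detector_u_vec(angle)
    normal = geometry.detector_normal(angle)

    u0 = rng.uniform(-n_pix * pitch / 2.0, n_pix * pitch / 2.0, n_photons)
    targets = det_c[None, :] + u0[:, None] * u_vec[None, :]
    dirs = targets - src[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bins = rng.choice(spectrum.energies_kev.size, size=n_photons, p=spectrum.weights)
    energy = spectrum.energies_kev[bins].astype(float)
    weight = np.full(n_photons, i0_photons * n_pix / n_photons)
    if bowtie is not None:
        col = np.clip(np.round(u0 / pitch + (n_pix - 1) / 2.0).astype(int), 0, n_pix - 1)
        trans = bowtie.transmission(spectrum.energies_kev)
        weight *= trans[col, bins]

    pos = np.broadcast_to(src, (n_photons, 2)).copy()
    order = np.zeros(n_photons, dtype=np.int32)
    lo = np.array(phantom.origin)
    hi = lo + np.array(phantom.shape) * np.array(phantom.voxel_size)

    def score(p, d, e, o, w):
        denom = d @ normal
        ok = np.abs(denom) > 1e-12
        t = np.where(ok, ((det_c - p) @ normal) / np.where(ok, denom, 1.0), -1.0)
        hitp = p + t[:, None] * d
        u = (hitp - det_c) @ u_vec
        k = np.floor(u / pitch + n_pix / 2.0).astype(int)
        good = ok & (t > 0) & (k >= 0) & (k < n_pix)
        val = w * detector_response(e, response)
        for ob, sq in ((0, None), (1, 0), (2, 1)):
            sel = good & ((o == ob) if ob < 2 else (o >= 2))
            np.add.at(scores[ob], k[sel], val[sel])
            if sq is not None:
                np.add.at(sumsq[sq], k[sel], val[sel] ** 2)

    # advance to the grid bounding box; photons that miss it fly to the detector
    t_enter, t_exit = _box_entry(pos, dirs, lo, hi)
    miss = ~(t_exit > np.maximum(t_enter, 0.0))
    if miss.any():
        score(pos[miss], dirs[miss], energy[miss], order[miss], weight[miss])
    keep = ~miss
    pos = pos[keep] + np.maximum(t_enter[keep], 0.0)[:, None] * dirs[keep]
    dirs, energy, order, weight = dirs[keep], energy[keep], order[keep], weight[keep]

    dy, dx = phantom.voxel_size
    ny, nx = phantom.shape
    for _ in range(10_000):
        if pos.shape[0] == 0:
            break
        # floor keeps steps finite through zero-attenuation regions
        mu_max = np.maximum(np.interp(energy, mu_tab_e, mu_max_tab), 1e-9)
        step_mm = -np.log(rng.random(pos.shape[0])) / mu_max * 10.0
        pos = pos + step_mm[:, None] * dirs
        inside = ((pos[:, 0] > lo[0]) & (pos[:, 0] < hi[0])
                  & (pos[:, 1] > lo[1]) & (pos[:, 1] < hi[1]))
        if (~inside).any():
            e = ~inside
            score(pos[e], dirs[e], energy[e], order[e], weight[e])
        pos, dirs, energy, order, weight = (
            pos[inside], dirs[inside], energy[inside], order[inside], weight[inside])
        if pos.shape[0] == 0:
            break
        rows = np.clip(np.floor((pos[:, 0] - lo[0]) / dy).astype(int), 0, ny - 1)
        cols = np.clip(np.floor((pos[:, 1] - lo[1]) / dx).astype(int), 0, nx - 1)
        labels = phantom.label_grid[rows, cols]
        mu_tot = np.empty(pos.shape[0])
        for m in np.unique(labels):
            sel = labels == m
            mu_tot[sel] = np.interp(energy[sel], mu_tab_e, mu_tab[m])
        mu_max = np.maximum(np.interp(energy, mu_tab_e, mu_max_tab), 1e-9)
        real = rng.random(pos.shape[0]) < mu_tot / mu_max
        if real.any():
            mu_c = compton_mu(ed_rel[labels[real]], energy[real])
            scatter = rng.random(real.sum()) < mu_c / np.maximum(mu_tot[real], 1e-30)
            absorbed = real.copy()
            absorbed[np.where(real)[0][scatter]] = False
            # Compton-scatter the surviving real-interaction photons
            idx = np.where(real)[0][scatter]
            if idx.size:
                theta = _sample_kn_angle(rng, energy[idx])
                energy[idx] = scattered_energy(energy[idx], np.abs(theta))
                c, s = np.cos(theta), np.sin(theta)
                dyv, dxv = dirs[idx, 0], dirs[idx, 1]
                dirs[idx, 0] = c * dyv + s * dxv
                dirs[idx, 1] = -s * dyv + c * dxv
                order[idx] += 1
            dead = absorbed | (energy < min_energy) | (order > max_interactions)
            if dead.any():
                alive = ~dead
                pos, dirs, energy, order, weight = (
                    pos[alive], dirs[alive], energy[alive], order[alive], weight[alive])


def _box_entry(pos, dirs, lo, hi):
    """Slab-method entry/exit parameters (mm) of rays into an AABB."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - pos) / dirs
        t2 = (hi[None, :] - pos) / dirs
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    return tmin, tmax


def _sample_kn_angle(rng, energies):
    """Rejection-sample in-plane scattering angles from the KN shape."""
    out = np.empty(energies.shape[0])
    todo = np.arange(energies.shape[0])
    peak = kn_differential_cross_section(energies, 0.0)  # maximum is at theta=0
    while todo.size:
        th = rng.uniform(0.0, np.pi, todo.size)
        accept = rng.random(todo.size) * peak[todo] <= kn_differential_cross_section(
            energies[todo], th)
        out[todo[accept]] = th[accept]
        todo = todo[~accept]
    return out * rng.choice([-1.0, 1.0], size=out.shape[0])


def simulate_higher_order_scatter(
    phantom: VoxelPhantom,
    geometry: ScanGeometry,
    spectrum: Spectrum,
    n_photons: int = 100_000,
    rng_seed: int = 0,
    **kwargs,
) -> ProjectionStack:
    """Multiple-scatter (order >= 2) fluence by Monte Carlo.

    Returns a stack whose pixel data is the higher-order score; the full
    per-order result (including standard errors) is attached as ``.mc``.
    """
    if n_photons < 10_000:
        raise ValueError("n_photons >= 10^4 required for stable means")
    res = run_photon_mc(phantom, geometry, spectrum, n_photons, rng_seed, **kwargs)
    counts = open_field_counts(geometry, spectrum, kwargs.get("bowtie"),
                               kwargs.get("i0_photons", 1.0e5))
    i0 = counts @ detector_response(spectrum.energies_kev,
                                    kwargs.get("response", "energy"))
    projs = [Projection(res.higher_order[k], float(a), i0)
             for k, a in enumerate(geometry.angles_deg)]
    stack = ProjectionStack(projs, geometry, spectrum,
                            kwargs.get("response", "energy"))
    stack.mc = res
    return stack


# ---------------------------------------------------------------------------
# ground-truth bundles and summary ratios


@dataclass
class ScatterGroundTruth:
    """Primary / first-order / higher-order decomposition of a scan."""

    primary: ProjectionStack
    first_order: ProjectionStack
    higher_order: ProjectionStack
    rng_seed: int = 0

    def __post_init__(self):
        for s in (self.first_order, self.higher_order):
            if s.as_array().shape != self.primary.as_array().shape:
                raise ValueError("component stacks must share shape")
            if np.any(s.as_array() < -1e-9):
                raise ValueError("scatter components must be nonnegative")

    @property
    def whole(self) -> ProjectionStack:
        """Primary plus all scatter: the measured projection I."""
        return self.primary.with_fluence(
            self.primary.as_array() + self.first_order.as_array()
            + self.higher_order.as_array())

    @classmethod
    def generate(cls, phantom, geometry, spectrum, site_downsample=2,
                 n_photons=50_000, rng_seed=0, bowtie=None,
                 i0_photons=1.0e5, response="energy",
                 smooth_sigma_px: float = 4.0,
                 smooth_sigma_angle: float = 1.0) -> "ScatterGroundTruth":
        """Simulate all three components for a phantom in one call.

        The Monte Carlo higher-order score is smoothed along the detector
        (Gaussian, ``smooth_sigma_px`` pixels) and circularly across
        gantry angles (``smooth_sigma_angle`` projections); 0 disables
        either. This is a variance reduction justified by the low spatial
        and angular frequency of multiple scatter; the mean is preserved.
        """
        from scipy.ndimage import gaussian_filter1d

        primary = forward_project_primary(phantom, geometry, spectrum, bowtie,
                                          i0_photons, response)
        first = simulate_first_order_scatter(phantom, geometry, spectrum,
                                             site_downsample, bowtie,
                                             i0_photons, response)
        higher = simulate_higher_order_scatter(phantom, geometry, spectrum,
                                               n_photons, rng_seed,
                                               bowtie=bowtie,
                                               i0_photons=i0_photons,
                                               response=response)
        arr = higher.as_array()
        if smooth_sigma_px > 0:
            arr = gaussian_filter1d(arr, smooth_sigma_px, axis=1, mode="nearest")
        if smooth_sigma_angle > 0 and arr.shape[0] > 2:
            arr = gaussian_filter1d(arr, smooth_sigma_angle, axis=0, mode="wrap")
        if smooth_sigma_px > 0 or smooth_sigma_angle > 0:
            higher = higher.with_fluence(arr)
        return cls(primary, first, higher, rng_seed)


@dataclass
class SPRResult:
    """Scatter-to-primary ratio map with its maximum."""

    ratio: np.ndarray  # (n_angles, n_pix), NaN where primary ~ 0
    max_ratio: float
    n_excluded: int


def scatter_primary_ratio(whole: ProjectionStack, primary: ProjectionStack,
                          min_primary_frac: float = 1e-6) -> SPRResult:
    """(whole - primary) / primary per pixel; pixels whose primary is below
    ``min_primary_frac`` of the open field are excluded and counted."""
    w = whole.as_array()
    p = primary.as_array()
    floor = min_primary_frac * primary.i0_array()
    valid = p > floor
    ratio = np.full(p.shape, np.nan)
    ratio[valid] = (w[valid] - p[valid]) / p[valid]
    return SPRResult(ratio, float(np.nanmax(ratio)), int((~valid).sum()))
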