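"""Fast first-order scatter estimator S1(P) and higher-order closures.

This is the in-loop model the correction iterates on: it maps a candidate
primary image to a first-order scatter image using only the detector data
itself — no access to the phantom. Each detector column's reading is
converted to a water-equivalent thickness, scatter sites are laid out
along the ray through that thickness, and every site radiates toward all
columns with Klein-Nishina weighting and water attenuation of the
scattered ray. The integral runs on a column-downsampled grid (scatter is
low-frequency) and is interpolated back to full resolution.

Higher-order scatter is closed either as a constant offset b or as a
fraction a of the first-order estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantoms import load_material
from .projector import AntiscatterGrid, Projection, ScanGeometry, Spectrum
from .scatter_sim import (
    compton_mu,
    planar_kn_pdf,
    scattered_energy,
)


@dataclass
class ScatterModelConfig:
    """Free choices of the S1(P) estimator.

    kernel_energy_kev : single energy at which the Klein-Nishina kernel and
        water attenuation are evaluated (None = spectrum mean energy).
    downsample_factor : detector-column stride of the scatter integral.
    n_sites : scatter sites distributed along each ray's water-equivalent
        chord.
    exit_path_rule : water thickness attenuating the scattered ray on its
        way out. ``fan_map`` (default) integrates the exit segment through
        the object support implied by the thickness map (each ray carries
        a water chord of its measured thickness centered at its closest
        approach to the isocenter); ``equivalent_cylinder`` takes the
        exact chord from the site to the boundary of a water cylinder
        whose radius is inferred from the thickness map;
        ``forward_remaining`` uses the water remaining beyond the site
        along its incident ray, stretched by the scattering-angle
        obliquity; ``half_target`` uses half the target column's
        water-equivalent thickness.
    response : detector weighting, matching the projector convention.
    """

    kernel_energy_kev: float | None = None
    downsample_factor: int = 4
    n_sites: int = 8
    exit_path_rule: str = "fan_map"
    response: str = "energy"
    n_exit_samples: int = 12

    def __post_init__(self):
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.exit_path_rule not in ("fan_map", "equivalent_cylinder",
                                       "forward_remaining", "half_target", "none"):
            raise ValueError("unknown exit_path_rule")

    def kernel_energy(self, spectrum: Spectrum | None) -> float:
        if self.kernel_energy_kev is not None:
            return float(self.kernel_energy_kev)
        if spectrum is None:
            raise ValueError("kernel energy unset and no spectrum given")
        return spectrum.mean_energy()


@dataclass
class ScatterEstimate:
    """State of the scatter model for one projection: S1, Sh and closure."""

    s1: np.ndarray
    sh: np.ndarray
    mode: str  # 'proportional_a' | 'constant_b'
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.mode not in ("proportional_a", "constant_b"):
            raise ValueError("mode must be 'proportional_a' or 'constant_b'")
        if np.any(self.s1 < 0) or np.any(self.sh < 0):
            raise ValueError("scatter estimates must be nonnegative")

    @property
    def total(self) -> np.ndarray:
        return self.s1 + self.sh


def water_equivalent_thickness(p: np.ndarray, i0: np.ndarray,
                               mu_water_per_cm: float) -> tuple[np.ndarray, int]:
    """Per-column water-equivalent thickness t = -ln(P/i0)/mu_w (cm).

    Returns (t, n_clipped) where n_clipped counts P > i0 pixels clipped
    to the open field."""
    ratio = np.asarray(p, float) / np.maximum(np.asarray(i0, float), 1e-300)
    n_clipped = int(np.sum(ratio > 1.0 + 1e-12))
    ratio = np.clip(ratio, 1e-12, 1.0)
    return -np.log(ratio) / mu_water_per_cm, n_clipped


def estimate_s1(
    primary_candidate: Projection,
    geometry: ScanGeometry,
    config: ScatterModelConfig,
    spectrum: Spectrum | None = None,
    grid: AntiscatterGrid | None = None,
) -> np.ndarray:
    """First-order scatter image from a candidate primary image alone.

    When an antiscatter grid is supplied, the candidate and its open field
    are assumed grid-attenuated (divided by Tp before the thickness
    conversion) and the returned scatter image is scaled by Ts.
    """
    p = primary_candidate.pixel_fluence
    i0 = primary_candidate.i0
    tp = ts = 1.0
    if grid is not None:
        tp, ts = grid.primary_transmission, grid.scatter_transmission
    e0 = config.kernel_energy(spectrum)
    water = load_material("water")
    mu_w = float(water.mu(e0))
    mu_c = float(compton_mu(1.0, e0))

    t_cm, n_clipped = water_equivalent_thickness(p / tp, i0 / tp, mu_w)
    if n_clipped:
        # routine for contaminated candidates (P0 = I exceeds i0 off-object)
        logging.getLogger(__name__).debug(
            "%d pixels exceeded the open field and were clipped", n_clipped)

    f = config.downsample_factor
    n_pix = geometry.detector_size
    coarse = np.arange(0, n_pix, f)
    # block-average t onto the coarse columns for stability
    t_c = np.array([t_cm[k:k + f].mean() for k in coarse])
    i0_c = np.array([(i0[k:k + f] / tp).mean() for k in coarse])

    angle = primary_candidate.angle_deg
    src = geometry.source_position(angle)
    det_c = geometry.detector_center(angle)
    u_vec = geometry.detector_u_vec(angle)
    u = geometry.pixel_u()
    pix_all = geometry.pixel_positions(angle)
    pix_c = pix_all[coarse]
    d = pix_c - src[None, :]
    ray_dir = d / np.linalg.norm(d, axis=1, keepdims=True)
    # closest approach of each ray to the isocenter: center of the assumed
    # water chord
    t_par = -(src[None, :] * ray_dir).sum(axis=1)
    mid = src[None, :] + t_par[:, None] * ray_dir

    n_s = config.n_sites
    frac = (np.arange(n_s) + 0.5) / n_s  # depth fractions within the chord
    # site positions: spread over the geometric chord (= WET, water object)
    offs = (frac - 0.5)[None, :, None] * (t_c[:, None, None] * 10.0) * ray_dir[:, None, :]
    sites = mid[:, None, :] + offs  # (n_rays, n_sites, 2)

    depth = frac[None, :] * t_c[:, None]  # (n_rays, n_sites) cm of water upstream
    remaining = t_c[:, None] - depth
    t_in = np.exp(-mu_w * depth)
    # photons entering the ray's pixel-tube (each coarse ray stands for f
    # detector columns of primary), per site segment of length t/n
    events = (f * i0_c[:, None] / _resp(e0, config.response)) * t_in * mu_c * (t_c[:, None] / n_s)

    # angular spread toward every coarse target column
    flat_sites = sites.reshape(-1, 2)
    d_out = pix_c[None, :, :] - flat_sites[:, None, :]
    r_out = np.linalg.norm(d_out, axis=-1)
    d_out_unit = d_out / np.maximum(r_out[..., None], 1e-12)
    d_in_unit = np.repeat(ray_dir, n_s, axis=0)
    cos_th = np.clip(np.einsum("sj,skj->sk", d_in_unit, d_out_unit), -1.0, 1.0)
    theta = np.arccos(cos_th)

    normal = geometry.detector_normal(angle)
    cosb = np.abs(d_out_unit @ normal)
    dtheta = geometry.detector_pixel_pitch * cosb / np.maximum(r_out, 1e-12)

    e_out = scattered_energy(e0, theta)
    mu_w_out = np.interp(e_out, water.mu_energies_kev, water.mu_values_per_cm)
    if config.exit_path_rule == "fan_map":
        exit_t = _fan_map_exit_path(
            flat_sites, d_out_unit, r_out, src, det_c, normal, u_vec,
            u[coarse], t_c, mid, config.n_exit_samples)
    elif config.exit_path_rule == "equivalent_cylinder":
        # water cylinder centered at the isocenter whose diameter is the
        # largest water-equivalent thickness seen by the detector
        r_mm = 10.0 * t_c.max() / 2.0
        proj = np.einsum("sj,skj->sk", flat_sites, d_out_unit)  # p . u
        p2 = np.sum(flat_sites**2, axis=1)[:, None]
        disc = proj**2 - p2 + r_mm**2
        exit_t = np.where(disc > 0, (-proj + np.sqrt(np.maximum(disc, 0.0))), 0.0)
        exit_t = np.clip(exit_t, 0.0, None) / 10.0  # mm -> cm of water
    elif config.exit_path_rule == "forward_remaining":
        exit_t = remaining.reshape(-1)[:, None] / np.clip(cos_th, 0.5, 1.0)
    elif config.exit_path_rule == "half_target":
        exit_t = np.broadcast_to(0.5 * t_c[None, :], theta.shape)
    else:
        exit_t = np.zeros_like(theta)
    t_out = np.exp(-mu_w_out * exit_t)
    pdf = planar_kn_pdf(e0, theta)
    resp_ratio = _resp(e_out, config.response)

    s1_c = np.einsum("s,sk->k", events.ravel(),
                     pdf * dtheta * t_out * resp_ratio)
    # interpolate from coarse column centers back to all columns
    s1 = np.interp(u, u[coarse], s1_c)
    return ts * np.maximum(s1, 0.0)


def _fan_map_exit_path(flat_sites, d_out_unit, r_out, src, det_c, normal,
                       u_vec, u_coarse, t_c, mid, n_samples):
    """Water path (cm) of each site->pixel exit segment through the object
    support implied by the thickness map.

    Every coarse ray carries a water chord of its measured water-equivalent
    thickness centered at its closest approach to the isocenter; a point is
    'in water' if it falls inside the chord of the ray it lies on. The exit
    segment is clipped to a bounding circle of the support before sampling
    so the midpoint rule spends its samples where the object can be.
    """
    l_mid = np.linalg.norm(mid - src[None, :], axis=1)  # (n_rays,)
    half_chord = 5.0 * t_c  # mm (t is cm of water; chord = 10 t)
    r_bound = float(np.max(np.linalg.norm(mid, axis=1) + half_chord) + 1e-6)

    pu = np.einsum("sj,skj->sk", flat_sites, d_out_unit)
    p2 = np.sum(flat_sites**2, axis=1)[:, None]
    disc = pu**2 - p2 + r_bound**2
    good = disc > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    l1 = np.clip(-pu - sq, 0.0, r_out)
    l2 = np.clip(-pu + sq, 0.0, r_out)
    span = np.maximum(l2 - l1, 0.0) * good

    fr = (np.arange(n_samples) + 0.5) / n_samples
    lq = l1[..., None] + fr[None, None, :] * span[..., None]  # (S, K, M)
    q = flat_sites[:, None, None, :] + lq[..., None] * d_out_unit[:, :, None, :]
    v = q - src
    denom = v @ normal
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    tpar = ((det_c - src) @ normal) / denom
    hit = src + tpar[..., None] * v
    uq = (hit - det_c) @ u_vec
    t_q = np.interp(uq, u_coarse, t_c)          # cm of water on that ray
    l_q = np.interp(uq, u_coarse, l_mid)        # mm, source -> chord center
    dist = np.linalg.norm(v, axis=-1)           # mm from source
    inside = np.abs(dist - l_q) <= 5.0 * t_q
    return span / 10.0 * inside.mean(axis=-1)


def _resp(e, mode):
    if mode == "energy":
        return np.asarray(e, float) / 100.0
    return np.ones_like(np.asarray(e, float))


def make_sh(s1: np.ndarray, mode: str, a: float = 0.0, b: float = 0.0) -> np.ndarray:
    """Higher-order closure: a * S1 (proportional) or a constant field b."""
    s1 = np.asarray(s1, float)
    if mode == "proportional_a":
        if a < 0:
            raise ValueError("a must be >= 0")
        return a * s1
    if mode == "constant_b":
        if b < 0:
            raise ValueError("b must be >= 0")
        return np.full_like(s1, float(b))
    raise ValueError("mode must be 'proportional_a' or 'constant_b'")
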