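"""Projection-stack persistence and run configuration.

Stacks are stored as a multi-page TIFF (one page per gantry angle, dtype
preserved, hence bit-exact round trips) plus a JSON sidecar carrying the
geometry, spectrum, per-pixel open-field values and any extra keys, which
are preserved verbatim on rewrite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .projector import Projection, ProjectionStack, ScanGeometry, Spectrum

_REQUIRED_SIDECAR = ("angles_deg", "geometry", "spectrum", "i0")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_projection_stack(path, stack: ProjectionStack,
                           extra: dict | None = None) -> Path:
    """Write a stack as ``<path>.tif`` + ``<path>.json``."""
    path = Path(path).with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.as_array()
    if data.ndim == 2:  # fan beam: one detector row per page
        data = data[:, None, :]
    tifffile.imwrite(path, data, photometric="minisblack")
    g = stack.geometry
    sidecar = {
        "angles_deg": [float(a) for a in g.angles_deg],
        "geometry": {
            "source_axis_distance": g.source_axis_distance,
            "axis_detector_distance": g.axis_detector_distance,
            "detector_pixel_pitch": g.detector_pixel_pitch,
            "detector_size": g.detector_size,
            "beam": g.beam,
        },
        "spectrum": {
            "energies_kev": [float(e) for e in stack.spectrum.energies_kev],
            "weights": [float(w) for w in stack.spectrum.weights],
        },
        "i0": [[float(v) for v in p.i0] for p in stack.projections],
        "detector_response_mode": stack.detector_response_mode,
    }
    sidecar.update(getattr(stack, "sidecar_extra", {}) or {})
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_projection_stack(path) -> ProjectionStack:
    """Read a stack written by :func:`write_projection_stack`.

    Unknown sidecar keys are kept on ``stack.sidecar_extra`` and written
    back verbatim on the next write.
    """
    path = Path(path).with_suffix(".tif")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path}; a stack needs a JSON sidecar "
            f"with fields {_REQUIRED_SIDECAR}")
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in _REQUIRED_SIDECAR if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} lacks required fields {missing}")
    geometry = ScanGeometry(angles_deg=np.array(sidecar["angles_deg"]),
                            **sidecar["geometry"])
    data = tifffile.imread(path)
    data = np.asarray(data).reshape(geometry.angles_deg.size, -1)
    spectrum = Spectrum(np.array(sidecar["spectrum"]["energies_kev"]),
                        np.array(sidecar["spectrum"]["weights"]))
    projections = [
        Projection(data[k], float(geometry.angles_deg[k]),
                   np.array(sidecar["i0"][k]))
        for k in range(data.shape[0])
    ]
    stack = ProjectionStack(projections, geometry, spectrum,
                            sidecar.get("detector_response_mode", "energy"))
    known = set(_REQUIRED_SIDECAR) | {"detector_response_mode"}
    stack.sidecar_extra = {k: v for k, v in sidecar.items() if k not in known}
    return stack


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def default_config() -> dict:
    """The packaged synthetic tissue-phantom experiment configuration."""
    from importlib import resources

    with resources.files("kvscatter._data").joinpath("gammex_synthetic.yaml").open() as fh:
        return yaml.safe_load(fh)
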