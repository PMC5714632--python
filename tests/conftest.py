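"""Shared fixtures: small fan-beam geometries and phantoms.

Expensive simulation products (primary stacks, oracle scatter) are
session-scoped so the suite computes each once.
"""

import numpy as np
import pytest

import kvscatter as kv


@pytest.fixture(scope="session")
def mono60():
    return kv.Spectrum.mono(60.0)


@pytest.fixture(scope="session")
def geo_single():
    """One gantry angle, 128-pixel detector, generous field of view."""
    return kv.ScanGeometry(
        source_axis_distance=1000.0, axis_detector_distance=500.0,
        detector_pixel_pitch=2.4, detector_size=128, angles_deg=[0.0])


@pytest.fixture(scope="session")
def water_cyl80():
    """16-cm water cylinder on a 96^2, 2-mm grid."""
    return kv.make_cylinder_phantom(80.0, (96, 96), 2.0)


@pytest.fixture(scope="session")
def cyl80_primary(water_cyl80, geo_single, mono60):
    return kv.forward_project_primary(water_cyl80, geo_single, mono60)


@pytest.fixture(scope="session")
def cyl80_first_order(water_cyl80, geo_single, mono60):
    return kv.simulate_first_order_scatter(water_cyl80, geo_single, mono60,
                                           site_downsample=4)


@pytest.fixture(scope="session")
def small_insert_phantom():
    """Three-insert water body for reconstruction tests (fits a 90-angle,
    96-pixel fan without truncation)."""
    inserts = [
        (kv.water_equivalent_material("dense-bone-like", 1.6), (30.0, 0.0), 10.0),
        (kv.water_equivalent_material("lung-like", 0.3), (-30.0, 0.0), 10.0),
        (kv.water_equivalent_material("adipose-like", 0.95), (0.0, 30.0), 10.0),
    ]
    return kv.make_insert_phantom(60.0, inserts, (64, 64), 2.0)
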