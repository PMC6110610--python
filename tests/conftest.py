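import numpy as np
import pytest

from centriotome import model_builder as mb
from centriotome.studies import _reference_volume
from centriotome.tomo_sim import WedgeMask


@pytest.fixture(scope="session")
def cho_preset():
    return mb.load_preset("cho")


@pytest.fixture(scope="session")
def s2_preset():
    return mb.load_preset("s2")


@pytest.fixture(scope="session")
def proximal_blade(cho_preset):
    spec = mb.blade_spec_for(cho_preset, "proximal")
    return mb.build_blade(spec, 48.0, seed=3)


@pytest.fixture(scope="session")
def proximal_gamma(cho_preset):
    return mb.particle_frame_gamma(
        cho_preset.radius_of("proximal"), cho_preset.tilt_of("proximal"),
        cho_preset.center_offset,
    )


@pytest.fixture(scope="session")
def blade_reference(proximal_blade, cho_preset, proximal_gamma):
    """Ideal rasterized proximal-blade reference, 1.75 nm voxels, 48^3."""
    return _reference_volume(
        proximal_blade, proximal_gamma, cho_preset.center_offset, 1.75, 48,
    )


@pytest.fixture(scope="session")
def tubule_centers(proximal_blade, cho_preset, proximal_gamma):
    return mb.tubule_centers_in_reference(
        proximal_blade, proximal_gamma, cho_preset.center_offset
    )


@pytest.fixture(scope="session")
def wedge60():
    return WedgeMask(-60.0, 60.0)


@pytest.fixture(scope="session")
def tiny_model(cho_preset):
    """96 nm CHO stub (proximal+distal, 4 segments per rod)."""
    preset = mb.preset_from_dict(
        dict(name="cho", length=96.0, domain_boundary=48.0,
             radius_proximal=cho_preset.radius_proximal,
             radius_distal=cho_preset.radius_distal,
             blade_tilt_proximal=cho_preset.blade_tilt_proximal,
             blade_tilt_distal=cho_preset.blade_tilt_distal)
    )
    return mb.assemble_centriole(preset, mb.FlatteningSpec(0.0), seed=7)


def rotation_distance_deg(r1, r2):
    """Geodesic distance between rotation matrices, degrees."""
    c = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))
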