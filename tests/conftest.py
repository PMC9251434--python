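import pytest

import corelandscape as cl

#: compact barrel for grid-heavy pore tests (same wall/bead scale, smaller
#: radius and height so fine rasterizations stay cheap)
MINI = dict(barrel_outer_radius=25.0, wall_thickness=10.0, ring_spacing=8.0)


def mini_config(**kwargs):
    params = {**MINI, **kwargs}
    return cl.AssemblyConfig(**params)


@pytest.fixture(scope="session")
def reference():
    return cl.build_reference_assembly(cl.AssemblyConfig())


@pytest.fixture(scope="session")
def mode_catalogue(reference):
    return cl.define_modes(reference)


@pytest.fixture(scope="session")
def surface():
    return cl.default_surface()
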