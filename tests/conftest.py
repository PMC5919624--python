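import pytest

import dosegradient as dg
from dosegradient.synthetic import GridSpec, MultiLayerSpec, make_multilayer


@pytest.fixture(scope="session")
def radial_small():
    """A compact radial SRS phantom (body r=30 mm) for fast pipeline tests."""
    spec = dg.RadialDoseSpec(body_radius=30.0)
    dose, body, ptv = dg.make_radial_dose(spec)
    return spec, dose, body, ptv


@pytest.fixture(scope="session")
def blob_layers():
    """Irregular 2.5 cm^3 blob expanded to 14 layers at 1-mm intervals, 0.5-mm grid."""
    grid = GridSpec(spacing=0.5, half_extent=27.0)
    spec = MultiLayerSpec(
        base_shape="blob", base_volume=2500.0, n_layers=14, interval=1.0, seed=1
    )
    return make_multilayer(spec, grid)


@pytest.fixture(scope="session")
def srs_table():
    from dosegradient import datasets

    return datasets.srs_reference()


@pytest.fixture(scope="session")
def multilayer_table():
    from dosegradient import datasets

    return datasets.multilayer_reference()
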