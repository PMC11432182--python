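import numpy as np
import pytest

from cystfem import (
    ExperimentConfig,
    LoadCase,
    build_attribute_map,
    build_model,
    default_material_table,
    generate_geometry,
    run_grid,
)
from cystfem.geometry import CLASS_CODES, LabelImage, standard_scenarios


@pytest.fixture(scope="session")
def materials():
    return default_material_table()


@pytest.fixture(scope="session")
def frontal_image():
    return generate_geometry("frontal", seed=1)


@pytest.fixture(scope="session")
def sagittal_image():
    return generate_geometry("sagittal", seed=1)


@pytest.fixture(scope="session")
def scenarios():
    return standard_scenarios()


def make_plate(n: int = 20, cls: str = "cortical", pixel_size: float = 0.5) -> LabelImage:
    """Uniform square plate of one tissue class (patch-test substrate)."""
    labels = np.full((n, n), CLASS_CODES[cls], dtype=np.uint8)
    return LabelImage(labels, pixel_size=pixel_size)


def solve_plate(image, materials, pressure=0.248, bottom_bc="roller",
                formulation="plane_strain", method="sparse"):
    from cystfem.fem import assemble_and_solve

    attrs = build_attribute_map(image, materials)
    model = build_model(
        image, attrs, LoadCase(pressure_override=pressure),
        formulation=formulation, bottom_bc=bottom_bc,
    )
    return model, assemble_and_solve(model, method=method)


@pytest.fixture(scope="session")
def full_grid_result():
    """One full default-grid run (84 solves), shared across acceptance tests."""
    return run_grid(ExperimentConfig())
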