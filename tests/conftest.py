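import numpy as np
import pandas as pd
import pytest

from ploidyscope import synthetic_data as sd


@pytest.fixture(scope="session")
def noise_free_render():
    """Small zero-noise population rendered to frames, with placement map."""
    spec = sd.population_spec_for_strain(
        "BALB_cJ", n_cells=60, n_reference=20, intensity_cv=0.0, seed=3
    )
    table = sd.generate_population(spec)
    img = sd.ImagingSpec(additive_noise_sd=0.0)
    frames, placement = sd.render_images(table, img, seed=3)
    return table, frames, placement


@pytest.fixture(scope="session")
def default_noise_render():
    """Default-noise population rendered to frames (nucleation accuracy checks)."""
    spec = sd.population_spec_for_strain(
        "BALB_cByJ", n_cells=400, n_reference=60, seed=5
    )
    table = sd.generate_population(spec)
    frames, placement = sd.render_images(table, sd.ImagingSpec(), seed=5)
    return table, frames, placement


def make_cell_table(groups):
    """Build (cells, calls) frames directly for composition tests.

    ``groups`` is a list of (count, n_nuclei, ploidy_class) tuples describing
    homogeneous cell groups of one cell type.
    """
    cells, calls = [], []
    nucleus_id = 0
    cell_id = 0
    for count, n_nuclei, cls in groups:
        for _ in range(count):
            ids = tuple(range(nucleus_id, nucleus_id + n_nuclei))
            nucleus_id += n_nuclei
            cells.append(
                dict(
                    cell_id=cell_id,
                    cell_type="cardiomyocyte",
                    nucleus_ids=ids,
                    n_nuclei=n_nuclei,
                    viable=True,
                    qc="ok",
                )
            )
            cell_id += 1
            value = {"2n": 1.0, "4n": 2.0, "8n": 4.0, "unassigned": 2.7}[cls]
            for i in ids:
                calls.append(
                    dict(nucleus_id=i, normalized_intensity=value, ploidy_class=cls)
                )
    return pd.DataFrame(cells), pd.DataFrame(calls)
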