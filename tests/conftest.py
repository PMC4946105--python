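import numpy as np
import pytest

from ctcscan.image import CD45, DAPI, EPITHELIAL, MESENCHYMAL
from ctcscan.segment import (
    BackgroundEstimate,
    CellCandidate,
    run_spot_selection,
)
from ctcscan.simulate import CellPopulation, FilterGeometry, generate_filter_spot


@pytest.fixture(scope="session")
def small_spot():
    """A small mixed spot: isolated leukocytes, CTCs, debris and clumps."""
    geom = FilterGeometry(spot_diameter_mm=0.3)
    pop = CellPopulation(n_leukocytes=80, n_ctcs=4, n_debris=40, n_leukocyte_clusters=3)
    return generate_filter_spot(geom, pop, seed=11)


@pytest.fixture(scope="session")
def small_selection(small_spot):
    return run_spot_selection(
        small_spot.images,
        pore_centers_um=small_spot.to_image_coords(small_spot.pore_centers_um),
    )


def make_candidate(
    idx: int = 0,
    area_um2: float = 100.0,
    dapi: float = 120.0,
    bg: float = 8.0,
    cd45: float = 9.0,
    epi: float = 9.0,
    mes: float = 9.0,
) -> CellCandidate:
    """A synthetic measured candidate (mask is a dummy 1-px patch)."""
    import math

    c = CellCandidate(
        id=idx,
        bbox=(0, 0, 1, 1),
        mask=np.ones((1, 1), dtype=bool),
        centroid_um=(0.0, 0.0),
        nucleus_area_um2=area_um2,
        equiv_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
    )
    c.dapi_avg = dapi
    c.background_avg = bg
    c.cd45_avg = cd45
    c.epithelial_avg = epi
    c.mesenchymal_avg = mes
    return c


@pytest.fixture
def flat_backgrounds():
    return {
        role: BackgroundEstimate(mean=8.0, sd=1.5, n_pixels=1000)
        for role in (DAPI, CD45, EPITHELIAL, MESENCHYMAL)
    }
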