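import numpy as np
import pytest

from thermoclade import synthetic, thermal, treeio

#: 3-tip worked example used throughout: depths {2, 1}, cluster {A,B} + C
TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return treeio.parse_newick(TOY_NEWICK)


@pytest.fixture
def toy_schedule(toy_tree):
    return treeio.branching_schedule(toy_tree)


@pytest.fixture
def small_raster():
    """5x8 one-degree raster with a constant-gradient SST field and one
    nodata (land) cell at row 1, col 2."""
    spec = thermal.GridSpec(
        ncols=8, nrows=5, xllcorner=0.0, yllcorner=0.0, cellsize=1.0, nodata=-9999.0
    )
    lat = spec.cell_lats()[:, None] * np.ones((1, 8))
    tmean = 25.0 - 0.5 * lat
    tmin, tmax = tmean - 3.0, tmean + 3.0
    for layer in (tmin, tmean, tmax):
        layer[1, 2] = -9999.0
    return thermal.SstRaster(spec=spec, tmin=tmin, tmean=tmean, tmax=tmax)


@pytest.fixture
def separated_tree():
    """20-tip tree: 5 species x 4 samples with 10x depth separation."""
    tree, truth = synthetic.simulate_gmyc_tree(
        synthetic.GmycSimConfig(k=5, m=4, separation=10.0, seed=42)
    )
    return tree, truth
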