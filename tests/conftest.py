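import numpy as np
import pytest

from gliovasc import synthetic as syn


@pytest.fixture(scope="session")
def tube_render():
    """Straight tube, radius 4 µm, noiseless, with full ground truth."""
    spec = syn.straight_tube_spec((32, 48, 96), radius=4.0, orientation="x")
    tree = syn.build_vessel_tree(spec)
    volume, gt = syn.render_volume(tree, syn.RenderParams(), seed=1)
    return volume, gt


@pytest.fixture(scope="session")
def branching_render():
    """Tree with known junction taxonomy {primary: 4, secondary: 1,
    tertiary: 1}, noiseless."""
    spec = syn.make_branching_tree((64, 128, 128), n_primary=4, n_secondary=1,
                                   n_tertiary=1)
    tree = syn.build_vessel_tree(spec)
    volume, gt = syn.render_volume(tree, syn.RenderParams(), seed=2)
    return tree, volume, gt


@pytest.fixture(scope="session")
def nuclei_render():
    """150 nuclei, no vessels, noiseless."""
    tree = syn.build_vessel_tree(syn.TreeSpec.make([], [], (48, 96, 96)))
    volume, gt = syn.render_volume(tree, syn.RenderParams(n_nuclei=150), seed=5)
    return volume, gt


@pytest.fixture(scope="session")
def tcell_render():
    """T cells at requested distances from a tube's endothelium."""
    spec = syn.straight_tube_spec((40, 96, 96), radius=8.0, orientation="x")
    tree = syn.build_vessel_tree(spec)
    volume, gt = syn.render_volume(
        tree, syn.RenderParams(tcell_distances=(0.0, 2.0, 15.0, 30.0)), seed=9)
    return volume, gt


@pytest.fixture(scope="session")
def myeloid_render():
    """200 myeloid cells with mixture MHCII in a tumor-mass/stroma layout."""
    tree = syn.build_vessel_tree(syn.TreeSpec.make([], [], (64, 160, 160)))
    volume, gt = syn.render_volume(
        tree,
        syn.RenderParams(myeloid_spec=syn.MyeloidSpec(n_cells=200),
                         gfap_mode="tumor_mass"),
        seed=4)
    return volume, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
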