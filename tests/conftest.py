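import pytest

from glucolux import design_study, geometry, optics


@pytest.fixture(scope="session")
def skin_scene():
    """Default 17 x 17 x 4 mm three-layer skin scene at 0.05-mm voxels."""
    return geometry.tissue_scene()


@pytest.fixture(scope="session")
def tissue_props():
    return optics.default_optical_properties()


@pytest.fixture(scope="session")
def designs():
    """The three default candidate designs."""
    return {f"design{i}": geometry.default_design(f"design{i}") for i in (1, 2, 3)}


@pytest.fixture(scope="session")
def offset_luminescence(skin_scene, designs, tissue_props):
    """Total luminescence of each design at Y offsets 0/3/5 mm, depth 2 mm.

    Shared by the design-comparison and offset-sensitivity acceptance checks
    (one Monte Carlo pass per design/offset at a reduced photon budget whose
    sampling error is far below the acceptance tolerances).
    """
    st = design_study.MCSettings(n_photons=100_000, n_emission=100_000, repeats=1, seed=1234)
    out = {}
    for k, (name, d) in enumerate(designs.items()):
        for o, yoff in enumerate((0.0, 3.0, 5.0)):
            df = design_study.luminescence_of(
                d, geometry.Placement(0.0, yoff, 2.0), skin_scene, st, tissue_props,
                tags=(k, o),
            )
            out[(name, yoff)] = float(df["total"].mean())
    return out
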