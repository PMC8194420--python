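import numpy as np
import pytest

from fossilscout.raster_io import DEFAULT_BANDS, SpectralScene
from fossilscout.synthetic_scene import SceneSpec, SiteSpec, generate_scene, plant_sites


@pytest.fixture
def tiny_scene() -> SpectralScene:
    """Deterministic 4x5 scene with 3 bands and one nodata pixel."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.0, 1.0, size=(4, 5, 3))
    mask = np.zeros((4, 5), dtype=bool)
    mask[3, 4] = True
    return SpectralScene(
        values=values,
        bands=("red", "nir", "swir1"),
        origin_easting=500_000.0,
        origin_northing=8_000_000.0,
        pixel_size=30.0,
        crs_tag="UTM test",
        nodata_mask=mask,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study scene + planted catalog (shared, read-only)."""
    spec = SceneSpec(seed=7)
    scene, truth = generate_scene(spec)
    catalog = plant_sites(
        truth,
        SiteSpec(seed=7),
        spec.origin_easting,
        spec.origin_northing,
        spec.pixel_size,
        spec.fossiliferous_class,
    )
    return spec, scene, truth, catalog
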