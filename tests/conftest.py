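import numpy as np
import pytest

from gliamap.scene import SectionScene
from gliamap.synthetic import (
    default_counts_config,
    default_scene_config,
    simulate_counts,
    simulate_section,
)
from gliamap.synthetic.scene_sim import GroupParams, SceneConfig


def fimbria_only_config(seed=0, mice=1, **group_kwargs) -> SceneConfig:
    """Small fimbria-only scene used for fast tests."""
    groups = group_kwargs.pop("groups", None) or {
        "YNG": GroupParams(density=150, align_sd=40, gal3_frac=0.02,
                           area_mu=np.log(60), aspect=1.2, apoe_frac=0.25),
        "OLD": GroupParams(density=300, align_sd=10, gal3_frac=0.35,
                           area_mu=np.log(110), aspect=3.0, apoe_frac=0.25,
                           apoe_offset=400.0),
    }
    scene = SectionScene(
        regions={"fimbria": np.array([[0, 0], [2000, 0], [2000, 500], [0, 500]], float)},
        midline=np.array([[0, 250], [2000, 250]], float),
        ventricle=np.array([[0, 0], [2000, 0]], float),
    )
    return SceneConfig(
        seed=seed,
        groups=groups,
        mice_per_group=mice,
        scene=scene,
        tracts_per_region={"fimbria": 12},
        tract_angle={"fimbria": 0.0},
        tract_angle_sd={"fimbria": 5.0},
    )


@pytest.fixture(scope="session")
def small_section():
    """One YNG + one OLD mouse in a fimbria-only scene."""
    return simulate_section(fimbria_only_config(seed=7))


@pytest.fixture(scope="session")
def two_region_section():
    cfg = default_scene_config(seed=3, groups=("YNG", "OLD"), mice_per_group=2)
    return simulate_section(cfg)


@pytest.fixture(scope="session")
def counts_dataset():
    """QC-ready AnnData (raw counts) plus ground truth, ~1600 cells."""
    cfg = default_scene_config(seed=3, groups=("YNG", "OLD"), mice_per_group=2)
    scene, *_ = simulate_section(cfg)
    ccfg = default_counts_config(seed=5, n_genes=300)
    return simulate_counts(ccfg, scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
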