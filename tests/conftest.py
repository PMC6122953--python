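import numpy as np
import pytest

from perinexus.storm_rla import Cluster, voxelize


def grid_sphere(center, radius, spacing=5.0):
    """Deterministic dense sampling of a solid sphere (for voxel oracles)."""
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
    g = g[(g**2).sum(axis=1) <= radius**2]
    return g + np.asarray(center, dtype=float)


def make_cluster(points, cid=0, voxel_nm=10.0, dilation_nm=0.0):
    cl = Cluster(id=cid, point_indices=np.arange(len(points)), points_nm=np.asarray(points, float))
    voxelize(cl, voxel_nm=voxel_nm, dilation_nm=dilation_nm)
    return cl


@pytest.fixture(scope="session")
def storm_scene():
    """A medium synthetic STORM scene with misregistration, reused across tests."""
    from perinexus.synth import StormSceneConfig, gen_storm_scene

    cfg = StormSceneConfig(
        n_pairs=24,
        background_per_um3=1.0,
        misreg_rotation_z_deg=2.0,
        misreg_translation_nm=(50.0, -30.0, 10.0),
    )
    return cfg, gen_storm_scene(cfg, seed=7)
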