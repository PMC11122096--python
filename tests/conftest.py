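import pytest

from oncosim import (
    StoichiometricModel,
    VirtualTumorParameters,
    VoxelGrid,
    fixture_path,
    make_phantom,
)


@pytest.fixture(scope="session")
def toy_model() -> StoichiometricModel:
    return StoichiometricModel.from_tsv(fixture_path("toy_warburg.tsv"))


@pytest.fixture()
def params() -> VirtualTumorParameters:
    # small hierarchy keeps the compartment index compact in unit tests
    return VirtualTumorParameters(
        T_c=24.0, T_G0=96.0, T_A=12.0, T_N=48.0, N_LIMP=3,
        R_A=1e-4, R_ADiff=4e-3, R_NDiff=4e-3,
        P_sym=0.3, P_sleep=0.2, P_G0toG1=0.1, dt=2.0,
    )


@pytest.fixture()
def small_phantom(params):
    index = params.build_index()
    grid = VoxelGrid(7, 7, 7, voxel_edge_mm=1.0)
    state, labels = make_phantom(grid, index, (3.5, 3.5, 3.5), 2.5, {"G1": 1.0})
    return state, labels, grid, index
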