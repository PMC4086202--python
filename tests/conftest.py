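import numpy as np
import pandas as pd
import pytest

from costnet.simulate import RTModel, SimConfig, generate_cohort


def tiny_roi_frame() -> pd.DataFrame:
    """8-node registry: 2 cortical communities + 3 subcortical ROIs."""
    rows = [
        ("CtxA1", 0, 0, 0, "synthetic", 0),
        ("CtxA2", 10, 0, 0, "synthetic", 0),
        ("CtxA3", 20, 0, 0, "synthetic", 0),
        ("CtxB1", 0, 20, 0, "synthetic", 0),
        ("CtxB2", 10, 20, 0, "synthetic", 0),
        ("PutL", 0, 40, 0, "synthetic", 1),
        ("CaudL", 10, 40, 0, "synthetic", 1),
        ("ThalL", 20, 40, 0, "synthetic", 1),
    ]
    return pd.DataFrame(
        rows, columns=["name", "x", "y", "z", "category", "subcortical"]
    )


TINY_ASSIGNMENT = {
    "CtxA1": "a",
    "CtxA2": "a",
    "CtxA3": "a",
    "CtxB1": "b",
    "CtxB2": "b",
    "PutL": "sub",
    "CaudL": "sub",
    "ThalL": "sub",
}


@pytest.fixture
def tiny_roi_table() -> pd.DataFrame:
    return tiny_roi_frame()


def tiny_sim_config(**overrides) -> SimConfig:
    """A fast, small cohort on the 8-node registry."""
    defaults = dict(
        n_subjects_group1=6,
        n_subjects_group2=6,
        n_runs=1,
        frames_per_run=50,
        tr_seconds=3.5,
        roi_table=tiny_roi_frame(),
        module_assignment=dict(TINY_ASSIGNMENT),
        attenuated_edges=(("CtxA1", "CtxB1"),),
        rt_model=RTModel(
            dlpfc_edge=("CtxA2", "PutL"), vlpfc_edge=("CtxB2", "CaudL")
        ),
        block_len_frames=8,
        rest_frames=2,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the full default cohort (62 ROIs, 14 vs 12)."""
    return generate_cohort(SimConfig(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
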