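import dataclasses

import numpy as np
import pandas as pd
import pytest

from zrpage import SampleDesign, SimConfig, simulate_experiment, zscore_normalize


def small_config(**overrides) -> SimConfig:
    """Desk-scale variant of the default four-group, n=3 design."""
    base = dict(n_genes=300, n_sets=15, set_size_range=(5, 15), seed=7)
    base.update(overrides)
    return dataclasses.replace(SimConfig(), **base)


def null_config(**overrides) -> SimConfig:
    return small_config(
        frac_strain_de=0.0, frac_treatment_de=0.0, frac_interaction_de=0.0,
        frac_coherent_sets=0.0, **overrides,
    )


@pytest.fixture(scope="session")
def sim():
    """A small simulated experiment with planted effects and coherent sets."""
    return simulate_experiment(small_config())


@pytest.fixture(scope="session")
def zmatrix(sim):
    return zscore_normalize(sim.raw)


@pytest.fixture()
def two_group_design():
    return SampleDesign(
        assignments={
            "E_1": "EXP", "E_2": "EXP", "E_3": "EXP",
            "C_1": "CTRL", "C_2": "CTRL", "C_3": "CTRL",
        }
    )


def random_zmatrix(n_genes: int, design: SampleDesign, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, len(design.sample_ids))),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=list(design.sample_ids),
    )
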