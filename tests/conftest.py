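"""Shared fixtures: small array designs and a standard simulated experiment."""

import warnings

import pytest

from pbmeta.design import make_debruijn_design

warnings.filterwarnings("ignore", category=UserWarning, module="pbmeta")


@pytest.fixture(scope="session")
def design8():
    """Order-8 design: 6-mer features, 2080 RC-collapsed k-mers, 4096 probes."""
    return make_debruijn_design(order=8, variable_length=23, seed=0)


@pytest.fixture(scope="session")
def design6():
    """Order-6 design: 4-mer features, 136 RC-collapsed k-mers."""
    return make_debruijn_design(order=6, variable_length=13, seed=0)


@pytest.fixture(scope="session")
def run_cfg8():
    from pbmeta.pipeline import RunConfig

    return RunConfig(design_order=8, variable_length=23)


@pytest.fixture(scope="session")
def loss_result(design8, run_cfg8):
    """One calibrated pipeline run with a planted uniform 0.5x affinity loss."""
    from pbmeta.pipeline import simulated_run
    from pbmeta.simulate import standard_experiment

    truths, layout, sim = standard_experiment(design8, "loss", motif_seed=12, sim_seed=101)
    return simulated_run(design8, truths, layout, sim, run_cfg8), truths


@pytest.fixture(scope="session")
def null_result(design8, run_cfg8):
    """One calibrated pipeline run with no planted effect."""
    from pbmeta.pipeline import simulated_run
    from pbmeta.simulate import standard_experiment

    truths, layout, sim = standard_experiment(design8, None, motif_seed=12, sim_seed=202)
    return simulated_run(design8, truths, layout, sim, run_cfg8), truths
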