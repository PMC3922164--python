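import pytest

from waspdom.synthdata import (
    SimConfig,
    make_loop_design,
    simulate_chc,
    simulate_microarray,
    simulate_ortholog_lists,
)
from waspdom import preprocess


@pytest.fixture(scope="session")
def array_sim_small():
    """A small but complete loop-design microarray simulation."""
    cfg = SimConfig(n_transcripts=120, frac_de=0.15, effect_size=1.5, seed=101)
    spots, samples, truth = simulate_microarray(cfg)
    design = make_loop_design(samples["sample"])
    return cfg, spots, samples, design, truth


@pytest.fixture(scope="session")
def expr_small(array_sim_small):
    cfg, spots, samples, design, truth = array_sim_small
    expr = preprocess.preprocess_pipeline(spots, design, samples)
    return expr, truth


@pytest.fixture(scope="session")
def chc_sim():
    cfg = SimConfig(seed=202)
    table, samples, truth, metadata = simulate_chc(cfg)
    return cfg, table, samples, truth, metadata


@pytest.fixture(scope="session")
def overlap_sim():
    cfg = SimConfig(universe_size=300, n_sig_focal=40, n_sig_other=50,
                    odds_ratio=1.0, seed=303)
    return cfg, simulate_ortholog_lists(cfg)
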