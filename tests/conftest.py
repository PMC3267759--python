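from __future__ import annotations

import pytest

from carpmir.pipeline import RunConfig, run_pipeline
from carpmir.simulate import SimulationConfig, generate_genome, make_ncrna_reference


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared by generator-level tests."""
    cfg = SimulationConfig(total_reads=20_000, seed=5)
    genome, hairpins, _ = generate_genome(cfg)
    return cfg, genome, hairpins, make_ncrna_reference(cfg.seed)


@pytest.fixture(scope="session")
def full_run():
    """One full-scale pipeline run (20 hairpins, 10^5 reads) shared by the
    end-to-end recovery checks."""
    cfg = RunConfig(
        simulation=SimulationConfig(n_hairpins=20, total_reads=100_000, seed=42),
        outdir="unused",
    )
    return cfg, run_pipeline(cfg, write=False)
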