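import pytest

from tregmeth.synthdata import SimDesign, default_planted, simulate_manifest, simulate_timecourse


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(
        n_probes=1500,
        n_chromosomes=3,
        planted_dmrs=default_planted(6),
        tregdr_count=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_design):
    return simulate_manifest(small_design)


@pytest.fixture(scope="session")
def small_dataset(small_design, small_world):
    matrix, sheet, truth = simulate_timecourse(small_design, small_world)
    return matrix, sheet, truth
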