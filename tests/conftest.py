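import pytest

from svcall.alignments import InsertSizeModel, estimate_insert_model
from svcall.simulate import Scenario, SVSpec, simulate_scenario


@pytest.fixture(scope="session")
def fr_model():
    """A fixed FR paired-end insert model: median 3000, sigma 300, k=3."""
    return InsertSizeModel(
        median_is=3000.0, sigma_is=300.0, expected_orientation="FR",
        k_discordant=3.0, n_pairs_sampled=10_000,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulation with one SV of each class (RF mate-pair, 10x)."""
    sc = Scenario(
        chrom_lengths=(300_000, 300_000),
        specs=(
            SVSpec("DEL", "chr1", 60_000, 10_000),
            SVSpec("DUP", "chr1", 150_000, 10_000, copies=1),
            SVSpec("INV", "chr2", 60_000, 12_000),
            SVSpec("INS", "chr2", 150_000, 1_500),
            SVSpec("TRA", "chr1", 250_000, chrom2="chr2", pos2=200_000),
        ),
        coverage=10.0,
    )
    return simulate_scenario(sc, seed=42)


@pytest.fixture(scope="session")
def small_sim_model(small_sim):
    return estimate_insert_model(small_sim.records)


@pytest.fixture(scope="session")
def null_sim():
    """SV-free simulation (reads from the unmodified reference)."""
    sc = Scenario(chrom_lengths=(400_000,), specs=(), coverage=10.0)
    return simulate_scenario(sc, seed=7)


@pytest.fixture(scope="session")
def seq_sim():
    """Simulation with read sequences attached, for realignment tests."""
    sc = Scenario(
        chrom_lengths=(300_000,),
        specs=(SVSpec("DEL", "chr1", 80_000, 10_000),
               SVSpec("INV", "chr1", 180_000, 12_000)),
        coverage=8.0,
    )
    return simulate_scenario(sc, seed=5, with_seqs=True)
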