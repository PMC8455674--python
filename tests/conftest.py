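import dataclasses

import numpy as np
import pytest

from mrkit import HarmonizedInstrumentSet, ScenarioConfig, generate_instrument_set


def rep_seeds(master: int, n: int) -> list[int]:
    """Independent 31-bit per-replicate seeds derived from one master seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(master).spawn(n)]


def random_instrument_set(rng: np.random.Generator, J: int) -> HarmonizedInstrumentSet:
    """An arbitrary (not necessarily realistic) instrument set for oracle tests."""
    return HarmonizedInstrumentSet(
        rsids=[f"rs{i}" for i in range(J)],
        gamma_hat=rng.uniform(-0.5, 0.5, J) + np.where(rng.random(J) < 0.5, 0.05, -0.05),
        sigma_x=rng.uniform(0.001, 0.05, J),
        Gamma_hat=rng.normal(0, 0.1, J),
        sigma_y=rng.uniform(0.005, 0.1, J),
    )


def replicate_sets(config: ScenarioConfig, master: int, n_reps: int):
    """Yield (instrument set, truth) replicates of one scenario."""
    for seed in rep_seeds(master, n_reps):
        yield generate_instrument_set(dataclasses.replace(config, seed=seed))


@pytest.fixture
def toy_summary_file(tmp_path):
    """A minimal 3-row canonical-format summary-statistics file."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"
        "rs1\tA\tG\t0.3\t0.10\t0.01\t1e-23\n"
        "rs2\tT\tC\t0.4\t-0.08\t0.01\t1.3e-15\n"
        "rs3\tC\tA\t0.2\t0.05\t0.01\t5.7e-7\n"
    )
    return path
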