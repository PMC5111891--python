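import numpy as np
import pytest

from plastcomp import GenomeSpec, MutationSpec, generate_plastome, mutate_genome

# a compact pair that still exercises every event class
SMALL_GENOME = dict(
    lsc_len=20_000, ir_len=4_000, ssc_len=6_000, n_genes=12, intron_genes=3
)


@pytest.fixture(scope="session")
def small_pair():
    """One deterministic synthetic pair with full planted truth."""
    genome, features, gen_truth = generate_plastome(
        GenomeSpec(**SMALL_GENOME, seed=7)
    )
    mutated, truth = mutate_genome(genome, features, MutationSpec(seed=8))
    return {
        "genome": genome,
        "features": features,
        "gen_truth": gen_truth,
        "mutated": mutated,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
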