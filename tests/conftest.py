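import numpy as np
import pytest

from grescan import synthetic as syn


@pytest.fixture(scope="session")
def motif_set():
    """The package's synthetic GRE motif models (full, degenerate, half)."""
    return syn.default_motif_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def planted_sites_200_per_class():
    """800 noise-free planted sites, 200 per four-way class, fixed seed."""
    spec = syn.SyntheticSpec(
        genome_length=600_000,
        n_sites_per_class={
            "C1": {"full_only": 200, "half_only": 200, "both": 200, "none": 200}
        },
        overlap_fraction=0.0,
        motif_mutation_rate=0.0,
        seed=42,
    )
    genome = syn.gen_genome(spec)
    peaks, truth, genome = syn.plant_sites(genome, spec)
    return spec, peaks, truth, genome
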