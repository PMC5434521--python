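import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from scaffoldphase import SimConfig, simulate_population


@pytest.fixture(scope="session")
def tiny_population():
    """Small error-free population shared across tests (cheap, deterministic)."""
    cfg = SimConfig(
        n_founder_haplotypes=12,
        n_founders=8,
        n_generations=3,
        offspring_per_mating=2,
        chrom_length_bp=20_000_000,
        n_dense_markers=300,
        n_scaffold_markers=30,
        seed=42,
    )
    return cfg, simulate_population(cfg)


@pytest.fixture(scope="session")
def noisy_population():
    """Same scale with 1% genotyping error."""
    cfg = SimConfig(
        n_founder_haplotypes=12,
        n_founders=8,
        n_generations=3,
        offspring_per_mating=2,
        chrom_length_bp=20_000_000,
        n_dense_markers=300,
        n_scaffold_markers=30,
        genotype_error_rate=0.01,
        seed=43,
    )
    return cfg, simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def block_flipper():
    """Pre-phase generator: truth with random whole-block orientation flips."""

    def flip_blocks(truth_alleles, rng, n_switch=2):
        out = truth_alleles.copy()
        n, m, _ = out.shape
        cuts_all = []
        for i in range(n):
            cuts = np.sort(rng.choice(np.arange(1, m), size=n_switch, replace=False))
            state = rng.integers(0, 2)
            bounds = np.concatenate([[0], cuts, [m]])
            for b in range(len(bounds) - 1):
                if (state + b) % 2 == 1:
                    sl = slice(bounds[b], bounds[b + 1])
                    out[i, sl] = out[i, sl, ::-1]
            cuts_all.append(cuts)
        return out, cuts_all

    return flip_blocks
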