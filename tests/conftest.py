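import pytest

from ionmut import synthetic_data as sd
from ionmut.genome import generate_genome

# nuisance parameters that keep simulated DP/AF safely inside the
# 10 <= DP <= 100, AF >= 0.25 filter window, so "zero caller error"
# scenarios really are error-free end to end
TIGHT = dict(depth_mean=55.0, depth_dispersion=400.0, af_noise_sd=0.02)

CALLERS = ("gatk", "samtools", "varscan")


@pytest.fixture(scope="session")
def toy_genome():
    """Two 300-kb chromosomes with ~12 genes each, deterministic."""
    genome, genes = generate_genome(n_chrom=2, chrom_len=300_000, gene_density=40e-6, seed=5)
    return genome, genes


@pytest.fixture(scope="session")
def cohort_truth(toy_genome):
    """Six mutant samples + control, 40 induced each, 50 shared background."""
    genome, _ = toy_genome
    return sd.generate_truth(
        genome, n_samples=6, n_induced=40, n_background=50, include_control=True, seed=9
    )


@pytest.fixture(scope="session")
def zero_error_profiles():
    return [sd.CallerProfile(c, fn_rate=0.0, fp_rate_per_mb=0.0, **TIGHT) for c in CALLERS]


@pytest.fixture(scope="session")
def zero_error_callsets(toy_genome, cohort_truth, zero_error_profiles):
    genome, _ = toy_genome
    return {
        t.sample_id: sd.simulate_caller_calls(t, zero_error_profiles, genome, seed=100 + i)
        for i, t in enumerate(cohort_truth)
    }
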