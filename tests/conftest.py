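import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from autozyg.report import PipelineConfig, run_pipeline
from autozyg.simulate import BreedingDesign, Genome, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One full default-design breeding simulation, shared across tests."""
    return simulate(BreedingDesign(), seed=1)


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Full pipeline on the default synthetic design (no files written)."""
    import warnings

    cfg = PipelineConfig(seed=1, make_figures=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg, out_dir=None, sim=default_sim)


@pytest.fixture(scope="session")
def pooled_ibd_regression(default_sim):
    """Pedigree-F vs realised-IBD regression pooled over replicate runs.

    The default genome is only ~0.5 Morgans, so a single replicate's
    realised autozygosity carries large Monte-Carlo error (slope sd ~0.09
    across seeds); pooling a fixed set of replicates estimates the slope
    within Monte-Carlo error. Seed 1 reuses the shared simulation.
    """
    from autozyg import pedigree as pm

    xs, ys = [], []
    for seed in range(5):
        sim = default_sim if seed == 1 else simulate(BreedingDesign(), seed=seed)
        ped = pm.validate_pedigree(sim.pedigree)
        F = pm.inbreeding_meuwissen_luo(ped)
        xs.append(F.reindex(sim.truth.index).to_numpy())
        ys.append(sim.truth["autozygosity_ibd"].to_numpy())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


@pytest.fixture()
def small_design():
    """A fast, reduced-census design for smoke/determinism tests."""
    return BreedingDesign(
        burn_in_generations=6,
        random_generations=2,
        random_males=6,
        random_females=12,
        founder_pool_size=18,
        random_offspring=44,
        selection_generations=5,
        dams_per_line=6,
        sires_per_line=3,
        litter_size=4,
        avoid_shared_grandparents=False,
        genome=Genome(n_chromosomes=2, snps_per_chromosome=300, chrom_span_bp=3_000_000),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
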