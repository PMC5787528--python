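import pytest

from cacsomatic.calling import CallerThresholds, run_caller
from cacsomatic.simulate import (SimConfig, generate_reference,
                                 simulate_cohort, score_against_truth)

SMALL_PANEL = [("GENE1", "chrS", 101, 220), ("GENE2", "chrS", 401, 520),
               ("GENE3", "chrS", 701, 820)]


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 6-sample cohort for unit-level caller checks."""
    cfg = SimConfig(n_samples=6, ref_length=1000, panel=tuple(SMALL_PANEL),
                    depth_mean=100.0, recurrent_artifact_n_samples=6,
                    somatic_rate_per_gene=0.5, seed=11)
    ref = generate_reference(cfg.ref_length, cfg.gc_fraction, seed=11)
    obs, truth = simulate_cohort(cfg, ref)
    return cfg, ref, obs, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-sample, depth-150 synthetic cohort."""
    cfg = SimConfig(seed=0)
    ref = generate_reference(cfg.ref_length, cfg.gc_fraction, seed=cfg.seed)
    obs, truth = simulate_cohort(cfg, ref)
    return cfg, ref, obs, truth


@pytest.fixture(scope="session")
def default_cohort_result(default_cohort):
    cfg, ref, obs, truth = default_cohort
    result = run_caller(obs, {truth.contig: ref}, truth.mini_dbsnp,
                        CallerThresholds(), panel=truth.panel)
    return result


@pytest.fixture(scope="session")
def default_cohort_score(default_cohort, default_cohort_result):
    _, _, _, truth = default_cohort
    return score_against_truth(truth, default_cohort_result)
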