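"""Shared fixtures: one small and one default-size synthetic experiment,
plus full pipeline runs reused by the end-to-end tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from lightomics.pipeline import run_pipeline
from lightomics.simulate import SimulationConfig, simulate_all

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast, fully featured miniature of the default experiment."""
    params = dict(
        seed=seed,
        n_genes=24,
        n_te=10,
        planted_deg_frac=0.42,  # one gene per temporal archetype
        n_planted_dmrs=8,
        n_rddm_genes=2,
        n_extra_units=60,
        n_mirna_families=6,
        n_bins=8,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_exp():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def default_exp():
    """The default-size experiment (the study conditions)."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_runs(tmp_path_factory):
    """Full pipeline on the default config at two noisy seeds."""
    out = {}
    for seed in (1, 2):
        outdir = tmp_path_factory.mktemp(f"run_seed{seed}")
        summary = run_pipeline({}, outdir, seed=seed)
        out[seed] = (summary, outdir)
    return out


@pytest.fixture(scope="session")
def noise_controlled_run(tmp_path_factory):
    """Pipeline run where planted margins exceed every test threshold:
    background DMRs keep clear of genes and sRNA shifts are 8-fold."""
    outdir = tmp_path_factory.mktemp("run_nc")
    summary = run_pipeline(
        {"simulate": {"background_dmrs_at_degs": False, "srna_shift_fold": 8.0}},
        outdir,
        seed=1,
    )
    return summary, outdir
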