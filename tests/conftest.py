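import warnings

import pytest

from ctdna_mpnst import GeneRegistry, SimConfig, analyze_cohort, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return GeneRegistry.default()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped synthetic cohort: 12 healthy + 44 PN + 44 MPNST cfDNA,
    19 tumors, 12-sample background panel."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full pipeline run on the default cohort (CI skipped for speed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(default_cohort, seed=11, n_boot=None)


def small_config(seed=0, **overrides):
    """A scaled-down cohort for repeated-simulation tests."""
    defaults = dict(
        seed=seed,
        n_healthy=6,
        n_pn=10,
        n_mpnst_patients=10,
        n_mpnst_cfdna=14,
        n_tumors=4,
        panel_size=6,
        n_offtarget_bins=60,
        scripted_mrd=False,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
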