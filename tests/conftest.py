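"""Shared fixtures: a small synthetic lane reused across test modules."""

import pytest

from tagtally.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_lane(tmp_path_factory):
    """A small multiplexed lane with errors, adapters and chimeras planted."""
    spec = FixtureSpec(
        n_samples=8,
        n_markers=40,
        seed=1234,
        reads_per_cell_mean=3.0,
        error_rate=0.005,
        adapter_readthrough_fraction=0.1,
        chimera_fraction=0.05,
    )
    outdir = tmp_path_factory.mktemp("small_lane")
    return generate_fixture(spec, outdir)


@pytest.fixture(scope="session")
def clean_lane(tmp_path_factory):
    """A small error-free lane: counts must reproduce truth exactly."""
    spec = FixtureSpec(
        n_samples=6,
        n_markers=25,
        seed=99,
        reads_per_cell_mean=2.0,
        error_rate=0.0,
        adapter_readthrough_fraction=0.0,
        chimera_fraction=0.0,
    )
    outdir = tmp_path_factory.mktemp("clean_lane")
    return generate_fixture(spec, outdir)
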