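"""Shared fixtures: the synthetic locus bundle, built once per session."""

from __future__ import annotations

import pytest

from regmap.pipeline import run_pipeline
from regmap.synth import DEFAULT_SEED, build_fixture, generate_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """In-memory validated bundle (self-checked at build time)."""
    return build_fixture(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk bundle written by the generator."""
    out = tmp_path_factory.mktemp("bundle")
    generate_paper_fixture(out, seed=DEFAULT_SEED)
    return out


@pytest.fixture(scope="session")
def pipeline_report(fixture_dir):
    """Full map report from one pipeline run over the on-disk bundle."""
    return run_pipeline(fixture_dir / "config.yaml")
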