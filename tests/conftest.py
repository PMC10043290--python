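"""Shared fixtures: one synthetic fixture bundle and one pair of pipeline
runs per session, reused by the pipeline and acceptance tests."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from fatebarrier import synthetic_data as syn
from fatebarrier.pipeline import default_config, run_pipeline

SESSION_SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("fixtures")
    syn.simulate(d, seed=SESSION_SEED)
    return d


@pytest.fixture(scope="session")
def truth(fixture_dir) -> dict:
    with open(fixture_dir / "truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def pipeline_runs(fixture_dir, tmp_path_factory):
    """Two complete pipeline runs on the same fixtures and seed; returns
    (summary dict, summary.json text of run 1, summary.json text of run 2)."""
    out1 = tmp_path_factory.mktemp("run1")
    out2 = tmp_path_factory.mktemp("run2")
    summary = run_pipeline(default_config(fixture_dir, seed=SESSION_SEED), out1)
    run_pipeline(default_config(fixture_dir, seed=SESSION_SEED), out2)
    return summary, (out1 / "summary.json").read_text(), (out2 / "summary.json").read_text()
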