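import csv
from pathlib import Path

import pytest

from polyanno import pipeline
from polyanno.config import PipelineConfig
from polyanno.simulate import SCENARIOS, generate_scenario, make_spec

DATA_DIR = Path(__file__).parent / "data"

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def table_rows():
    """Published annotation-table rows whose printed coverage is verified."""
    with open(DATA_DIR / "annotation_tables.tsv") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@pytest.fixture(scope="session")
def scenario_dirs(tmp_path_factory):
    base = tmp_path_factory.mktemp("scenarios")
    dirs = {}
    for name in SCENARIOS:
        d = base / name
        generate_scenario(make_spec(name, seed=FIXTURE_SEED), d)
        dirs[name] = d
    return dirs


@pytest.fixture(scope="session")
def scenario_results(scenario_dirs):
    """Default-config pipeline results per scenario (computed once)."""
    results = {}
    for name, d in scenario_dirs.items():
        data = pipeline.load_scenario(d)
        results[name] = (data, pipeline.annotate(data, PipelineConfig()))
    return results
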