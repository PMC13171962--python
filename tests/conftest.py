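import pytest

from asval import run_qc
from asval.synthetic import fixture_configs, simulate_run


def passing_segments(run):
    """Classify + Q10-filter a simulated run, return (records, segments)."""
    records = run_qc.quality_filter(run_qc.classify_reads(run.records))
    keep = {r.read_id for r in records}
    return records, [s for s in run.segments if s.read_id in keep]


@pytest.fixture(scope="session")
def fixture_runs():
    """The canonical fixture simulations, shared across the suite."""
    return {name: simulate_run(cfg) for name, cfg in fixture_configs(seed=11).items()}


@pytest.fixture(scope="session")
def fixture_cfgs():
    return fixture_configs(seed=11)
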