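import time

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

PIPELINE_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full synthetic pipeline across five generator seeds (shared by the
    recovery checks); returns (results by seed, wall seconds per run)."""
    from gh19net.pipeline import run_synthetic_pipeline

    results, seconds = {}, {}
    for seed in PIPELINE_SEEDS:
        t0 = time.perf_counter()
        results[seed] = run_synthetic_pipeline(seed=seed)
        seconds[seed] = time.perf_counter() - t0
    return results, seconds


@pytest.fixture()
def toy_records():
    from gh19net.records import SequenceRecord

    return [
        SequenceRecord(id="a", residues="ACDEFGHIKLMNPQRSTVWY" * 3,
                       is_seed=True, activity_label="chitinase"),
        SequenceRecord(id="b", residues="ACDEFGHIKLMNPQRSTVWY" * 3),
        SequenceRecord(id="c", residues="MKLVWWYHHNQRST" * 5),
    ]
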