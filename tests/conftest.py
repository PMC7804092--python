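import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from concerted.simulate import ReadSet, RepeatArrayGenome, SimConfig


@pytest.fixture
def tiny_cfg() -> SimConfig:
    """Small, fast configuration for unit tests (not the study conditions)."""
    return SimConfig(
        n_lineages=3, n_generations=200, repeat_len=60,
        copy_number_init=40, copy_number_bounds=(10, 80),
        mu=1e-5, gc_rate=0.1, uco_rate=0.1, uco_block=4,
        seq_error=1e-3, reads_per_strain=500, env_total_reads=1200,
        n_months=12, seed=11,
    )


@pytest.fixture
def two_copy_genome() -> RepeatArrayGenome:
    return RepeatArrayGenome(copies=["ACGTACGT", "ACGTACGA"], lineage_id="g0")


def make_reads(seq_counts: dict[str, int], sample_id: str = "s1",
               month: int | None = None) -> ReadSet:
    """Expand a {sequence: count} dict into a ReadSet."""
    seqs, samples, months = [], [], []
    for seq, n in seq_counts.items():
        seqs.extend([seq] * n)
        samples.extend([sample_id] * n)
        months.extend([month] * n)
    if month is None:
        return ReadSet(sequences=seqs, sample_ids=samples, provenance="strain")
    return ReadSet(sequences=seqs, sample_ids=samples,
                   provenance="environmental", month_index=months)
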