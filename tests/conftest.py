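import numpy as np
import pytest
from hypothesis import settings

from syndna import (
    SampleCounts,
    assign_pool,
    build_dilution_series,
    design_panel,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """Default 10-sequence spike-in panel (2,000 bp, 26–66% GC)."""
    return design_panel(seed=11)


@pytest.fixture(scope="session")
def series():
    """Five 10-fold dilutions: 1 down to 1e-4 ng/µL."""
    return build_dilution_series(1.0, 10.0, 5)


@pytest.fixture(scope="session")
def pool(panel, series):
    return assign_pool([r.id for r in panel], series, pool_id="pool1")


@pytest.fixture(scope="session")
def panel_gc(panel):
    return {r.id: r.realized_gc for r in panel}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


SAM_FIXTURE = "\n".join([
    "@HD\tVN:1.6\tSO:unknown",
    "@SQ\tSN:refA\tLN:300",
    "@SQ\tSN:refB\tLN:300",
    # three primary alignments to refA, read length 100, NM 1/2/0
    "r1\t0\trefA\t1\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:1",
    "r2\t0\trefA\t101\t60\t100M\t*\t0\t0\t" + "C" * 100 + "\t*\tNM:i:2",
    "r3\t16\trefA\t201\t60\t100M\t*\t0\t0\t" + "G" * 100 + "\t*\tNM:i:0",
    # secondary alignment: ignored entirely
    "r1\t256\trefB\t1\t0\t100M\t*\t0\t0\t*\t*\tNM:i:5",
    # two unmapped reads: total_reads only
    "r4\t4\t*\t0\t0\t*\t*\t0\t0\t" + "T" * 100 + "\t*",
    "r5\t4\t*\t0\t0\t*\t*\t0\t0\t" + "T" * 100 + "\t*",
]) + "\n"


@pytest.fixture
def sam_path(tmp_path):
    path = tmp_path / "toy.sam"
    path.write_text(SAM_FIXTURE)
    return path


@pytest.fixture
def toy_counts():
    """Hand-sized library: two taxa plus two spike-ins."""
    return SampleCounts(
        sample_id="toy",
        counts={"taxA": 400, "taxB": 100, "p126": 50, "p136": 5},
        total_reads=1000,
    )
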