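import random

import pytest

from ptgr.assembly import Design, GeneSpec, TuSpec
from ptgr.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def fixture_set():
    return generate_fixtures(42)


@pytest.fixture(scope="session")
def registry(fixture_set):
    return fixture_set[0]


@pytest.fixture(scope="session")
def backbone(fixture_set):
    return fixture_set[1]


@pytest.fixture(scope="session")
def operon_design():
    """Dual-reporter operon: tac promoter, sod RBS x2, mCherry then eGFP."""
    return Design(
        "operon2",
        (TuSpec("tac", (GeneSpec("sod_rbs", "mCherry"), GeneSpec("sod_rbs", "eGFP"))),),
        "pGA1",
    )


@pytest.fixture(scope="session")
def cluster_design():
    """Two transcriptional units: tac-eGFP then sod-mCherry."""
    return Design(
        "cluster2",
        (
            TuSpec("tac", (GeneSpec("sod_rbs", "eGFP"),)),
            TuSpec("sod", (GeneSpec("sod_rbs", "mCherry"),)),
        ),
        "pGA1",
    )


def random_plasmid_seq(rng: random.Random, length: int, sites: list[str]) -> str:
    """Random circular top strand with the given recognitions planted apart."""
    seq = [rng.choice("ACGT") for _ in range(length)]
    slot = max(1, length // max(1, len(sites)))
    for i, rec in enumerate(sites):
        pos = (i * slot + rng.randrange(max(1, slot - len(rec)))) % (length - len(rec))
        seq[pos : pos + len(rec)] = list(rec)
    return "".join(seq)
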