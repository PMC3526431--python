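import hashlib

import pytest

from tigerasm.fixtures import standard_fixture
from tigerasm.pipeline import run_tiger
from tigerasm.seq_io import ContigSet


def assembly_digest(contigs: ContigSet) -> str:
    """Order-independent digest of an assembly's sequence content up to
    reverse complement (contig ids and output order are irrelevant)."""
    from tigerasm._dna import canonical

    seqs = sorted(canonical(c.sequence) for c in contigs)
    return hashlib.sha256("\n".join(seqs).encode()).hexdigest()


@pytest.fixture(scope="session")
def standard_conditions():
    """The standard synthetic study conditions (genome, reads, config)."""
    genome, repeat_truth, reads, read_truth, config = standard_fixture(seed=7)
    return {
        "genome": genome,
        "repeat_truth": repeat_truth,
        "reads": reads,
        "read_truth": read_truth,
        "config": config,
    }


@pytest.fixture(scope="session")
def standard_run(standard_conditions):
    """One serial pipeline run on the standard conditions, shared by the
    pipeline-level tests (the run is deterministic, so sharing is safe)."""
    sc = standard_conditions
    result = run_tiger(sc["config"], sc["reads"], reference=sc["genome"])
    return result
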