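from __future__ import annotations

import numpy as np
import pytest

from vardesk.normalize import Reference
from vardesk.variants import Transcript


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160501)


@pytest.fixture()
def tiny_ref():
    #          1         11        21        31        41        51
    # pos:     123456789012345678901234567890123456789012345678901234567890
    seq = "GGTACACACATGGGGCTTTTACGATCGGATCCATGCTGAAGCGTACGTAGCTAGCTAGCA"
    return Reference({"chr1": seq})


@pytest.fixture(scope="session")
def repeat_ref():
    """A 400 bp reference rich in planted repeat tracts."""
    rng = np.random.default_rng(7)
    seq = list(rng.choice(list("ACGT"), size=400))

    def put(pos, s):  # 1-based
        seq[pos - 1 : pos - 1 + len(s)] = list(s)

    put(50, "T" + "CA" * 9 + "G")
    put(120, "C" + "T" * 10 + "G")
    put(200, "A" + "GAT" * 6 + "C")
    put(300, "G" + "AT" * 8 + "C")
    return Reference({"chr1": "".join(seq)})


@pytest.fixture(scope="session")
def plus_tx():
    """A + strand transcript: 3 exons, CDS from mid-exon1 to mid-exon3."""
    return Transcript("GENEP", "TX.P", "chr1", "+",
                      ((101, 160), (201, 260), (301, 360)), 121, 340)


@pytest.fixture(scope="session")
def minus_tx():
    return Transcript("GENEM", "TX.M", "chr1", "-",
                      ((101, 160), (201, 260), (301, 360)), 121, 340)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One shared small simulated run (kept session-scoped: it is read-only)."""
    from vardesk.synthfix import SimSpec, simulate_run

    out = tmp_path_factory.mktemp("simrun")
    return simulate_run(SimSpec(seed=11), out)
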