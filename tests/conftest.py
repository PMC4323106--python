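"""Shared synthetic fixtures, sized for fast test runs.

The session-scoped fixtures build one small clade-V world (genome +
both protocol libraries + alignments) reused across test modules.
"""

import pytest

from nemasrna import sio, synth

SEED = 11
N_READS = 40_000


@pytest.fixture(scope="session")
def clade_v_config():
    return synth.clade_v_config(seed=SEED)


@pytest.fixture(scope="session")
def clade_v_genome(clade_v_config):
    return synth.make_genome(clade_v_config, n_contigs=2, contig_length=50_000)


@pytest.fixture(scope="session")
def clade_v_libs(clade_v_genome, clade_v_config):
    """(dependent library, its truth), (independent library, its truth)."""
    dep = synth.simulate_library(
        clade_v_genome, clade_v_config,
        sio.LibraryProtocol(five_prime_dependent=True), N_READS,
    )
    indep = synth.simulate_library(
        clade_v_genome, clade_v_config,
        sio.LibraryProtocol(five_prime_dependent=False), N_READS,
    )
    return dep, indep


@pytest.fixture(scope="session")
def aln_indep(clade_v_genome, clade_v_libs):
    (_, _), (lib_indep, _) = clade_v_libs
    return sio.align_exact(sio.trim_filter(lib_indep), clade_v_genome)
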