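#!/usr/bin/env python
"""Tiered miRNA conservation calls against the planted reference set.

Writes mirna_conservation.tsv; the summary reports the conserved fraction per tier.
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("mircons", __doc__)
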