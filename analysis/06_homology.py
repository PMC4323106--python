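#!/usr/bin/env python
"""Proteome evolution, best-hit conservation matrix, jackknife incongruity test.

Writes conservation_matrix.tsv; the summary reports the jackknife p (flagged when it is a 1/reps bound).
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("homology", __doc__)
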