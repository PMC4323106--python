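#!/usr/bin/env python
"""Transposon siRNA statistics: repeat assignment, strand bias, Dicer overhang signature.

Writes strand_counts.tsv and overhang_histogram.tsv; the summary reports the strand-bias chi-squared and the modal 3' overhang.
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("tesirna", __doc__)
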