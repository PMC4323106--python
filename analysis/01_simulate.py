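#!/usr/bin/env python
"""Generate the synthetic genome, annotations, truth table and both protocol libraries.

Writes genome.fa, repeats.bed, library_5p_{dependent,independent}.fa and the per-read truth table under --out-dir.
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("simulate", __doc__)
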