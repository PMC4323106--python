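#!/usr/bin/env python
"""piRNA signatures: upstream motif discovery, genomic clustering, ping-pong overlap histogram.

Writes motif_pwm.tsv, clusters.bedgraph and pingpong_histogram.tsv; the summary reports the motif consensus, flagged cluster fraction, ping-pong z-score and position-10 A fraction.
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("pirna", __doc__)
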