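#!/usr/bin/env python
"""Bisulfite table simulation, repeat methylation enrichment, sRNA-gene association.

Writes methylation.tsv and methylation_enrichment.tsv; the summary reports per-class enrichment p-values and the Mann-Whitney p for sRNA density at methylated genes.
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("meth", __doc__)
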