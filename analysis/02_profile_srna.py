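#!/usr/bin/env python
"""Length x first-nucleotide profiles and 5'-triphosphate inference by protocol differencing.

Writes profile_5p_{dependent,independent}.tsv; the summary reports whether a triphosphate population is present and its modal length.
"""

from common import run_stage

if __name__ == "__main__":
    run_stage("profile", __doc__)
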