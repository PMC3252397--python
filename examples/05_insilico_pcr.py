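"""Exact-match in-silico PCR with the published qRT-PCR primer pairs.

Without the (non-redistributed) genome, templates are synthesized to
carry each primer pair at its published product size, demonstrating
specificity checking and amplicon sizing.
"""

import numpy as np

from shspkit import find_amplicon, reverse_complement
from shspkit.published import PRIMER_PAIRS
from shspkit.sequences import SequenceRecord

rng = np.random.default_rng(0)
for locus, pair in PRIMER_PAIRS.items():
    filler = pair.expected_amplicon_bp - len(pair.forward) - len(pair.reverse)
    template = SequenceRecord(
        id=locus,
        seq="".join(rng.choice(list("ACGT"), 40)) + pair.forward
        + "".join(rng.choice(list("ACGT"), filler))
        + reverse_complement(pair.reverse) + "".join(rng.choice(list("ACGT"), 40)),
    )
    bp = find_amplicon(template, pair)
    print(f"{locus}: amplicon {bp} bp (published {pair.expected_amplicon_bp} bp)")
# find_amplicon searches both strands, requires exact primer matches, and
# raises if a pair would produce more than one product (non-specificity).
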