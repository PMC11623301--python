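"""Flag RIP-like hypermutation in an element copy with dinucleotide indices.

Repeat-induced point mutation (C->T in CpA context and the strand-symmetric
G->A in TpG) depletes CpA/TpG and enriches TpA; an affected ("derelict")
element copy shows a raised product index and a lowered substrate index.
"""

import numpy as np

from starscreen import apply_rip, rip_indices

rng = np.random.default_rng(13)
element = "".join(rng.choice(list("ACGT"), size=20_000))
derelict = apply_rip(element, fraction=0.4, seed=13)


def summarize(label, seq):
    profile = rip_indices(seq, window=2000, step=1000)
    product = np.mean([w.product_index for w in profile.windows if w.product_index])
    substrate = np.mean([w.substrate_index for w in profile.windows if w.substrate_index])
    flagged = sum(w.flagged() for w in profile.windows)
    print(
        f"{label}: product {product:.3f}, substrate {substrate:.3f}, "
        f"{flagged}/{len(profile.windows)} windows flagged"
    )


summarize("intact copy  ", element)
summarize("derelict copy", derelict)

# An intact copy sits near product ~1 / substrate ~1; the RIP-mutated copy
# crosses the conventional product > 1.1 and substrate < 0.9 heuristics.
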