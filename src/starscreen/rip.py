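"""Dinucleotide indices for flagging RIP-like hypermutation.

Repeat-induced point mutation (RIP) is a fungal genome-defense process
that converts C to T preferentially in CpA context (and symmetrically G
to A in TpG context on the forward strand). Affected element copies —
immobilized "derelicts" — show depleted CpA/TpG and enriched TpA. The
standard composite indices quantify this per window:

* product index   = f(TpA) / f(ApT)                (rises under RIP)
* substrate index = (f(CpA)+f(TpG)) / (f(ApC)+f(GpT))  (falls under RIP)
* composite       = product - substrate

Windows whose denominator is zero carry ``None`` rather than a
fabricated value. The conventional flagging heuristics (product > 1.1
and substrate < 0.9) are exposed but not applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Optional

import numpy as np

PRODUCT_FLAG_THRESHOLD = 1.1
SUBSTRATE_FLAG_THRESHOLD = 0.9

ALL_DINUCLEOTIDES = tuple("".join(p) for p in _iterproduct("ACGT", repeat=2))


@dataclass(frozen=True)
class RIPWindow:
    start: int
    end: int
    product_index: Optional[float]
    substrate_index: Optional[float]
    composite: Optional[float]

    def flagged(
        self,
        product_threshold: float = PRODUCT_FLAG_THRESHOLD,
        substrate_threshold: float = SUBSTRATE_FLAG_THRESHOLD,
    ) -> bool:
        return (
            self.product_index is not None
            and self.substrate_index is not None
            and self.product_index > product_threshold
            and self.substrate_index < substrate_threshold
        )


@dataclass(frozen=True)
class RIPProfile:
    seq_id: str
    windows: tuple[RIPWindow, ...]
    window: int
    step: int


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Overlapping dinucleotide counts; windows containing N are skipped."""
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    counts = dict.fromkeys(ALL_DINUCLEOTIDES, 0)
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        if "N" not in dinuc:
            counts[dinuc] += 1
    return counts


def _indices(counts: dict[str, int]) -> tuple[Optional[float], Optional[float], Optional[float]]:
    product = counts["TA"] / counts["AT"] if counts["AT"] else None
    sub_den = counts["AC"] + counts["GT"]
    substrate = (counts["CA"] + counts["TG"]) / sub_den if sub_den else None
    composite = product - substrate if product is not None and substrate is not None else None
    return product, substrate, composite


def rip_indices(seq: str, window: int = 1000, step: int = 500, seq_id: str = "seq") -> RIPProfile:
    """Sliding-window RIP indices; a window longer than the sequence collapses
    to a single whole-sequence window."""
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window >= len(seq):
        starts = [0]
        window_eff = len(seq)
    else:
        starts = list(range(0, len(seq) - window + 1, step))
        window_eff = window
    windows = []
    for s in starts:
        counts = dinucleotide_counts(seq[s : s + window_eff])
        product, substrate, composite = _indices(counts)
        windows.append(RIPWindow(s, s + window_eff, product, substrate, composite))
    return RIPProfile(seq_id=seq_id, windows=tuple(windows), window=window_eff, step=step)


def apply_rip(seq: str, fraction: float, seed: int = 0) -> str:
    """Simulate RIP-type transitions: C->T at a fraction of CpA sites and
    G->A at the same fraction of TpG sites (strand-symmetric targets).

    Mutations are applied against the original context in one pass.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chars = list(seq)
    ca_sites = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CA"]
    tg_sites = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "TG"]
    for sites, pos_off, new in ((ca_sites, 0, "T"), (tg_sites, 1, "A")):
        n = round(fraction * len(sites))
        if n:
            chosen = rng.choice(len(sites), size=n, replace=False)
            for j in chosen:
                chars[sites[j] + pos_off] = new
    return "".join(chars)
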