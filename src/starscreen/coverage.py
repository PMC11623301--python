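"""Element presence calling from read coverage breadth.

A strain is scored against an element reference by mapping its reads and
asking what fraction of reference positions is covered at all (breadth,
not mean depth). Breadth above the presence threshold (default 0.90,
i.e. the ">90% read coverage across the reference" rule) calls the
element present; breadth below the absence threshold calls it absent;
anything between is a partial/truncated copy.

The internal mapper is deliberately simple — exact k-mer anchoring plus
a read-level identity check — which is sufficient for the substitution-
only synthetic reads this package generates. Real-data users can bypass
it entirely by supplying a precomputed per-base depth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GenomeSequence, ReadRecord, reverse_complement

DEFAULT_K = 21
PRESENT_THRESHOLD = 0.90
ABSENT_THRESHOLD = 0.10
MIN_READ_IDENTITY = 0.90

STATUS_PRESENT = "present"
STATUS_PARTIAL = "partial"
STATUS_ABSENT = "absent"


@dataclass
class DepthProfile:
    """Per-base read depth over one reference sequence."""

    ref_id: str
    depth: np.ndarray  # int array, length == reference length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class PresenceCall:
    strain_id: str
    breadth: float
    status: str
    present_threshold: float = PRESENT_THRESHOLD
    absent_threshold: float = ABSENT_THRESHOLD


def map_reads(
    reads: Sequence[ReadRecord],
    reference: GenomeSequence,
    k: int = DEFAULT_K,
    min_identity: float = MIN_READ_IDENTITY,
) -> tuple[DepthProfile, int]:
    """Place each read at its first exact k-mer anchor; verify by identity.

    Both orientations are tried ('+' first). A placement must agree with
    the reference at >= min_identity over the overlapping span, otherwise
    the read is unmapped. Returns the depth profile and the mapped count.
    """
    if not reads:
        raise ValueError("no reads supplied")
    if reference.length < k:
        raise ValueError("reference shorter than the seed length")
    ref = reference.residues
    ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    index: dict[str, int] = {}
    for pos in range(len(ref) - k + 1):
        kmer = ref[pos : pos + k]
        if "N" not in kmer and kmer not in index:
            index[kmer] = pos  # leftmost anchor wins, deterministically
    depth = np.zeros(reference.length, dtype=np.int64)
    mapped = 0
    for read in reads:
        placed = _place(read.sequence, index, ref_arr, k, min_identity)
        if placed is None:
            placed = _place(
                reverse_complement(read.sequence), index, ref_arr, k, min_identity
            )
        if placed is not None:
            lo, hi = placed
            depth[lo:hi] += 1
            mapped += 1
    return DepthProfile(ref_id=reference.id, depth=depth), mapped


def _place(
    seq: str, index: dict[str, int], ref_arr: np.ndarray, k: int, min_identity: float
) -> tuple[int, int] | None:
    n_ref = ref_arr.size
    for offset in range(len(seq) - k + 1):
        pos = index.get(seq[offset : offset + k])
        if pos is None:
            continue
        start = pos - offset
        lo = max(0, start)
        hi = min(n_ref, start + len(seq))
        if hi - lo < k:
            return None
        read_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        seg = read_arr[lo - start : hi - start]
        ident = float((seg == ref_arr[lo:hi]).mean())
        if ident >= min_identity:
            return lo, hi
        return None  # anchored but too diverged: reject, do not rescan
    return None


def depth_from_table(ref_id: str, rows: Sequence[tuple[int, int]], length: int) -> DepthProfile:
    """Build a profile from (position, depth) pairs (externally produced)."""
    depth = np.zeros(length, dtype=np.int64)
    for pos, d in rows:
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside reference of length {length}")
        depth[pos] = d
    return DepthProfile(ref_id=ref_id, depth=depth)


def coverage_breadth(profile: DepthProfile, min_depth: int = 1) -> float:
    """Fraction of reference positions with depth >= min_depth."""
    if profile.depth.size == 0:
        raise ValueError("empty depth profile")
    return float((profile.depth >= min_depth).mean())


def call_presence(
    breadth: float,
    strain_id: str = "strain",
    present_threshold: float = PRESENT_THRESHOLD,
    absent_threshold: float = ABSENT_THRESHOLD,
) -> PresenceCall:
    """Band the breadth into present / partial / absent."""
    if not 0.0 <= absent_threshold < present_threshold <= 1.0:
        raise ValueError("require 0 <= absent_threshold < present_threshold <= 1")
    if breadth > present_threshold:
        status = STATUS_PRESENT
    elif breadth < absent_threshold:
        status = STATUS_ABSENT
    else:
        status = STATUS_PARTIAL
    return PresenceCall(
        strain_id=strain_id,
        breadth=breadth,
        status=status,
        present_threshold=present_threshold,
        absent_threshold=absent_threshold,
    )
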