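"""Genomic neighborhoods of candidate genes.

A neighborhood is a run of at least ``min_genes`` distinct flagged genes
on one contig in which every consecutive pair (by coordinate) is within
``max_gap`` of each other, distance measured between gene edges (end of
one gene to start of the next). This is single-linkage chaining, so a
neighborhood's end-to-end span may far exceed ``max_gap``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GeneAnnotation

DEFAULT_MIN_GENES = 3
DEFAULT_MAX_GAP = 25_000
DEFAULT_FLANK = 25_000


@dataclass(frozen=True)
class Neighborhood:
    contig_id: str
    member_gene_ids: tuple[str, ...]
    span: tuple[int, int]
    flanked_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.member_gene_ids)) != len(self.member_gene_ids):
            raise ValueError("duplicate member gene ids")


def find_neighborhoods(
    genes: Sequence[GeneAnnotation],
    min_genes: int = DEFAULT_MIN_GENES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Neighborhood]:
    """Single-linkage chaining of flagged genes per contig.

    Genes are sorted by start per contig; consecutive genes whose
    nearest-edge gap is <= max_gap are linked; chains with >= min_genes
    distinct ids are emitted, sorted by (contig, span start).
    """
    if min_genes < 1 or max_gap < 0:
        raise ValueError("min_genes must be >= 1 and max_gap >= 0")
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    out: list[Neighborhood] = []
    for contig in sorted(by_contig):
        chain: list[GeneAnnotation] = []
        max_end = 0
        ordered = sorted(by_contig[contig], key=lambda g: (g.start, g.end, g.gene_id))
        for g in ordered:
            # nearest-edge distance to the chain is start minus the chain's
            # max end (not the previous gene's end: genes may nest/overlap)
            if chain and g.start - max_end <= max_gap:
                chain.append(g)
                max_end = max(max_end, g.end)
            else:
                if len(chain) >= min_genes:
                    out.append(_emit(contig, chain))
                chain = [g]
                max_end = g.end
        if len(chain) >= min_genes:
            out.append(_emit(contig, chain))
    out.sort(key=lambda n: (n.contig_id, n.span[0]))
    return out


def _emit(contig: str, chain: list[GeneAnnotation]) -> Neighborhood:
    return Neighborhood(
        contig_id=contig,
        member_gene_ids=tuple(g.gene_id for g in chain),
        span=(min(g.start for g in chain), max(g.end for g in chain)),
    )


def extend_neighborhood(
    nbhd: Neighborhood,
    all_genes: Iterable[GeneAnnotation],
    flank: int = DEFAULT_FLANK,
) -> Neighborhood:
    """Attach every gene overlapping the span extended by ±flank (clipped at 0)."""
    lo = max(0, nbhd.span[0] - flank)
    hi = nbhd.span[1] + flank
    members = set(nbhd.member_gene_ids)
    flanked = list(nbhd.member_gene_ids)
    extras = [
        g
        for g in all_genes
        if g.contig_id == nbhd.contig_id
        and g.gene_id not in members
        and g.start < hi
        and g.end > lo
    ]
    extras.sort(key=lambda g: (g.start, g.gene_id))
    flanked.extend(g.gene_id for g in extras)
    return Neighborhood(
        contig_id=nbhd.contig_id,
        member_gene_ids=nbhd.member_gene_ids,
        span=nbhd.span,
        flanked_gene_ids=tuple(flanked),
    )
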