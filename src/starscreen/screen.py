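"""The "BLAST-all" screen: per-gene best hits, candidate flags, background.

Every annotated gene of the query genome is searched against the full
partner genome and the single top hit kept — one scatter point per gene
(identity versus alignment length). Genes whose best hit is both longer
than ``min_len`` and more identical than ``min_identity`` (strict
inequalities, following the published ">100 bp … >96%" wording) are
candidate horizontal transfers; the unweighted mean identity of the
remaining genes with hits is the vertical-descent background (~72% for
inter-species pairs at the divergence this screen targets). Candidates
falling outside a known element interval are reflagged ``external``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import BestHit, GenomeIndex, SearchParams, best_hit
from .io_formats import GeneAnnotation, GenomeSequence, gene_sequence

FLAG_BACKGROUND = "background"
FLAG_CANDIDATE = "candidate"
FLAG_EXTERNAL = "external"
FLAG_NO_HIT = "no_hit"

_COLUMNS = [
    "gene_id",
    "gene_start",
    "gene_end",
    "subject_contig",
    "subject_start",
    "subject_end",
    "strand",
    "align_len",
    "pct_identity",
    "score",
    "flag",
]


@dataclass
class HitTable:
    """Per-gene best hits for one genome pair plus screening parameters.

    ``rows`` is a DataFrame with one row per query gene in input order;
    no-hit genes carry NaN subject fields and flag ``no_hit``. Flags are
    unset (empty string) until :func:`classify_candidates` runs.
    """

    rows: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.rows)

    @property
    def n_hits(self) -> int:
        return int(self.rows["align_len"].notna().sum())

    @property
    def n_candidates(self) -> int:
        return int((self.rows["flag"] == FLAG_CANDIDATE).sum())

    def summary(self) -> dict:
        out = {
            "n_genes": self.n_genes,
            "n_hits": self.n_hits,
            "n_candidates": self.n_candidates,
        }
        try:
            out["background_mean_identity"] = background_mean_identity(self)
        except ValueError:
            out["background_mean_identity"] = float("nan")
        return out

    def to_records(self) -> list[dict]:
        recs = []
        for _, r in self.rows.iterrows():
            rec = {c: r[c] for c in _COLUMNS}
            for key in ("subject_start", "subject_end", "align_len", "score"):
                if pd.notna(rec[key]):
                    rec[key] = int(rec[key])
                else:
                    rec[key] = None
            if pd.isna(rec["pct_identity"]):
                rec["pct_identity"] = None
            if not isinstance(rec["subject_contig"], str):
                rec["subject_contig"] = None
            recs.append(rec)
        return recs


def best_hit_table(
    genes: Sequence[GeneAnnotation],
    query_genome: GenomeSequence,
    target_genome: GenomeSequence,
    params: SearchParams = SearchParams(),
) -> HitTable:
    """Search every query gene against the target genome; one row per gene."""
    if not genes:
        raise ValueError("empty gene set")
    if target_genome.length == 0:
        raise ValueError("empty target genome")
    index = GenomeIndex(target_genome, params.seed_len)
    rows = []
    for gene in genes:
        seq = gene_sequence(gene, query_genome)
        hit = best_hit(gene.gene_id, seq, index, params)
        if hit is None:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "gene_start": gene.start,
                    "gene_end": gene.end,
                    "subject_contig": None,
                    "subject_start": np.nan,
                    "subject_end": np.nan,
                    "strand": None,
                    "align_len": np.nan,
                    "pct_identity": np.nan,
                    "score": np.nan,
                    "flag": FLAG_NO_HIT,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "gene_start": gene.start,
                    "gene_end": gene.end,
                    "subject_contig": hit.subject_contig,
                    "subject_start": hit.subject_span[0],
                    "subject_end": hit.subject_span[1],
                    "strand": hit.strand,
                    "align_len": hit.align_len,
                    "pct_identity": hit.pct_identity,
                    "score": hit.score,
                    "flag": "",
                }
            )
    return HitTable(
        rows=pd.DataFrame(rows, columns=_COLUMNS),
        params={"seed_len": params.seed_len, "min_score": params.min_score},
    )


def classify_candidates(
    table: HitTable, min_len: int = 100, min_identity: float = 96.0
) -> HitTable:
    """Flag candidate rows: align_len > min_len AND pct_identity > min_identity.

    Both inequalities are strict. Rows with hits that miss either
    threshold are flagged background; no-hit rows keep ``no_hit``.
    """
    if min_len <= 0 or min_identity <= 0:
        raise ValueError("thresholds must be positive")
    if min_identity > 100:
        raise ValueError("min_identity cannot exceed 100")
    rows = table.rows.copy()
    has_hit = rows["align_len"].notna()
    is_cand = has_hit & (rows["align_len"] > min_len) & (rows["pct_identity"] > min_identity)
    rows.loc[has_hit & ~is_cand, "flag"] = FLAG_BACKGROUND
    rows.loc[is_cand, "flag"] = FLAG_CANDIDATE
    rows.loc[~has_hit, "flag"] = FLAG_NO_HIT
    params = dict(table.params)
    params.update({"min_len": min_len, "min_identity": min_identity})
    return HitTable(rows=rows, params=params)


def background_mean_identity(table: HitTable) -> float:
    """Unweighted mean identity over non-candidate rows with hits."""
    rows = table.rows
    mask = rows["align_len"].notna() & (rows["flag"] != FLAG_CANDIDATE)
    if not mask.any():
        raise ValueError("no non-candidate rows with hits")
    return float(rows.loc[mask, "pct_identity"].mean())


@dataclass(frozen=True)
class LocalizationResult:
    n_inside: int
    n_outside: int

    @property
    def fraction_inside(self) -> float:
        return self.n_inside / (self.n_inside + self.n_outside)


def localization_check(
    table: HitTable, element_interval: tuple[int, int]
) -> tuple[HitTable, LocalizationResult]:
    """Split candidates by overlap with the known element interval (genome A).

    Candidates whose gene interval does not overlap the element are
    reflagged ``external`` (the scatter's "outside the element" class).
    """
    lo, hi = element_interval
    if not 0 <= lo < hi:
        raise ValueError("invalid element interval")
    rows = table.rows.copy()
    cand = rows["flag"] == FLAG_CANDIDATE
    if not cand.any():
        raise ValueError("no candidates to localize")
    overlaps = (rows["gene_start"] < hi) & (rows["gene_end"] > lo)
    outside = cand & ~overlaps
    rows.loc[outside, "flag"] = FLAG_EXTERNAL
    n_out = int(outside.sum())
    n_in = int((cand & overlaps).sum())
    return HitTable(rows=rows, params=dict(table.params)), LocalizationResult(n_in, n_out)


def scatter_plot(table: HitTable, path: str) -> None:
    """Identity-vs-length scatter of best hits, colored by flag."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        FLAG_BACKGROUND: "0.6",
        FLAG_CANDIDATE: "red",
        FLAG_EXTERNAL: "green",
    }
    fig, ax = plt.subplots(figsize=(6, 4))
    rows = table.rows[table.rows["align_len"].notna()]
    for flag, color in colors.items():
        sub = rows[rows["flag"] == flag]
        if len(sub):
            ax.scatter(sub["align_len"], sub["pct_identity"], s=8, c=color, label=flag)
    ax.set_xlabel("best-hit alignment length (bp)")
    ax.set_ylabel("percent identity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
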