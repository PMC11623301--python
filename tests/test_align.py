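import numpy as np
import pytest

from starscreen import align as al
from starscreen.io_formats import GenomeSequence, reverse_complement

S112 = al.Scoring(match=1, mismatch=-1, gap=-2)


class TestOracle:
    def test_identical_sequences(self):
        aln = al.dp_align_oracle("ACGT", "ACGT", S112)
        assert aln.score == 4 and al.percent_identity(aln) == 100.0

    def test_single_mismatch_full_length(self):
        # full-length alignment (score 6) beats the perfect 5-mer suffix (score 5)
        aln = al.dp_align_oracle("ACGTACGT", "ACCTACGT", S112)
        assert (aln.columns, aln.matches, aln.score) == (8, 7, 6)
        assert al.percent_identity(aln) == 87.5

    def test_disjoint_alphabets_give_empty_alignment(self):
        aln = al.dp_align_oracle("AAAA", "TTTT", S112)
        assert aln.score == 0 and aln.columns == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            al.dp_align_oracle("", "ACGT", S112)

    def test_gap_is_taken_when_strictly_cheaper(self):
        # bridging the inserted base joins two matching blocks: 7 matches - one
        # gap (-2) = 5, strictly better than any ungapped placement (max 4)
        aln = al.dp_align_oracle("ACGTGCA", "ACGATGCA", S112)
        assert aln.gaps == 1 and aln.matches == 7 and aln.score == 5 and aln.columns == 8

    def test_tie_breaks_prefer_fewer_columns(self):
        # gapped (6 matches - gap) and shifted ungapped (5 matches - mismatch)
        # both score 4; the tie-break picks the shorter alignment
        aln = al.dp_align_oracle("AAATTT", "AAAGTTT", S112)
        assert aln.score == 4 and aln.gaps == 0 and aln.columns == 6

    def test_n_never_matches(self):
        aln = al.dp_align_oracle("ANNA", "ANNA", S112)
        # optimum avoids the N columns entirely: two single-base alignments, take first
        assert aln.matches == aln.columns == 1


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "matches,columns,expected", [(96, 100, 96.0), (100, 100, 100.0), (7, 8, 87.5)]
    )
    def test_values(self, matches, columns, expected):
        aln = al.Alignment((0, columns), (0, columns), columns, matches, 0, 0)
        assert al.percent_identity(aln) == expected

    def test_zero_columns_rejected(self):
        with pytest.raises(ValueError):
            al.percent_identity(al.Alignment((0, 0), (0, 0), 0, 0, 0, 0))

    def test_score_invariant_under_joint_reverse_complement(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=60))
            f = al.dp_align_oracle(a, b, S112)
            r = al.dp_align_oracle(reverse_complement(a), reverse_complement(b), S112)
            assert f.score == r.score


def _planted_instance(rng, gene_len=40, genome_len=400, sub_rate=0.1, indels=False):
    """A gene planted as a mutated substring of a random genome."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    gene = rng.choice(bases, size=gene_len).tobytes().decode()
    copy = list(gene)
    for i in range(len(copy)):
        if rng.random() < sub_rate:
            copy[i] = "ACGT"[(("ACGT".index(copy[i])) + rng.integers(1, 4)) % 4]
    if indels and rng.random() < 0.5:
        pos = int(rng.integers(5, len(copy) - 5))
        if rng.random() < 0.5:
            del copy[pos]
        else:
            copy.insert(pos, "ACGT"[rng.integers(0, 4)])
    flank = genome_len - len(copy)
    left = int(rng.integers(0, flank + 1))
    genome = (
        rng.choice(bases, size=left).tobytes().decode()
        + "".join(copy)
        + rng.choice(bases, size=flank - left).tobytes().decode()
    )
    return gene, GenomeSequence("g", genome), (left, left + len(copy))


def _has_seed(gene: str, idx: al.GenomeIndex) -> bool:
    k = idx.k
    for seq in (gene, reverse_complement(gene)):
        for i in range(len(seq) - k + 1):
            if idx.positions(seq[i : i + k]):
                return True
    return False


def _seed_in_span(gene: str, idx: al.GenomeIndex, span: tuple[int, int]) -> bool:
    """True if an exact seed anchors either gene strand inside the planted span."""
    k = idx.k
    lo, hi = span
    for seq in (gene, reverse_complement(gene)):
        for i in range(len(seq) - k + 1):
            if any(lo - k < p < hi for p in idx.positions(seq[i : i + k])):
                return True
    return False


def check_seed_extend_vs_oracle(gene, genome, span, params):
    """Shared oracle-equivalence check; returns True when equality was asserted.

    Seed-and-extend must equal the exhaustive DP optimum whenever an exact
    seed anchors the planted region; when nothing anchors it, the search may
    miss it but can never beat the oracle.
    """
    idx = al.GenomeIndex(genome, params.seed_len)
    hit = al.best_hit("q", gene, idx, params)
    oracle = max(
        al.dp_align_oracle(gene, genome.residues, params.scoring).score,
        al.dp_align_oracle(reverse_complement(gene), genome.residues, params.scoring).score,
    )
    if _seed_in_span(gene, idx, span):
        assert hit is not None and hit.score == oracle
        return True
    if hit is None:
        assert not _has_seed(gene, idx)
    else:
        assert hit.score <= oracle
    return False


class TestBestHit:
    def test_identity_invariant_under_query_reverse_complement(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            gene, genome, _span = _planted_instance(rng, gene_len=80, sub_rate=0.05)
            idx = al.GenomeIndex(genome, 11)
            fwd = al.best_hit("q", gene, idx, al.SearchParams(min_score=10))
            rev = al.best_hit("q", reverse_complement(gene), idx, al.SearchParams(min_score=10))
            assert fwd is not None and rev is not None
            assert fwd.score == rev.score
            assert fwd.pct_identity == pytest.approx(rev.pct_identity)
            assert fwd.subject_span == rev.subject_span

    def test_exact_substring_hits_at_full_length(self):
        rng = np.random.default_rng(1)
        gene, genome, _span = _planted_instance(rng, sub_rate=0.0)
        idx = al.GenomeIndex(genome, 11)
        hit = al.best_hit("q", gene, idx, al.SearchParams(min_score=10))
        assert hit is not None
        assert hit.pct_identity == 100.0 and hit.align_len == len(gene)

    def test_score_matches_dp_oracle_on_planted_instances(self):
        """Seed-and-extend local score equals the exhaustive DP optimum."""
        rng = np.random.default_rng(2)
        params = al.SearchParams(min_score=10)
        n_checked = 0
        for trial in range(60):
            gene, genome, span = _planted_instance(
                rng, sub_rate=float(rng.uniform(0, 0.15)), indels=True
            )
            n_checked += check_seed_extend_vs_oracle(gene, genome, span, params)
        assert n_checked >= 50

    def test_mutated_ortholog_identity_close_to_oracle(self):
        rng = np.random.default_rng(3)
        gene, genome, _span = _planted_instance(rng, gene_len=300, genome_len=1000, sub_rate=0.28)
        idx = al.GenomeIndex(genome, 11)
        hit = al.best_hit("q", gene, idx)
        assert hit is not None
        oracle = al.dp_align_oracle(gene, genome.residues, al.Scoring())
        oracle_id = 100.0 * oracle.matches / oracle.columns
        assert abs(hit.pct_identity - oracle_id) <= 2.0

    def test_unrelated_genome_gives_no_hit(self):
        rng = np.random.default_rng(4)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        gene = rng.choice(bases, size=200).tobytes().decode()
        genome = GenomeSequence("g", rng.choice(bases, size=5000).tobytes().decode())
        idx = al.GenomeIndex(genome, 13)
        assert al.best_hit("q", gene, idx, al.SearchParams(seed_len=13)) is None

    def test_reverse_strand_hit_reported_on_forward_coordinates(self):
        rng = np.random.default_rng(5)
        gene, genome, _span = _planted_instance(rng, gene_len=60, genome_len=300, sub_rate=0.0)
        rc_genome = GenomeSequence("g", reverse_complement(genome.residues))
        idx = al.GenomeIndex(rc_genome, 11)
        hit = al.best_hit("q", gene, idx, al.SearchParams(min_score=10))
        assert hit is not None and hit.strand == "-"
        lo, hi = hit.subject_span
        assert rc_genome.residues[lo:hi] == reverse_complement(gene)

    def test_deterministic_reruns(self):
        rng = np.random.default_rng(6)
        gene, genome, _span = _planted_instance(rng, sub_rate=0.1)
        idx = al.GenomeIndex(genome, 11)
        assert al.best_hit("q", gene, idx) == al.best_hit("q", gene, idx)

    def test_gene_shorter_than_seed_rejected(self):
        genome = GenomeSequence("g", "ACGT" * 30)
        idx = al.GenomeIndex(genome, 11)
        with pytest.raises(ValueError):
            al.best_hit("q", "ACGTACG", idx)
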