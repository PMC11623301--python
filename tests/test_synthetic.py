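import math

import numpy as np
import pytest

from starscreen import synthetic as syn

# frozen fingerprint of the named study fixtures; any change to the fixture
# constants must be deliberate and update this value
FIXTURE_SHA256 = "f48fb1a3d558bf145c5dffbd9db62f33e62af3d1395fab482bae5e6a1a2f0c64"


def _cfg(**kw):
    base = dict(
        n_background_genes=10,
        gene_length_range=(200, 300),
        intergenic_length_range=(50, 100),
        substitution_prob=0.278,
        seed=1,
    )
    base.update(kw)
    return syn.SyntheticPairConfig(**base)


class TestBackgroundPair:
    def test_no_mutation_limit(self):
        pair = syn.generate_background_pair(_cfg(substitution_prob=0.0))
        assert (pair.truth["realized_identity"] == 100.0).all()

    def test_mean_identity_matches_binomial_expectation(self):
        # s = 0.278 over 200 genes of ~1 kb: mean realized identity 72.2 +- 0.5
        cfg = _cfg(
            n_background_genes=200,
            gene_length_range=(1000, 1000),
            substitution_prob=0.278,
            seed=17,
        )
        pair = syn.generate_background_pair(cfg)
        mean = pair.truth["realized_identity"].mean()
        assert abs(mean - 72.2) < 0.5

    def test_identity_variance_is_binomial_consistent(self):
        s = 0.25
        cfg = _cfg(
            n_background_genes=300, gene_length_range=(800, 800), substitution_prob=s, seed=9
        )
        pair = syn.generate_background_pair(cfg)
        var = pair.truth["realized_identity"].var() / 100.0**2
        expected = s * (1 - s) / 800
        assert var == pytest.approx(expected, rel=0.35)

    def test_same_seed_reproduces_byte_identical_pairs(self):
        a = syn.generate_background_pair(_cfg(seed=5))
        b = syn.generate_background_pair(_cfg(seed=5))
        assert a.genome_a.residues == b.genome_a.residues
        assert a.genome_b.residues == b.genome_b.residues
        assert a.truth.equals(b.truth)

    def test_genes_match_annotated_intervals(self):
        pair = syn.generate_background_pair(_cfg())
        for g, row in zip(pair.genes_a, pair.truth.itertuples()):
            assert (g.start, g.end) == (row.start_a, row.end_a)
            assert g.end - g.start == row.length

    @pytest.mark.parametrize(
        "kw",
        [
            {"substitution_prob": 1.0},
            {"gene_length_range": (300, 200)},
            {"gene_length_range": (50, 80)},
            {"n_background_genes": 0},
            {"gc_content": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestPlantElement:
    def test_perfect_cargo_copies_are_identical(self):
        pair = syn.generate_background_pair(_cfg(seed=2))
        site_a = (pair.genes_a[4].end + pair.genes_a[5].start) // 2
        site_b = (pair.genes_b[4].end + pair.genes_b[5].start) // 2
        spec = syn.ElementSpec(
            element_id="E",
            cargo_genes=(("e0", 300, 1.0),),
            captain_length=500,
            insertion_site_a=site_a,
            insertion_site_b=site_b,
        )
        planted = syn.plant_element(pair, spec, seed=2)
        row = planted.truth.set_index("gene_id").loc["e0"]
        ga = planted.genome_a.residues[int(row.start_a) : int(row.end_a)]
        gb = planted.genome_b.residues[int(row.start_b) : int(row.end_b)]
        assert ga == gb
        assert row.realized_identity == 100.0

    def test_element_interval_length_is_conserved(self):
        pair = syn.generate_background_pair(_cfg(seed=3))
        site_a = (pair.genes_a[4].end + pair.genes_a[5].start) // 2
        site_b = (pair.genes_b[4].end + pair.genes_b[5].start) // 2
        spec = syn.ElementSpec(
            element_id="E",
            cargo_genes=(("e0", 300, 0.98), ("e1", 250, 0.97)),
            captain_length=500,
            insertion_site_a=site_a,
            insertion_site_b=site_b,
        )
        planted = syn.plant_element(pair, spec, seed=3)
        lo, hi = planted.element_interval_a
        assert hi - lo == spec.total_length == 500 + 300 + 250 + 2 * 200
        assert planted.genome_a.length == pair.genome_a.length + spec.total_length

    def test_planted_identity_is_exact(self):
        pair = syn.generate_background_pair(_cfg(seed=4))
        site_a = (pair.genes_a[4].end + pair.genes_a[5].start) // 2
        site_b = (pair.genes_b[4].end + pair.genes_b[5].start) // 2
        spec = syn.ElementSpec(
            element_id="E",
            cargo_genes=(("e0", 400, 0.97),),
            insertion_site_a=site_a,
            insertion_site_b=site_b,
        )
        planted = syn.plant_element(pair, spec, seed=4)
        row = planted.truth.set_index("gene_id").loc["e0"]
        ga = planted.genome_a.residues[int(row.start_a) : int(row.end_a)]
        gb = planted.genome_b.residues[int(row.start_b) : int(row.end_b)]
        mismatches = sum(x != y for x, y in zip(ga, gb))
        assert mismatches == round(0.03 * 400)
        assert row.realized_identity == 100.0 * (400 - mismatches) / 400

    def test_insertion_inside_gene_rejected(self):
        pair = syn.generate_background_pair(_cfg(seed=5))
        inside = (pair.genes_a[0].start + pair.genes_a[0].end) // 2
        spec = syn.ElementSpec(
            element_id="E",
            cargo_genes=(("e0", 300, 1.0),),
            insertion_site_a=inside,
            insertion_site_b=0,
        )
        with pytest.raises(ValueError, match="inside a gene"):
            syn.plant_element(pair, spec, seed=5)


class TestReads:
    def test_read_count_formula(self):
        genome = syn.generate_background_pair(
            _cfg(n_background_genes=80, gene_length_range=(1000, 1000), intergenic_length_range=(250, 250))
        ).genome_a
        assert genome.length == 80 * 1000 + 81 * 250  # 100,250 bp
        reads, starts = syn.simulate_reads(genome, depth=10, read_len=150, seed=1)
        assert len(reads) == math.ceil(10 * genome.length / 150)
        assert len(starts) == len(reads)

    def test_error_free_reads_are_exact_substrings(self):
        genome = syn.generate_background_pair(_cfg(seed=6)).genome_a
        reads, starts = syn.simulate_reads(genome, depth=2, read_len=100, error_rate=0.0, seed=2)
        for r, s in zip(reads[:50], starts[:50]):
            assert genome.residues[s : s + 100] == r.sequence

    def test_same_seed_identical_fastq(self):
        genome = syn.generate_background_pair(_cfg(seed=6)).genome_a
        a, _ = syn.simulate_reads(genome, depth=1, read_len=100, error_rate=0.01, seed=3)
        b, _ = syn.simulate_reads(genome, depth=1, read_len=100, error_rate=0.01, seed=3)
        assert a == b

    def test_read_longer_than_genome_rejected(self):
        genome = syn.GenomeSequence("g", "ACGT" * 10)
        with pytest.raises(ValueError):
            syn.simulate_reads(genome, depth=1, read_len=100, seed=0)


class TestCross:
    def test_default_model_growth_fractions(self):
        df = syn.simulate_cross(syn.DEFAULT_CROSS, 10_000, seed=1)
        se = math.sqrt(0.75 * 0.25 / 10_000)
        assert abs(df["grows_at_2"].mean() - 0.75) < 3 * se
        # growth at the high concentration is exactly the element genotype
        assert (df["grows_at_5"] == df["element"].astype(bool)).all()

    def test_no_conferring_locus_means_no_growth(self):
        model = syn.CrossModel(loci=(("inert", ()),), concentrations=(2.0, 5.0))
        df = syn.simulate_cross(model, 50, seed=2)
        assert not df["grows_at_2"].any() and not df["grows_at_5"].any()

    def test_invalid_progeny_count_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_cross(syn.DEFAULT_CROSS, 0, seed=1)


class TestFixtures:
    def test_fixture_constants_are_frozen(self):
        assert syn.fixture_checksum() == FIXTURE_SHA256

    def test_fixture_cargo_identities_straddle_thresholds(self):
        mi = syn.FIXTURES["mi_pair"]
        assert len(mi.cargo_identities) == 20 and min(mi.cargo_identities) >= 0.98
        pi = syn.FIXTURES["pi_pair"]
        assert sum(1 for p in pi.cargo_identities if p == 1.0) == 10
        assert len(pi.cargo_identities) == 18
        assert all(0.90 <= p <= 0.955 for p in pi.cargo_identities if p < 1.0)
        chi = syn.FIXTURES["chi_pair"]
        assert len(chi.cargo_identities) == 35
        assert sum(1 for p in chi.cargo_identities if p >= 0.97) == 29
        assert all(0.85 <= p <= 0.95 for p in chi.cargo_identities if p < 0.97)

    def test_build_fixture_is_deterministic(self):
        a, _ = syn.build_fixture("mi_pair")
        b, _ = syn.build_fixture("mi_pair")
        assert a.genome_a.residues == b.genome_a.residues
        assert a.genome_b.residues == b.genome_b.residues
        assert a.element_interval_a == b.element_interval_a

    def test_unknown_fixture_rejected_with_names(self):
        with pytest.raises(ValueError, match="mi_pair"):
            syn.build_fixture("nope")
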