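import pytest

from starscreen import synthetic as syn
from starscreen import screen as scr


@pytest.fixture(scope="session")
def small_pair():
    """A small background pair (20 genes, ~72% ortholog identity)."""
    cfg = syn.SyntheticPairConfig(
        n_background_genes=20,
        gene_length_range=(300, 500),
        intergenic_length_range=(100, 300),
        substitution_prob=0.278,
        seed=42,
    )
    return syn.generate_background_pair(cfg)


@pytest.fixture(scope="session")
def small_element_pair():
    """A small pair carrying a planted 5-cargo element (one gene below 96%)."""
    cfg = syn.SyntheticPairConfig(
        n_background_genes=20,
        gene_length_range=(300, 500),
        intergenic_length_range=(100, 300),
        substitution_prob=0.278,
        seed=43,
    )
    pair = syn.generate_background_pair(cfg)
    mid = 10
    spec = syn.ElementSpec(
        element_id="E",
        cargo_genes=(
            ("e_c00", 400, 1.0),
            ("e_c01", 350, 0.99),
            ("e_c02", 420, 0.985),
            ("e_c03", 380, 0.98),
            ("e_c04", 400, 0.90),  # below the 96% screen
        ),
        captain_length=800,
        insertion_site_a=(pair.genes_a[mid].end + pair.genes_a[mid + 1].start) // 2,
        insertion_site_b=(pair.genes_b[mid].end + pair.genes_b[mid + 1].start) // 2,
    )
    return syn.plant_element(pair, spec, seed=43)


@pytest.fixture(scope="session")
def small_screen(small_element_pair):
    """Classified hit table of the small element pair at the >100bp/>96% screen."""
    pair = small_element_pair
    table = scr.best_hit_table(pair.genes_a, pair.genome_a, pair.genome_b)
    return scr.classify_candidates(table, min_len=100, min_identity=96.0)


@pytest.fixture(scope="session")
def fixture_demos():
    """Full-pipeline reports for the three named study fixtures (pinned seeds)."""
    from starscreen.demo import run_demo

    return {name: run_demo(name) for name in ("mi_pair", "pi_pair", "chi_pair")}
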