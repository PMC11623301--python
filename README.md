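# starscreen

Detection of horizontally transferred giant fungal transposons
(*Starships*) between genome pairs.

*Starships* are giant mobile elements (tens to hundreds of kb) of
Pezizomycotina fungi: a tyrosine-recombinase "captain" gene heads the
element and mobilizes a large cargo of host-adaptive genes — for example
a formaldehyde-detoxification cluster. Because a recently transferred
element is nearly identical in donor and recipient while the rest of the
two genomes has diverged for millions of years, horizontal transfer
leaves a stark signature in a simple statistic: the best-hit nucleotide
identity of each gene of one genome searched against the other.

`starscreen` implements that inference stack as a tested Python library:

1. **BLAST-all screen** (`starscreen.screen`) — every annotated gene of
   genome A is searched against genome B (seed-and-extend, both
   strands); the single top hit per gene gives one point of an identity
   vs alignment-length scatter. Genes with best hits of length
   > 100 bp *and* identity > 96% (strict, configurable; a 97% and a
   100%-identity preset exist) are HGT candidates; the unweighted mean
   identity of the remaining genes is the vertical-descent background,
   ~72% for the inter-species pairs this screen targets.
2. **Cargo neighborhoods** (`starscreen.neighborhoods`) — candidates are
   clustered by single-linkage chaining: at least 3 distinct genes whose
   consecutive nearest-edge gaps are ≤ 25 kb, then extended by ±25 kb of
   flanking genes.
3. **Coverage presence calls** (`starscreen.coverage`) — a strain is
   scored for an element by mapping its reads to the element reference;
   breadth (fraction of positions with depth ≥ 1) > 0.90 calls the
   element present, < 0.10 absent, between the two a partial/truncated
   copy.
4. **Segregation genetics** (`starscreen.segregation`) — expectations and
   exact tests for haploid crosses: a progeny inherits at least one of
   *n* unlinked resistance loci with probability 1 − (1/2)^n (50% for
   one locus, 75% for two); marker–phenotype cosegregation is tested
   with Fisher's exact test, observed counts with an exact binomial
   test.
5. **Synthetic genome pairs** (`starscreen.synthetic`) — first-class
   generators for everything above: diverged ortholog pairs (per-site
   substitution probability *s*, expected identity exactly 1 − *s*),
   planted elements with per-cargo-gene identities, uniform error-prone
   reads, and haploid cross progeny. Three frozen fixtures (`mi_pair`,
   `pi_pair`, `chi_pair`) emulate the element comparisons the screen is
   calibrated against.
6. **RIP profiling** (`starscreen.rip`) — sliding-window dinucleotide
   indices (TpA/ApT product, (CpA+TpG)/(ApC+GpT) substrate) to flag
   repeat-induced point mutation in "derelict" element copies.

A hand-written full Smith–Waterman oracle (`dp_align_oracle`) backs the
production search in the test suite, and every exact test is checked
against direct enumeration.

## Worked example

```sh
python examples/screen_genome_pair.py
```

```
genome A: 382,947 bp, 220 genes
element planted at (179653, 210142) in A
candidates (>100 bp, >96% identity): 20
background mean identity: 72.29%
fraction of candidates inside the element: 1.00
neighborhood: chrA:181853-210142 (20 genes)
```

The two genomes diverge at 27.8% of gene sites, so ortholog best hits
average ~72% identity — the vertical-descent baseline. Exactly the 20
cargo genes of the planted element exceed the >100 bp / >96% screen, all
of them localize inside the element interval, and they chain into a
single ≥3-genes-within-25-kb neighborhood: the signature of one recent
horizontal transfer on a deeply diverged background.

The other examples cover presence calling from read coverage
(`examples/coverage_presence.py`), cross segregation
(`examples/segregation_cross.py`) and RIP profiling
(`examples/rip_profiling.py`). The same stages are scriptable through a
thin CLI:

```sh
starscreen demo --fixture mi_pair --outdir out/   # full pipeline + artifacts
starscreen screen --genes A.gff3 --query A.fa --target B.fa \
    --min-len 100 --min-ident 96 --out hits.tsv
```

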