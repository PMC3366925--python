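# mtphylo

Tools for mtDNA control-region phylogeography: the kind of analysis used to
read maternal population history out of a large regional survey of human
mitochondrial DNA. The package covers the full path from per-sample variant
tables to dated haplogroup clades:

* **Variant notation** — parsing and serializing rCRS-relative tokens
  (`16360`, `106-111d`, `309.1C`, `64@`, `16182C`, `152Y`), circular
  coordinates on the 16,569-bp molecule, site filters, mutational
  distances, and variant calling from FASTA sequences.
* **Haplogroup classification** — best-path motif matching on a rooted
  haplogroup tree whose edges carry diagnostic mutations, with proper
  handling of back mutations (`@`) and of diagnostics that fall outside a
  sample's sequenced window; regional frequency tables with Pearson χ²
  tests of geographic structure.
* **Median-joining networks** — binary character coding of haplotypes,
  minimum-spanning networks with tolerance ε, quasi-median (majority)
  vector addition, and network-based clade dating.
* **Coalescence dating** — the ρ statistic (mean mutational distance of a
  clade's haplotypes to its root) with the heuristic standard error
  σ² = Σₑ lₑ(nₑ/N)², conversion to years through a molecular clock
  (whole-molecule default: one mutation per 3,624 years), and
  maximum-likelihood branch lengths on a fixed topology under HKY85 with
  32-category discrete-gamma rates and partitioned hypervariable segments.
* **Diversity statistics** — nucleotide diversity π, mean pairwise
  differences k, haplotype diversity Hd with the n/(n−1) correction,
  polymorphic-site counts.
* **Pedigree handling** — terminal-maternal-ancestor (TMA) origin
  filtering and deterministic deduplication of maternally related sample
  clusters.
* **Synthetic cohorts** — a generator that emulates a region-stratified
  survey (default composition: a 1,350-sample, 12-region cohort with
  known haplogroup frequencies), evolving haplotypes on star genealogies
  of known age, with foreign-TMA samples and relatedness clusters, plus a
  truth record that makes every downstream stage testable offline.

## Worked example

```python
import mtphylo as m

# classify a control-region haplotype carrying the 6-bp "Huetar" deletion
h = m.Haplotype("PA00001", m.parse_variants("73@ 106-111d 16360"))
tree = m.HaplogroupTree.bundled("a2")
print(m.classify(h, tree))
# ClassificationResult(sample_id='PA00001', best_node='A2af', matched=3,
#                      expected=3, private_mutations=0, score=1.0)

# date a clade from a rooted mutation-count genealogy
t = m.GenealogyTree.from_newick("((a:1,b:1):1,c:2)r;")
est = m.to_years(m.rho_sigma(t), m.ClockConfig(), scale="whole_molecule")
print(round(est.rho, 3), round(est.sigma, 3), round(est.age_years))
# 2.0 0.943 7248
```

The ρ of 2.0 says the three sampled lineages sit on average two mutations
from the clade root; at one mutation per 3,624 years that dates the
founder to ≈7,248 years, with σ translating to a ±3,417-year heuristic
standard error.

A full pipeline run on a synthetic cohort (TMA filter → kin dedup →
classification → frequency table + χ² → diversity → focal-clade network →
dating):

```bash
mtphylo run --simulate --seed 7 --outdir out/
```

writes `classification.tsv`, `frequency_table.tsv`, `diversity.tsv`,
`network.gml`/`.dot`, and `ages.tsv`. With the default composition the
frequency table's Grand Total row shows 51.04 % A2 and 83.48 % Native
American lineages (99.16 % Native in the indigenous comarcas), and the
focal-clade network dates the 6-bp-deletion clade to ≈23.6 ka — the
conditions the generator is built to emulate.

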