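# Methods

This note documents the models and procedures implemented in `mtphylo`,
the choices made where several reasonable designs existed, and what the
synthetic-data tests do and do not demonstrate about real data.

## Coordinates and variant notation

All variants are named relative to the 16,569-bp rCRS coordinate system,
1-based, with the molecule treated as circular. Intervals are closed on
both ends; an interval whose start exceeds its end wraps the origin (the
default sequenced window, np 16000–580, covers the whole control region
this way). The token grammar follows field convention: bare positions are
transitions, a trailing base is a transversion (or a heteroplasmy when the
base is an IUPAC ambiguity code), `d` marks deletions (spans accepted with
hyphen or en-dash on input, serialized with a hyphen), `.kB` marks the
k-th inserted base after a position, and a trailing `@` marks a back
mutation. Parsing and serialization are exact inverses over this grammar.

Site filters express the two counting conventions used throughout:

* **network profile** — substitutions only, except that the 6-bp deletion
  at nps 106–111 is retained as a single character (it is a stable clade
  diagnostic); insertions, other deletions and heteroplasmies are
  dropped, as is length variation in the C-stretches (303–315,
  16184–16193) and the unstable sites 16182C, 16183C, 16194C and 16519.
* **stats profile** — substitutions only, for diversity statistics.

Reversion tokens denote the reference state and never count as
differences. The two-base deletion 522–523d parses and counts as one
character under the `none` profile but is dropped by both defaults.

## Variant calling from sequence

Complete genomes are compared to the reference by global edit-distance
alignment (edlib), after which indels are normalized to their 3'-most
placement within repeats — the standard naming convention for human
mtDNA. A query more than 5 % divergent from the reference is rejected
rather than misaligned. The packaged reference generator produces a
deterministic synthetic 16,569-bp sequence (clearly labelled synthetic):
every coordinate-level computation in the package is independent of the
actual bases, and users align real data against the real rCRS FASTA.

## Haplogroup classification

A haplogroup tree is a rooted tree whose edges carry defining motifs. A
sample is evaluated against each node's *net founder motif*: positive
entries accumulated root-to-node, minus entries cancelled by a downstream
reversion. A node is a candidate call when

1. every observable founder variant is present in the sample,
2. every observable reverted variant is absent, and
3. the node's defining branch carries observable evidence — at least one
   surviving positive mutation the sample has, or, when the branch's only
   observable evidence is a back mutation, that back mutation is satisfied
   *and* the parent node is itself contradicted by the reverted sites.

Rule 3 is the promotion policy for negative evidence. Absence of a
mutation alone must not push a call deeper (a control-region sample with
a clade's basal motif is not assigned to a sub-clade whose only in-window
diagnostic is a reversion), but when the choice is between a parent whose
motif the sample contradicts and a child whose reversion explains the
contradiction, the child is the consistent call. Diagnostics outside the
sample's sequenced window are unobservable: skipped entirely, never
counted as mismatches. Among candidate nodes the call is the deepest,
tie-broken by fewer unexplained (private) mutations and then
lexicographically, making classification fully deterministic.

The bundled cohort-wide tree encodes the published A2ad/A2af clade
definitions (A2af: 73@, 106–111d, 5460, 16360; A2af1: +64@, 6794, 7960;
A2af1a: +89; A2af1b: +11482; A2ad: 16175, 16300) under an A2 node;
motifs for the other major haplogroups are coarse control-region
stand-ins sufficient for synthetic cohorts and demonstrations — real
analyses should load a full phylogeny file.

Frequency tables collapse sub-haplogroup calls into major-clade bins by
longest label prefix and report row percentages per region with
count-weighted subtotal rows (provinces, comarcas, grand total).
Geographic structure is tested with Pearson's χ² (no continuity
correction), df = (R−1)(C−1).

## Median-joining networks

Haplotypes are binary-coded over their filtered variants; identical rows
merge with multiplicity (circle sizes), constant columns are removed, and
per-character weights default to 1. The network construction iterates:

1. build the minimum-spanning network — an edge of weight d is kept iff
   its endpoints are not connected using edges of weight < d − ε
   (ε = 0 default: the union of all minimum spanning trees);
2. for every connected triple (two of three pairs linked), add the
   quasi-median — the column-wise majority profile — if new;
3. repeat until no new vector arises.

Majority medians lie on pairwise geodesics, so median addition can only
shorten connections. One guard is applied when the final edge set is
assembled: wherever chains of short median steps would displace a direct
minimum-spanning link of the sampled haplotypes (leaving a sampled pair
connected only by a longer path), that link is restored. This makes the
advertised invariant — every minimum spanning tree of the data embeds in
the network at exact mutational lengths — hold unconditionally, which the
tests verify against a brute-force oracle on random instances. Unsampled
vectors that end as dangling leaves are pruned.

For dating, a clade network is rooted at the clade's founder profile
(supplied as an explicit ancestor row; it carries no sample weight unless
the founder haplotype was actually observed). ρ is the
multiplicity-weighted mean shortest-path length from the root to every
sampled haplotype; reticulations cannot change this length, only the
path identity.

## Coalescence dating

**ρ/σ.** For a rooted genealogy with integer mutation counts on edges,
ρ is the multiplicity-weighted mean root-to-leaf distance and
σ² = Σₑ lₑ (nₑ/N)², summing over edges, with nₑ the number of sampled
descendants of edge e and N the total sample count. Identical sampled
sequences each count as a leaf. Ages in years are ρ × rate; the only
hard-coded calibration is the whole-molecule rate of one mutation per
3,624 years. A control-region rate must be supplied explicitly by the
user (`ClockConfig.control_region_rate`), since published control-region
calibrations differ and the choice materially moves ages.

**Maximum likelihood.** On a fixed topology, branch lengths (expected
substitutions per site) are estimated under HKY85 with empirical base
frequencies, a shared transition/transversion parameter κ, discrete-gamma
rate variation (32 equal-probability categories represented by their
category means — the classic discretization), and three partitions:
HVS-I (16051–16400), HVS-II (68–263) and the remainder, each with a free
rate multiplier normalized to a site-weighted mean of one. Indels and
excluded sites are ignored. The likelihood is computed by Felsenstein
pruning over compressed site patterns, with the HKY generator
diagonalized once per (κ, partition) through its √π-symmetrized form.
Optimization is bounded L-BFGS-B on log-transformed parameters
(branch lengths, κ, α, multipliers), converged at relative
log-likelihood change below 1e-8; correctness is pinned by an exhaustive
state-summation oracle and by the Jukes–Cantor closed form
−(3/4)·ln(1 − 4p/3) in the equal-frequency, κ = 1, single-category limit.
An ML clade age is the mean root-to-leaf path length × 16,569 sites
(expected mutations) × years per mutation.

## Diversity statistics

Statistics are computed on variant sets, not raw alignments. The
compared-site count L is the sequenced window minus positions deleted or
heteroplasmic in any sample and minus explicitly excluded positions; this
keeps k = π·L exact by construction. k is the mean pairwise difference
under the stats filter (computed from per-variant sample counts,
Σ c(n−c)/C(n,2), with the all-pairs summation retained as a test oracle);
Hd uses the n/(n−1)-corrected form. Distinct haplotypes are distinct
filtered variant sets.

## Pedigree deduplication

Relatedness clusters are an *input* (in the emulated study they came from
an external genealogy-database search, not a described algorithm): the
package validates disjointness, keeps the lexicographically smallest
sample id per cluster — a deterministic stand-in for an unstated choice —
and logs removals. TMA filtering partitions samples by terminal maternal
ancestor origin and reports exclusion counts per origin. The pipeline
reports its own arithmetic at each stage rather than forcing any
particular published total, since pre-filter overlaps (foreign-TMA
members of related clusters) are not generally reconstructible.

## Synthetic cohorts: what they emulate, and what they do not

The generator draws samples per region with a fixed haplogroup
composition whose default encodes a 1,350-sample, 12-region survey
(9 provinces, 3 indigenous comarcas; 689 A2 of which 326 fall in the
6-bp-deletion clade and 42 in the 16175/16300 clade, quotas scaled
proportionally for smaller cohorts). Each haplotype is the haplogroup's
founding motif plus a Poisson(age/rate) number of private transitions at
hotspot-weighted control-region positions (5× at classic fast sites;
positions diagnostic in the haplogroup tree are excluded from the private
pool so that composition reconstruction is exact). Default founder ages
are field-plausible: 23,240 y for the focal deletion clade, 17,000 y for
its major sub-branches, 16,000–40,000 y elsewhere; the generator's clock
is the whole-molecule rate, interpreted as the rate of observable
mutations in the sequenced window. Foreign-TMA samples (149 by default,
with origin frequencies matching the emulated survey) and relatedness
clusters (42 pairs + 13 triplets sharing a haplotype) are layered on top.
`composition="exact"` places counts by quota; `sampled` draws
multinomially. A JSON truth record carries every latent variable.

Deliberate non-realism: lineages within a haplogroup are simulated as a
star genealogy, so haplotype sharing between unrelated samples is rare
and haplotype diversity saturates near 1 — higher than real surveys,
where shared internal branches produce a few hundred distinct haplotypes
among a thousand samples. Passing tests therefore demonstrate correctness
of the estimators (composition reconstruction, unbiased ρ recovery,
classification accuracy), not realistic diversity spectra; diversity
statistics on real data depend on the real genealogy. Recurrent mutation
is present (hotspots), but rate heterogeneity beyond the 5× hotspot class
and purifying selection are not modelled.

## Numerical and degenerate-input choices

* ε defaults to 0 in median-joining (the common default); larger ε can
  only add nodes and links (verified property).
* Classification with an empty variant set returns the tree root with a
  vacuous score of 1.
* Diversity requires n ≥ 2; the pipeline logs and skips the stage for a
  single sample, and likewise skips the network stage when the focal
  clade is absent.
* χ² rejects zero-margin tables rather than silently collapsing.
* ML fits flag non-convergence in the result rather than raising; zero
  empirical base frequencies are guarded with a unit pseudocount.
* Alignment columns containing gaps, N, or ambiguity codes are dropped
  from the likelihood (indels ignored).
* All randomness flows from explicit integer seeds; replicate
  Monte-Carlo streams are spawned from a single root `SeedSequence`.

## Problem sizes used by the packaged checks

The exhaustive ρ/σ oracle covers all 11,464 rooted binary leaf-labelled
topologies with 2–7 leaves; likelihood correctness is checked exhaustively
on 5-leaf, 50-site instances (and the Jukes–Cantor limit at 2,000 sites);
median-joining guarantees run over 200 random ≤8-taxon instances; the ρ
calibration uses 500 replicate star clades of 200 lineages at a true age
of 23,240 y. These sizes keep every check exact or statistically sharp
while the whole battery runs in seconds.

## Known limitations

* The classifier is motif-exact (score threshold 1 on observable
  expectations); there is no probabilistic rescue of samples with
  genotyping error at diagnostic sites.
* The bundled non-A2 motifs are simplified; classification quality on
  real cohorts is bounded by the user-supplied tree.
* The ML machinery estimates branch lengths on a fixed topology only;
  there is no topology search.
* Network dating assumes the restriction of the network to sampled taxa
  is tree-like from the root up to length-preserving reticulations.
* The indel-placement convention for C-stretch insertions is assumed
  3'-most; it is disregarded by the default filters in any case.
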