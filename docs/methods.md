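# Methods

## Haplotype calling

A gene's haplotype universe is defined by the biallelic SNPs whose 1-based
VCF position falls inside the gene's CDS intervals. Internally all
coordinates are 0-based half-open; GFF3 (1-based inclusive) and BED
(already half-open) are converted once at the I/O boundary, which keeps
every containment test on a single convention. Multi-allelic records and
indels are dropped at read time with a logged count; no MAF or missingness
filter is applied by default (both are available as options).

Genotypes are treated as unphased and effectively haploid: the panel is a
selfing crop, so one haplotype per accession per gene is the unit of
identity. Residual heterozygous calls and missing calls are resolved by
policy:

- `major-allele` (default): replace with the site's majority allele across
  accessions (ties go to the reference allele). Rationale: residual
  heterozygosity in inbred accessions is mostly noise, and this keeps every
  accession in scope.
- `drop-accession`: exclude the accession from that gene's scope.
- `missing-code`: keep a third symbol `N`, so partially missing strings
  form their own haplotypes.

Haplotype labels (`Hap1`, `Hap2`, ...) are assigned by descending frequency
in a single labeling scope — by default the full panel — with ties broken
by the lexicographically smaller allele string, and are then held fixed
across sub-scopes so that `Hap1` denotes the same allele string in every
population, landrace/modern-variety split and network. A gene with zero
CDS SNPs yields exactly one haplotype (the empty string) carried by all
accessions; such genes are classed HK.

## Diversity and differentiation

Shannon's equitability is Pielou evenness: the Shannon entropy of the
within-scope haplotype frequencies divided by `ln(gcHapN)` of the *same*
scope, defined as 0 for a single haplotype. Normalising by the scope's own
haplotype count (rather than a panel-wide count) makes a population of
near-unique haplotypes approach 1 and a monomorphic one exactly 0.
Diversity classes bin `E_H` at 0.05, 0.3 and 0.7 with the stated boundary
memberships (0.05 and 0.3 belong to the upper class, 0.7 to `high`, 1
included).

Major haplotypes are those at frequency ≥ 1% of the scope (inclusive); an
absolute-count mode (≥ `min_count` carriers) is available as an
alternative definition. The predominant haplotype is the frequency
maximum, ties again broken by allele string.

Nei's genetic identity between two populations is the cosine-style
normalised cross-product of their frequency vectors, computed after
aligning both on the union of their haplotype sets with zeros for
absences. Frequencies are always computed within each population
independently. Values strictly below 0.35 (configurable) are flagged as
strong differentiation; the boundary value itself is not flagged.

## Breeding impact

Lost/new/retained sets are plain set differences/intersections of the
haplotype sets observed in the landrace and modern-variety scopes. The
major-haplotype accounting runs on each scope's own major set, so a
haplotype rare in landraces but frequent in modern varieties counts as a
promotion ("new major") while remaining "retained" in the all-haplotype
accounting; a "retained major" must be major in both scopes.

The predominant-shift test forms a 2×2 carrier/non-carrier ×
landrace/modern table for the landrace-predominant haplotype and applies
Pearson's chi-square without continuity correction (correction available
by flag; at panel-scale counts it is immaterial). A zero margin is
degenerate: p is reported as 1 with a flag rather than as an error, so
monomorphic genes flow through the accounting. Significance of a shift
defaults to p < 0.05.

Panel-level percentages divide the mean per-locus lost/new counts by
supplied population-wide per-locus mean haplotype (and major-haplotype)
counts and are rounded to one decimal — the convention under which the
published accounting of the 24-locus comparison reproduces exactly.

## Haplotype networks

Distances between haplotypes are Hamming counts over their allele strings.
The network is a deterministic minimum-spanning construction: candidate
edges sorted by (mutation count, sorted label pair) and added Kruskal-style
iff they join distinct components. The closest-first connection rule is
what the deterministic MST implements; full statistical-parsimony
probability calculations are out of scope. Two options extend it: skipped
edges that belong to some other minimum spanning tree (weight equal to the
heaviest edge on the tree path they would close) can be retained as
"ambiguous" links, and a parsimony-style connection limit can refuse edges
above a mutation ceiling, leaving multiple components. Only major
haplotypes enter networks. Node annotations carry panel frequency and
per-population carrier counts (every population present, zeros included).

## Association and allele mining

Association is a plain one-way ANOVA of trait values across major-haplotype
groups — deliberately no kinship or structure correction, mirroring the
descriptive use of the statistic. Groups under `min_group_n` (default 2)
observations are dropped with a log entry; fewer than two eligible groups
makes the gene×trait pair not-testable. An all-equal response is reported
as F = 0, p = 1; zero within-group variance with distinct means as F = ∞,
p = 0. No multiple-testing correction is applied across genes or traits by
default (raw p with the 1e-7 "strong" convention, strict inequality);
Benjamini-Hochberg can be layered on by the caller.

The compact letter display is computed from pairwise procedures — Tukey
HSD on the studentized range by default, Duncan's multiple range test
(rank-span-dependent protection level $1-(1-\alpha)^{p-1}$, harmonic mean
group size for unbalance) as the alternative — by lettering the maximal
cliques of the "not significantly different" graph, ordered by descending
group mean. This guarantees the display property exactly: two groups share
a letter iff their pairwise test is non-significant.

Favorable haplotype: extreme mean trait value, direction configurable
per trait (default highest; the highest value of a yield component is not
always agronomically best, hence the switch); ties resolved by larger
carrier count, then label. Unfavorable haplotype: the major haplotype of
minimum frequency, the frequency-based reading of the concept; a
lowest-trait-value alternative is expressible via `favorable_hap(...,
direction="min")`. The predominant-vs-unfavorable contrast is a Welch
t-test, not testable when either group has n < 2.

## Synthetic panels

The generator emulates the features of a multi-population inbred panel the
pipeline depends on, at desk scale:

- **Haplotype pools with geometric decay.** Each polymorphic gene gets a
  per-population pool of distinct allele strings with frequencies
  proportional to $r^k$ (default ratio r = 0.7, pool size 12), producing
  one predominant haplotype plus a tail of rare ones — with this default
  the rarest pool members sit below the 1% major threshold, so promotion
  events are meaningful.
- **Divergence.** A configurable fraction of each population's pool is
  population-private; pool orders are independently permuted per
  population, so identity declines smoothly as the private fraction grows
  and reaches 0 at full divergence.
- **Monomorphic genes.** The first `round(fraction_monomorphic × n_genes)`
  genes carry no segregating CDS site at all (deterministic rounding, so
  tests can assert exact counts).
- **Breeding bottleneck.** A modern-variety population keeps a uniform
  random `bottleneck_retain` fraction of its parent landrace pool (so the
  expected lost fraction is 1 − retain), re-skews frequencies
  geometrically, occasionally promotes a parent-rare haplotype to a major
  rank (`rare_promotion_rate`), and gives each accession a novel
  single-crossover recombinant of two pool haplotypes with probability
  `recomb_rate`.
- **Phenotypes.** baseline + planted additive haplotype effects +
  Gaussian noise; effects are stated in units of the residual SD when
  `noise_sd = 1`. Effects are attached by rank in the base population's
  pool so a planted effect lands on a major haplotype.

All draws come from a single seeded generator; a config reproduces its
VCF/BED/TSV/JSON outputs byte for byte. What the generator does **not**
emulate: linkage between genes, coalescent genealogy, realistic
mutation-rate spectra, genotyping error or missingness patterns, and
population structure within populations. Passing recovery tests therefore
show the estimators are consistent under the generator's assumptions, not
that those assumptions hold for any real panel.

### Scenario presets (study conditions)

- **A_diversity** — 26 genes (2 monomorphic), four populations sized
  180/77/22/19 (the Xian/Geng/Aus/Bas panel in miniature, ≈1/10 of the
  subspecies proportions). Used for end-to-end pipeline checks.
- **B_bottleneck** — 24 polymorphic genes, landrace 700 / modern 300 with
  retention 0.5, recombination 0.02, rare promotion 0.05. Used for
  lost-fraction recovery (target 0.5 ± 0.05 across 10 seeds).
- **C_association** — 1,000 accessions, one polymorphic gene, one planted
  1-SD effect on the second-ranked (major) haplotype. Used for
  favorable-allele recovery (≥ 9/10 seeds at p < 1e-7). The null
  false-positive control uses a custom no-effect configuration of 25 genes
  × 20 traits × 2 seeds (1,000+ gene-trait pairs at n = 300).

## Numerical choices and degenerate inputs

- Frequency-vector validation tolerates 1e-9 deviation from sum 1; the
  major threshold comparison is inclusive with a 1e-12 guard; equitability
  is clipped into [0, 1] against rounding.
- Tie-breaks are total and documented everywhere (allele string for labels
  and predominance, sorted label pair for network edges, carrier count then
  label for favorable calls), making every output order-invariant and
  reproducible.
- Degenerate inputs prefer flagged results over exceptions where a
  scientific meaning exists (degenerate chi-square table → p = 1 + flag;
  single-group ANOVA → not-testable; empty major set → no unfavorable
  call), and raise `InputError` where none does (empty scope, zero
  frequency vector, unequal string lengths).

## Known limitations

- The pipeline is haplotype-identity based: no protein-consequence
  annotation, no FST/π/Tajima's D, no median-joining networks with inferred
  intermediates, no mixed-model association.
- Carrier counts for the 2×2 shift test are reconstructed from rounded
  frequencies times scope size; exact for the package's own outputs, and
  accurate to ±1 carrier if frequencies were externally rounded.
- The lost/new/retained accounting operates on *observed* haplotype sets;
  with small samples, rare haplotypes missing from a sample inflate
  apparent losses. The recovery test quantifies this at the preset sample
  sizes.
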