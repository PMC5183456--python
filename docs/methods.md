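# Methods

This document describes what each stage computes and the design decisions
behind the non-obvious choices. Thresholds and their boundary semantics are
stated explicitly because several are deliberately asymmetric.

## Event detection and simulation

A transduction event candidate is a prophage-resident gene annotated as
bacterial (`gene_class == "bacterial"`). The simulator plants such events by
copying a donor CDS into a prophage of a recipient, optionally mutating it
with a controlled non-synonymous/synonymous ratio (`omega_true`) and a
Poisson-distributed substitution count (`n_subs_per_event`). Genomes evolve
along a random species tree; GC content drifts along branches; prophages are
drawn from a small pool of unrelated ancestral phage types so that prophages
of the same type cluster together while viral genes never collide with the
bacterial gene pool. Recipient choice follows a similarity kernel
(probability ∝ exp(−strength × patristic distance)); with
`similarity_kernel_strength = 0` the realized donor–recipient similarity
distribution matches the all-pairs background. A ground-truth ledger records
donor, recipient, carrying prophage, family, and planted substitution count
for every event, enabling exact recovery tests.

## Sequence comparison

* **Global alignment** uses the Gotoh affine-gap algorithm (gap open 10, gap
  extend 0.5, match 1 / mismatch 0). Percent identity is matches over aligned
  columns. A banded identity upper bound (via edit distance) prefilters
  all-against-all comparisons; the margin is conservative so the prefilter
  never discards a pair that full alignment would accept.
* **Genome similarity** (`s_gs`) is the Jaccard index of canonical 20-mer
  sets; `s_cds` restricts the k-mers to coding regions. Both are computed on
  **prophage-masked** chromosomes: prophages are mobile cargo, and leaving
  them in lets the transferred genes themselves (and shared phage backbones)
  masquerade as host similarity. Masking restores the kernel-off null (all
  predictor AUCs ≈ 0.5) without touching the measures or the generator.
* **GC similarity** is 100 minus the absolute GC% difference. **Codon usage
  distance** (`d_cu`) is the Euclidean distance between relative synonymous
  codon-usage profiles computed over chromosomal (non-prophage) CDS.

## Clustering

Prophage proteins are compared all-against-all; pairs from different genomes
at **≥ 95.0% identity** with reciprocal best-hit status become edges (94.9%
is excluded) weighted by identity. Protein families are connected components
of Markov clustering (expansion 2, inflation 2). Each node's self-loop is set
to its maximum incident edge weight (floor 1.0): with a fixed unit loop, a
heavily weighted two-node edge oscillates under expansion and identical
protein pairs are wrongly split into singletons.

Prophages are then described by their family content and merged into
orthologous **phage entities** by single-linkage at content Jaccard
**strictly > 0.7** (a pair at exactly 0.70 stays separate). Prophages with no
bacterial-flagged gene are excluded from entity formation but counted as
singletons.

## Donor inference

For each candidate gene, homologs are gathered at **≥ 90.0% protein
identity** (90.0 is included). Distances are Poisson-corrected protein
distances; families whose distances saturate are excluded. A neighbor-joining
tree is built and midpoint-rooted. The donor call logic:

* no homolog → excluded (`no_homolog`);
* exactly one homolog → that genome is the donor (`pair`);
* otherwise, if the query's sister group is a single leaf or a clade from one
  genome, that genome is the donor; if the query nests inside a clade of
  recipient-genome copies, the event is an autolog candidate.

Calls are validated with a **consolidation test**: the unconstrained NJ tree
is compared against an NJ tree constrained to place the query with the
recipient clade, using per-site log-likelihood differences under a Poisson
model and a bootstrap of site resamplings (an RELL-style approximation — the
topologies are fixed and only sites are resampled, which is orders of
magnitude cheaper than re-estimating trees per replicate). Calls where the
constrained placement is not significantly worse are treated as unresolved
rather than forced.

NJ with midpoint rooting is used instead of a full ML tree search, and NG86
instead of ML codon models (below): at ≥ 90% identity within a family the
distances are short and nearly additive, where NJ is consistent, and the
ledger-recovery tests confirm the cheap estimators suffice.

## dLGT network

Events become a directed network with bacteria and phage entities as nodes:
a **D edge** donor→phage and an **R edge** phage→recipient per event, with
multiplicities as weights (donor-less events contribute only their R edge).
The package reports weakly connected components, degree distributions per
subset (full, D-only, R-only), an autolog census, and the deepest shared
taxonomic rank of each donor–recipient pair (host range).

## Randomization

Null networks preserve the bipartite structure exactly: edges are rewired by
repeated **pair switching within each direction class** (a D edge is only
swapped with another D edge, R with R), which preserves every node's in- and
out-degree and the per-class edge-weight multiset exactly, because weights
travel with the rewired edges. Note what is *not* preserved: per-node
in-strength (weighted in-degree) cannot be held fixed by any switching null
that moves integer-weighted edges, so significance statements are about the
degree structure, not the strength sequence. Empirical p-values use the
add-one estimator (r + 1)/(n + 1), so p is never zero.

## Barriers

* **ROC analysis** scores how well each pairwise measure separates connected
  donor–recipient pairs from unconnected background pairs. AUC equals the
  normalized Mann–Whitney count of concordant pairs (ties count ½). Codon
  usage distance is sign-inverted (smaller = more similar); habitat sharing
  is a binary predictor, for which AUC reduces to (TPR + 1 − FPR)/2.
* **Habitat transfer matrix**: counts of donor-habitat × recipient-habitat
  over resolved events; the same-habitat fraction is tested against the
  degree-preserving null ensemble.
* **Functional composition**: transferred genes vs chromosomal background by
  functional category, χ² test with a Fisher exact fallback for sparse
  tables, and per-habitat per-category post-hoc tests corrected by
  Benjamini–Hochberg FDR.
* **Similarity by category**: one-way ANOVA with Tukey HSD post-hoc on
  donor–recipient similarity grouped by the transferred gene's category.

## Selection

Pairwise dN/dS follows the Nei–Gojobori (1986) method: synonymous and
non-synonymous sites are counted fractionally per codon, multi-step codon
differences are averaged over all substitution pathways that avoid stop
codons, and proportions are Jukes–Cantor corrected. Pairs with p ≥ 0.75 are
flagged saturated. **Autologs** (donor = recipient) give a natural paired
design — the genomic copy is a same-genome reference for the prophage copy —
so purifying selection is tested as a one-sided Wilcoxon signed-rank test of
dS > dN across autolog pairs, complemented by a paired comparison of codon
adaptation index (CAI, geometric mean of relative adaptiveness under the
recipient's chromosomal usage).

## Defaults and problem sizes

The study conditions are the simulator defaults: 50 genomes, 250 CDS per
genome (so 200 events can be planted without family reuse), 200 events, 9%
autologs, kernel strength 10, planted dN/dS 0.12, tree depth 0.3
substitutions/site, GC range 35–65%. Pipeline defaults: RBH identity 95%,
homolog identity 90%, orthology Jaccard 0.7, k = 20, 1000 null replicates at
100 swaps per edge, α = 0.05, FDR 0.05, 10 000 consolidation bootstrap
replicates. The test suite scales some scenarios down (e.g. 8–20 genomes for
I/O and property tests) as its own choice of problem size; the acceptance
checks run at the full study scale.

What the simulator does **not** emulate — and hence what passing tests do not
show about real data: real gene annotation and prophage-boundary errors,
recombination within genes, horizontal transfer by mechanisms other than
transduction, compositional amelioration of transferred genes over time, and
genuinely shared ancestral prophages between related strains. Recovery rates
on real genomes will be lower than on the ledger.

## Determinism

Every stochastic step takes an explicit seed; ties are broken
lexicographically; artifacts are emitted with sorted keys and sorted rows.
Two runs of the full pipeline with the same dataset and seed produce
byte-identical output files.
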