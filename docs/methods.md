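# Methods

This document specifies the estimators and algorithms implemented by
`isoanchor`, exactly as computed, with the rationale for each design choice
and the known limitations.

## Anchored and family-specific marker sets

A *marker set* is an ordered collection of genes expected in single copy
across a taxonomic group. Given a closed, complete isolate genome (the
*anchor*), the **anchored set** is the base set restricted to markers the
anchor carries (copy count ≥ 1). Markers the anchor lacks cannot be
expected in any member of its lineage; they are excluded and recorded with
reason `absent-from-anchor`. The operation is idempotent and its provenance
(parent set id plus per-marker exclusion reasons) travels with the derived
set.

**Family-specific sets** extend the same logic to lineage-wide losses the
anchor alone cannot reveal. For each family, the prevalence of every marker
of the anchored set is computed across the family's *environmental* genomes
(the anchor is excluded from screening: a single complete genome would mask
genuine family-wide absences, and its completeness is not representative of
the collection). A marker with prevalence strictly below 0.10 is flagged as
a `systematic-absence(family)` and removed. The strict `<` tolerates rare
spurious hits while never flagging at exactly the threshold; a threshold of
0 therefore flags nothing. An optional completeness-weighted variant
divides raw prevalence by the collection's mean completeness (capped at 1)
to correct for dropout in incomplete genomes.

## Completeness, contamination, and genome size

* **Completeness** = 100 × (set markers present with copy ≥ 1) / |set|.
  This is deliberately the *simple fraction*, not a collocated-set weighted
  estimator in the style of CheckM. The simple fraction is fully specified
  and reproducible, and it makes marker-set substitution arithmetically
  transparent: re-scoring a genome against a corrected set changes its
  size estimate by exactly the completeness ratio. Collocation-weighted
  estimators require an unpublished marker co-occurrence structure and give
  systematically different values; they are out of scope.
* **Contamination** = 100 × Σ max(copies − 1, 0) / |set| — the mean number
  of *extra* copies per set gene.
* **QC filter**: a genome passes only with completeness strictly above 80%
  AND contamination strictly below 5%. Both boundaries are exclusive: a
  genome at exactly 80% fails.
* **Genome size** = assembly_length / (completeness / 100). A closed
  genome at 100% completeness is its own size estimate; the same 1.62 Mbp
  assembly stays 1.62 Mbp. Because corrected marker sets raise completeness,
  they shrink inferred sizes — e.g. an estimate of 1.18 Mbp at 84.2%
  completeness becomes 1.18 × 84.2 / 94.6 ≈ 1.05 Mbp when the family set
  raises completeness to 94.6%.

## Sketch ANI and species clustering

Genomes are reduced to **bottom sketches**: the smallest 5000 distinct
64-bit hashes (splitmix64 finalizer) of canonical 21-mers (lexicographic
minimum of each k-mer and its reverse complement; k-mers containing non-ACGT
characters are skipped, and k-mers never span contig joins). For two
sketches the Jaccard similarity J is estimated over the union's smallest s
hashes; under a Poisson substitution model the shared k-mer fraction
w = 2J/(1+J) relates to per-site divergence d by w ≈ e^(−kd), so

    ANI = 100 × (1 + ln(2J/(1+J)) / k).

J = 0 is reported as ANI 0 with a `saturated` flag — the true distance is
merely beyond the sketch's resolution, and saturated pairs are treated as
missing (below any threshold) downstream.

**Species clustering** is greedy centroid clustering at ANI ≥ 93%:
genomes are visited in descending quality priority (completeness − 5 ×
contamination, then assembly length, then id), each new representative
absorbing every unassigned genome at or above the threshold. There is no
transitive chaining. The **expanded set** keeps the representatives plus
every member *strictly below* 99% ANI to its representative: a member at
98.9% is distinct within-species diversity, one at 99.0% a near-duplicate.

## Relative evolutionary distance and ranks

On a rooted tree with branch lengths, RED(root) = 0, RED(leaf) = 1, and for
an internal node n with parent p,

    RED(n) = RED(p) + (d / u) × (1 − RED(p)),

where d is the branch p→n and u the mean path length from p to its
descendant leaves (computed by weighted postorder means; values clamped to
[0, 1]). RED is invariant under global branch-length rescaling. Trees must
arrive rooted; no rerooting or averaging over rootings is performed, and a
subtree whose mean leaf distance is zero is an error.

Internal non-root nodes whose RED falls in a rank's half-open interval
[lo, hi) receive that rank (defaults: family [0.25, 0.55), genus
[0.65, 0.90)). When an ancestor and descendant both qualify for one rank,
the node nearer the interval midpoint wins by default; a "highest node
wins" rule is available.

## Read recruitment

Inputs are per-sample, per-genome mapping summaries (mapped reads, covered
positions, genome length, total sample reads); competitive mapping happens
upstream (a SAM ingestion helper counts primary alignments only).
**Detection** is breadth of coverage (covered / length). **Relative
abundance** is 100 × mapped / total-sample-reads, zeroed wherever detection
falls below 0.25 — low breadth with non-trivial read counts is the
signature of spurious recruitment to conserved regions. Abundances roll up
additively genome → genus → family → order and are averaged within depth
bins ([0,100), [100,200), [200,300]; the last bin right-closed) and regions.

## Group statistics

Kruskal–Wallis (tie-corrected midranks, chi-square approximation; scipy)
tests whether any group differs; all-identical data returns H = 0, p = 1,
and groups smaller than 5 trigger a warning. When the omnibus test is
significant, Dunn's pairwise z on pooled midranks with the tie term
T = Σ(t³ − t)/(12(N − 1)) locates the differences, with Holm step-down
adjustment by default. Both are invariant under strictly monotone
transformations of the data.

## Synthetic data generator

Every pipeline input can be generated with the answers recorded
(`ground_truth.yaml`). All stages draw from independent seeded streams, so
the same seed yields byte-identical bundles and changing one stage's
parameters does not reshuffle another's draws.

* **Taxonomy**: 4 families with (10, 4, 4, 4) genera (22 total), 3 genomes
  per genus plus the anchor as a basal leaf of the last family. The tree is
  ultrametric with family nodes at depths in (0.30, 0.50) and genus nodes
  in (0.70, 0.85); on an ultrametric tree RED equals relative depth, so the
  planted nodes land inside the default rank intervals by construction.
* **Markers**: a 280-marker universe; 28 anchor-absent markers lost from
  every genome including the anchor; family extra losses (12, 24, 11, 1)
  planted only in environmental genomes, so the anchor's family set exceeds
  the anchor's own inventory by one marker. Retained markers are single
  copy with a 0.5% duplication rate.
* **Incompleteness**: per-genome completeness c from Beta(5, 2) rescaled
  onto [0.6, 1] (mean ≈ 0.89); markers retained i.i.d. with probability c
  (a "block" mode drops a contiguous chromosomal arc instead), genes
  binomially, assembly length = true length × retained gene fraction. True
  lengths are Normal(1.3 Mbp, 0.15 Mbp); the anchor family's %GC is
  Normal(36.3, 0.5), other families Normal(34.5, 1.0).
* **Sequences**: one 30 kb sequence per genome evolved by i.i.d.
  substitution along family/genus/leaf branches. Branch rates are inverted
  from the divergence ladder 0.02 / 0.10 / 0.25 (within genus / within
  family / between families), composed via p ⊕ q = p + q − (4/3)pq, placing
  within-genus ANI near 98% (above the 93% species threshold, below the 99%
  dereplication threshold) and between-genus ANI near 90%.
* **Recruitment**: 3 regions × depths {5, 50, 90, 150, 250} m × 3
  replicates, 10⁷ reads of 150 bp per sample. The order total declines
  linearly from 4.5% at the surface to 2.5% at 300 m (×1.3 in the
  Mediterranean-like region); family shares start at (0.50, 0.12, 0.25,
  0.13) with exponential depth gradients (−0.8, −0.7, −0.6, +1.2) per
  100 m — three surface-enriched families and a deep-enriched anchor
  family. Genus shares within a family are one Dirichlet(1) draw; mapped
  reads are multinomial and covered positions follow the Poisson breadth
  L(1 − e^(−coverage)).

### What the generator does and does not emulate

Substitution is i.i.d. with no indels, rate heterogeneity, or
recombination; marker dropout is i.i.d. (or block) rather than
assembly-graph-shaped; recruitment has no read errors or mapping bias.
These simplifications are what make the planted parameters exactly
recoverable, which is the point: the acceptance suite checks the estimators
against the planted answers, not against biology.

## Pipeline determinism and limitations

The pipeline runs markers → qc → cluster → red → recruit → stats, fails
fast with the stage name on error, and writes a `manifest.yaml` without
timestamps: identical inputs give byte-identical outputs. RED is computed
on the full input tree, not re-pruned to QC survivors, so rank recovery is
a property of the consumed tree.

Known limitations: completeness is the simple fraction (see above);
sketch ANI saturates for very distant pairs (J = 0) and carries a small
positive bias (≪ 1 percentage point at 5% divergence with k = 21, sketch
5000); the recruitment model's detection gate means taxa whose genomes all
fall below 25% breadth contribute zero abundance by design.
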