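# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic cohorts do and do not emulate, and the
design decisions taken where the underlying protocol left the choice open.

## Genome model and I/O

A cohort is a set of `GenomeRecord`s: named contigs, CDS features with
1-based inclusive coordinates, and per-genome metadata (species, genus, one
of six isolation-source categories, CheckM-style completeness and
contamination percentages). GFF3 is parsed with gffutils; the `gene`,
`product` and `note` attributes are matched case-insensitively and
multi-valued attributes are joined with `"; "` before any screening, so the
annotation text the regex stage sees is a deterministic function of the
file. Translations come from the supplied protein FASTA keyed by locus tag;
features missing from it are self-translated with bacterial table 11
(minus-strand spans reverse-complemented, trailing stop trimmed, ambiguous
codons rendered as X, start codons translated as the annotated residue so a
supplied protein FASTA and a self-translation never disagree on position 1).
A CDS referencing an unknown contig is a hard error; a CDS whose span is not
a codon multiple is skipped with a warning rather than silently mistranslated.
Conversion to half-open coordinates is confined to this module.

## Assembly QC

N50 is the contig length at which the cumulative sum of
descending-sorted contig lengths first reaches half the assembly; GC% counts
G+C over unambiguous bases only (ambiguity codes leave both numerator and
denominator). The inclusion gate applies four criteria: whitelisted assembly
level and not MAG/single-cell derived (metadata flags — these are
retrieval-time properties, not computable from sequence), at most 200
contigs unless contig N50 ≥ 50 kb, completeness ≥ 95% and contamination
≤ 5%. All thresholds are inclusive on the stated side — the literal reading
of the printed inequalities — and the gate is monotone: improving any single
metric never flips a pass into a fail. Species with fewer than 10 passing
genomes are dropped; an empty cohort halts the pipeline with an explicit
error rather than emitting empty tables.

## Marker screening

The marker panel is a TSV of (marker_id, regex, target fields, category,
subcategory) compiled case-insensitively. Word boundaries and synonym
alternations are encoded in the patterns themselves; the engine does plain
substring search, keeping the panel the single source of matching
semantics and fully replaceable by a user panel. One CDS can hit several
markers (all hits kept — abundance roll-ups are reported at category level
and no precedence rule is defensible), but never twice for the same marker.
The packaged taxonomy groups markers into the major functional categories
used in collapsed-heatmap summaries (cold/heat stress tolerance,
defense/CRISPR-Cas, carbohydrate utilization and transport, cell
envelope/EPS, acid tolerance/energy metabolism, amino-acid/general
metabolism, vitamin/cofactor biosynthesis, bacteriocin/antimicrobial
peptides); it ships as editable data, not code. The *dltA* entry is a
reconstruction: it appears in the validation-marker subset without a printed
screening pattern, so the panel carries a D-alanylation annotation pattern
for it. Matrices support genome or species rows; marker, subcategory or
category columns; presence, count or proportion values. Proportion rows
divide by the row total; zero-hit rows stay all-zero and are flagged rather
than renormalised.

## Sequence confirmation

Candidates are aligned with exact Smith–Waterman (no heuristic seeding —
reference panels are small enough that the exact optimum is affordable)
under BLOSUM62 with affine gap costs 11 + k for a gap of length k, the
BLASTp defaults. Conventions, stated because tools differ:

* percent identity = identical aligned pairs / alignment columns, gap
  columns included (the conservative choice);
* query coverage = aligned query span / query length;
* E = K·m·n·e^(−λS) with the standard gapped BLOSUM62 constants λ = 0.267,
  K = 0.041, m the query length and n the summed length of the marker's
  reference set. Only the decision threshold (E ≤ 1e−5) is contractual; the
  statistics are not meant to reproduce BLAST's composition-adjusted
  E-values.

A hit is confirmed when identity ≥ 40%, coverage ≥ 0.70 and E ≤ 1e−5, all
boundaries inclusive. The best reference is chosen by raw score, ties broken
by E-value then accession, so outcomes are deterministic. Markers without
references yield an explicit `NO_REFERENCE` outcome. Concordance per marker
is confirmed/candidates; a marker with zero candidates is reported as NA,
never 0%. An adapter ingests external 12-column tabular alignments for users
who ran their own search. The aligner engine is Biopython's
`PairwiseAligner`; the test suite checks its scores against an independent
hand-written affine-gap dynamic program on hundreds of random peptide pairs,
and re-derives identity and coverage from the raw traceback blocks.

## Safety screening

Two alignment panels filter tabular hits: AMR at coverage ≥ 0.50 and
identity ≥ 90, virulence factors at coverage ≥ 0.70 and identity ≥ 90,
boundaries retained. Coverage is treated as query-relative (the convention
is unstated in some upstream tools; the choice is flagged here and in output
headers). Rows missing either value are rejected with reason `MALFORMED`
rather than dropped. Two term panels scan annotation text with the same
semantics as the marker screen: biogenic-amine decarboxylases and
transporters (hdcA, tdc/tyrDC, odc, cadA, tyrP) and hemolysins/cytolysins
(word-boundary-anchored `hly*`/`cyl*` gene symbols plus hemolysin/cytolysin
product terms — "crystallin" does not match). Prevalence is the percentage
of a species' genomes carrying at least one retained hit for a gene, copy
number ignored. The module reports; it draws no safety verdict (source
descriptions of classical-virulence-factor findings are internally
inconsistent, so the artifact stays descriptive).

## Bacteriocin profiling

Only structural-role hits create loci. Within one genome, contig and
bacteriocin name, hits overlapping by more than 50% of the shorter span
merge transitively (union span, best score); identical duplicates are
removed first. The 50% fraction is a config parameter — the source protocol
says only "overlapping or redundant". Consolidation is idempotent.
Subclasses come from a packaged, editable name → subclass table covering
every bacteriocin named in the published species summary (normalised by case
and whitespace; unmapped names become "other"). Counting is structural-locus
based; whether published abundance counts whole clusters is unstated, so the
narrower, better-defined quantity is used. The species summary reports
% of genomes with ≥ 1 locus, total locus count, distinct names, top-3
dominant names (ties lexicographic) and a producer tier: strong at ≥ 500
total loci, moderate strictly between 50 and 500, low/none otherwise. The
tier thresholds are inferred; the published 35-row species table ships as
package data and the rule is checked against every row.

## CAZyme aggregation

The dbCAN DIAMOND-workflow rule: per query keep the single hit with the
highest bit score (ties: lowest E-value, then lexicographic subject), then
keep it only if E < 1e−102, strictly. Subject-label dialects "GH13",
"GH13_31" and "ACC|GH13(…)" are parsed; the family is normalised to its base
with the subfamily kept in its own column, and the class is the alphabetic
prefix. Unparsable labels are dropped with a logged warning. Whether
multi-domain proteins should count more than once is unstated upstream;
top-1 per protein is enforced as written. The search itself is external; the
synthetic generator emits tabular hits with a known best-hit structure.

## Pan-genome

Greedy centroid clustering (CD-HIT style) stands in for a full
CD-HIT + BLAST + MCL pipeline: proteins visited longest-first (ties by id)
join the first centroid reached at ≥ 95% local-alignment identity with ≥ 80%
coverage of the shorter sequence, else found a new family. The 80% coverage
floor prevents domain-level chaining and is exposed in config. Agreement
with single-linkage clustering is guaranteed only for well-separated
families (within-family identity far above, between-family far below the
threshold), which the synthetic fixtures provide and the tests verify; on
real twilight-zone data greedy and single-linkage can differ. A shared
5-mer prescreen skips alignments that cannot plausibly reach the threshold;
it is a pure speed-up on separated data. Paralogs may share a family;
prevalence counts distinct genomes. Partition: soft-core ≥ 95% prevalence,
shell 15–95%, cloud < 15% (no additional strict-core tier is defined).
Accumulation curves average cumulative distinct-family counts over seeded
random genome orderings (default 100 permutations) and report quartiles;
the final-step mean increment estimates the per-genome novel-family rate.
Unique genes are families private to one genome.

## Synthetic cohorts

The generator's defaults are the study conditions for every end-to-end
test: 3 species × 12 genomes, genome lengths 60–90 kb and GC sampled in
0.32–0.53 (the genomic spread of the real family, scaled down ~30-fold so a
cohort builds in seconds), six isolation-source categories with a realistic
weight on "missing" metadata, ~90 core families, a 40-family accessory pool
at rate 0.35, 5 private genes per genome plus filler singletons up to the
target length — an open pan-genome by construction. Background sequence is
i.i.d. at the target GC: codon choice is steered so each coding sequence
lands near the genome's GC target, intergenic spacers (≥ 50 bp) get an
exact-proportion fill, and a degenerate GC range is honoured to within
about half a percentage point.

Planted features all carry manifest entries. Markers plant in three modes:
exact reference copies, substitution-diverged copies whose realized identity
equals the target to within rounding (substitutions only, so coverage stays
100% and identity is controlled independently; targets below 5% are
rejected as uncontrollable), and decoys — marker-consistent annotation text
on an unrelated random sequence. The default plan mixes exact plants across
the panel with 60%-diverged *dnaK* and *bsh*/*srtA* decoys so that
confirmation has true positives, borderline positives and true negatives to
separate. Reference "curated" proteins are synthetic, derived
deterministically from the marker id (stable across runs and machines).
Manifest identity for a plant is identical-pairs / query-length — a
near-global measure that is 100 for exact copies, ≈ target for diverged
copies and small for decoys even when a short local alignment is itself
high-identity. Bacteriocin plants write structural loci plus a raw hit
table with redundant overlapping duplicates and immunity/transport rows to
exercise consolidation; safety plants control identity and coverage exactly
(alignment panels) or plant annotated gene symbols (term panels); CAZyme
tables plant a known best hit per query with weaker secondary hits and a
15% tranche of above-cutoff E-values.

What the cohorts do **not** emulate: phylogeny, recombination, codon usage,
indels, truncated or frame-shifted genes, annotation noise (typos,
inconsistent nomenclature), contamination, or realistic intergenic
structure. Passing tests therefore demonstrate that the rules and
aggregations are implemented correctly — not that the regex panel's
sensitivity/specificity on real Prokka annotations matches its behaviour on
the lexicon-generated text.

## Determinism and problem sizes

A single top-level seed derives per-stage seeds (all below 2³¹) via a seed
sequence; identical config and inputs give byte-identical output bundles,
which the suite checks by hashing two complete runs. Problem sizes used by
the tests and the acceptance script — 36-genome cohorts, 15-genome
core/unique clustering fixtures, 100-permutation accumulation curves,
200-pair alignment oracles — were chosen as the smallest sizes at which
every planted structure is still unambiguous; all are parameters, not
limits.

## Known limitations

Regex screening inherits annotation quality; the confirmation stage bounds
false positives only for markers with references. E-values are classical
Karlin–Altschul, not composition-based. Greedy clustering is
order-dependent by design (the order is fixed and documented). The producer
tiers are an inferred rule that exactly reproduces the published table but
has no mechanistic meaning. Term-panel safety screening cannot distinguish
functional genes from pseudogenes.
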