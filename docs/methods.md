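# Methods

## Scope and model

`syngc` quantifies the association between three per-gene properties of
plant genomes: whether a gene has remained at its ancestral chromosomal
position (synteny), its third-codon-position GC content near the start
codon (GC3-50), and the bisulfite methylation of its 5′ end. The package
takes gene models (GFF3 + CDS FASTA), precomputed homolog anchor pairs,
per-cytosine methylation tables and an optional gene→GO map; homology
search itself (tblastx/BLASTP-style steps) is out of scope — anchors and GO
annotations are inputs.

## Synteny

Anchors are chained per chromosome pair and orientation. A chain must be
strictly increasing in genome-A gene rank and strictly monotone in genome-B
rank (ascending for orientation `+`, descending for `-`), with consecutive
rank gaps of at most `max_gap` (default 20) in both genomes. Chains with
fewer than `min_anchors` anchors (default 7, the conventional floor that
separates conserved segments from chance collinearity) are discarded.

Chains are extracted best-score-first from a longest-chain dynamic program,
removing each extracted chain's anchors so that no anchor enters two
blocks; ties break deterministically by start ordinal, then `+` before `-`.
For chromosome pairs with at most `exact_max_anchors` anchors (default 12)
the chainer instead solves the disjoint-chain packing exactly (memoised
subset search maximising total chained anchors): at that scale the exact
optimum is affordable and removes the rare configurations where greedy
extraction of the single longest chain blocks two shorter chains whose
union is larger. Scoring is anchor count only; similarity weighting is
deliberately not used because block size is the only criterion the analysis
depends on.

Tandem arrays — genes on one chromosome within `tandem_window` (default 10)
ordinals sharing an anchor partner, taken to transitive closure — are
collapsed to their lowest-ordinal member before chaining, and the
representative's block membership is propagated back to every member.
Self-comparisons drop the identity diagonal first, so self-synteny reflects
retained polyploid duplicates only. A gene is syntenic iff it belongs to at
least one block in at least one comparison.

One-to-many anchors are allowed into the DP; disjointness is enforced only
at block assignment. Quota or Ks filtering, syntenic depth and ancestral
reconstruction are out of scope.

## GC3 metrics

`gc3_50` is the G/C fraction among the third bases of codons 1–50. Codon 1
(ATG) is included: the definition reads most naturally as the literal first
50 codons, and its fixed G shifts every gene identically (+0.02 floor), so
no between-group comparison is affected. Values therefore live on the 2 %
lattice {0, 0.02, …, 1.00}. `gc3_full` covers all complete codons but
excludes a terminal stop codon (stops are constrained — two of three end in
A — and would bias short genes). CDS filters, applied before any GC3 value
is computed, in fixed precedence: fewer than 50 complete codons
(`too_short`), first codon ≠ ATG (`no_atg`), any non-ACGT character
anywhere in the CDS (`ambiguous_base`); soft-masked lowercase is uppercased
first. The positional profile reports, per codon index, the mean G/C
indicator across genes long enough to contribute.

## Copy number

The first 150 bp of each CDS (the same 5′ window the methylation analysis
uses) is searched against the assembly with an ungapped seed-and-extend
matcher: exact 12-mer seeds on both strands, one ungapped alignment per
candidate diagonal, accepted at ≥ 90 % identity over ≥ 90 % of the query —
an operational stand-in for a high-stringency BLASTN cutoff. Accepted hits
whose spans overlap by ≥ 50 % (of the shorter span) merge into loci, so a
locus hit on both strands or by staggered HSPs counts once. A precomputed
BLAST tabular file (E < 1e-30) can substitute for the internal matcher and
is counted with the same locus-merging rule. Hit counts bin as
1 / 2–9 / 10+ → single / moderate / repetitive; the gene's own locus
guarantees ≥ 1.

## Methylation

Cytosine context is read 5′→3′ on the cytosine's own strand: CG if base 2
is G; CHG if base 2 ∈ {A,C,T} and base 3 is G; CHH if bases 2 and 3 are
both in {A,C,T}. At a sequence end CG is still decidable one base short;
CHG/CHH are not and such sites are excluded. Context strings in allc input
are trusted as given (collapsed from trinucleotides); when a genome
sequence is available the simulator-side contexts are assigned from it
directly.

The weighted level of a region is Σ m_reads / Σ total_reads over covered
context cytosines of both strands inside the region — equivalent to a
coverage-weighted mean of per-site levels, and invariant under splitting or
merging reads at a site. The region is the first 150 bp of the transcript
in transcription direction, from the annotated transcript start (for
simulated data, the CDS start). Zero-coverage sites contribute nothing;
a context with no covered sites is NA.

Class summaries (syntenic vs non-syntenic; copy classes) are **unweighted
means across genes** of per-gene weighted levels, not pooled read counts:
each gene counts once regardless of depth. This convention matters when
comparing against externally tabulated per-gene averages and is applied
consistently everywhere.

## Association statistics

Group comparisons use the two-sided Wilcoxon rank-sum test. The exact path
builds the permutation distribution of the rank-sum with a subset-sum DP
over doubled midranks (exact with ties) and defines the two-sided p as the
probability of a rank-sum at least as far from its expectation as observed.
Auto mode uses the exact path when the smaller sample has ≤ 10 observations
and the pooled data are tie-free, otherwise the tie-corrected normal
approximation with continuity correction (scipy's asymptotic
Mann–Whitney). Correlations are reported with both Pearson and Spearman
(the choice is not obvious a priori; Pearson is designated primary),
p-values from the t-transform; pairs with missing values are dropped and
zero-variance inputs return NA.

GC3-50 histograms use the statistic's natural 2 % lattice with no
smoothing. Methylation-by-GC3 curves report, per 2 % bin and context, the
unweighted mean of per-gene levels plus the total covered context-site
count; bins with fewer than 200 context sites are flagged not-shown to
suppress noise from sparse bins.

GO enrichment: the universe is genes with both an annotation and a synteny
status; terms with ≥ 20 annotated genes in that universe are tested
one-sidedly in each direction with the hypergeometric distribution, the
more enriched direction reported. Significance uses the raw p at 0.01 —
deliberately uncorrected, since the cross-species summary (how many species
are significant per term and direction) is the quantity of interest;
Benjamini–Hochberg values are emitted as an extra column. GO DAG
propagation is out of scope.

## Synthetic data

The generator produces an ancestor of `n_chromosomes × genes_per_chromosome`
genes, splits it into two lineages and applies, per lineage: inversions and
translocations (contiguous segments, lengths uniform in 10–40 genes),
tandem duplications (adjacent copy, same class), dispersed duplications
(copy at a random locus; the source is drawn with 4:1 odds from the
duplication-prone class; with probability 0.5 the original is subsequently
lost — the canonical route out of synteny), and random losses. Anchors are
emitted for all homologous pairs, duplicates included.

Coding sequences start with ATG and draw each further third base G/C with
probability equal to the class target — 0.92 for the duplication-resistant
class and 0.40 for the prone class, reproducing the bimodal grass-like
GC3-50 distribution with modes near 94 % and 40 % (codon 1's fixed G makes
the expected GC3-50 equal 0.98·target + 0.02). First/second codon positions
use a stop-avoiding alphabet (when position 1 is T, position 2 is
restricted to C/T), excluding TAA/TAG/TGA deterministically rather than by
rejection sampling. Genes are laid out on chromosome sequences with 300 bp
random spacers, random strand per gene, giving copy-number search and
methylation a real coordinate space.

Bisulfite calls: per gene and context a true level is drawn from a
class-specific Beta distribution (CG means 0.30 prone / 0.10 resistant,
CHG 0.15 / 0.03, CHH 0.05 / 0.01 — preserving the usual CG > CHG > CHH
ordering of gene-end methylation and the higher methylation of
duplication-prone genes); every cytosine of both strands in the 5′ 150 bp
then receives Binomial(read_depth = 30, level) methylated reads.

Ground-truth blocks are maximal runs, in genome-A order, of
ancestral-locus copy pairs staying on one B chromosome with monotone
ordinals and rank gaps ≤ 20, plus an absorption pass: a pair orphaned at a
rearrangement junction that still extends a neighbouring run under the same
gap/monotonicity rule joins it (rearrangement endpoints occasionally land,
by coincidence, within the gap tolerance of another conserved segment).
Runs of ≥ 7 pairs are truth blocks; tandem copies adjacent to an in-block
primary inherit its status, mirroring how the detector propagates status
through collapsed arrays. Overlapping rearrangements can carve inverted
remnants at exactly the 7-anchor floor where the greedy detector and this
independent definition legitimately disagree on one or two anchors; at the
generator's default scale this affects ≲ 1 % of block anchors.

Default study conditions: 3 chromosomes × 1000 genes, 65 %
duplication-prone, 8 inversions, 4 translocations, 600 dispersed and 100
tandem duplications, 150 losses per lineage. The dispersed-duplication
pressure gives roughly a 2:1 syntenic:non-syntenic split, and the prone
fraction was calibrated once (over three seeds, then frozen) so that the
realized syntenic-minus-non-syntenic GC3-50 gap is ≈ 0.12 — the magnitude
of the difference reported between the two gene classes of grass genomes —
with the class GC3 targets held at their bimodal 0.92/0.40 modes.

A single seed drives deterministic per-stage substreams
(`numpy.random.SeedSequence.spawn`), so identical configs give
byte-identical fixtures and adding a stage never perturbs earlier draws.

What the simulator does **not** emulate: sequence evolution on first/second
codon positions (duplicates are exact copies), indels, polyploidy,
CHH islands, coverage heterogeneity, or partial methylation epialleles.
Passing tests therefore demonstrate correctness of the measurement chain
and recoverability of planted signal — not that real genomes contain such
signal.

## Numerical and degenerate-input choices

- GFF3 coordinates convert to 0-based half-open internally; "first splice
  variant" means the first mRNA child in file order (logged per gene).
- Genes without a CDS record load with a warning and fail the CDS filters
  downstream rather than erroring at parse time.
- Anchor rows with unresolvable ids are dropped with a count; duplicated
  rows deduplicate; a file with no resolvable pair is an error.
- allc rows with m_reads > total_reads abort with the offending row named;
  zero-coverage rows are kept but flagged.
- The per-gene table prints floats at 4 decimals and NA for undefined
  values; the reader reproduces records bit-exactly.
- Chain extraction ties break by (start ordinal, `+` before `-`); blocks
  sort by (chrom_a, first ordinal).
- Empty anchor lists yield empty block lists; an empty gene set is an error
  for classification.

## Pipeline determinism and scale

`run_pipeline` executes io → synteny → GC → copy number → methylation →
stats; every output starts with `# syngc <version> config=<sha256[:12]>
seed=<seed>` and contains no timestamps, so a rerun on identical inputs is
byte-identical. The default simulated scale (≈ 3250 genes, ≈ 1.6 Mb per
genome, ≈ 250 k cytosine calls per species) runs the complete pipeline in
well under a minute on one CPU; the test-suite scales (2 × 300-gene
recovery runs, 10 000-CDS oracle sweeps, 200-set chaining comparisons) were
chosen so the whole suite and the acceptance script each finish in a few
minutes.

## Known limitations

- The internal copy-number matcher is ungapped; an indel inside an
  otherwise identical copy splits or rejects the alignment where gapped
  BLASTN would accept it. The BLAST-tabular input path exists for that case.
- GO enrichment treats terms independently (no DAG structure).
- The exact chain packing is exponential and capped at small anchor counts;
  beyond the cap the greedy extraction is a heuristic without an optimality
  certificate.
- Methylation regions use annotated transcript starts; UTR mis-annotation
  shifts the window.
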