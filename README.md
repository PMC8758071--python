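# syngc

Tools for asking how a plant gene's duplication history is written into its
sequence composition and epigenetic state. In grass genomes, genes that have
stayed in their ancestral chromosomal position (syntenic genes) are strongly
enriched for high GC content at third codon positions, while genes that have
moved — typically through dispersed duplication followed by loss of the
original copy — sit in a low-GC, more heavily methylated class. `syngc`
implements the full analysis chain needed to measure that association:

- **Synteny detection** — collinear block chaining between two gene orders
  from homolog anchor pairs: per chromosome pair and orientation, a
  longest-chain dynamic program links anchors whose rank deltas satisfy
  0 < Δ ≤ *max_gap* in both genomes, keeps chains of ≥ 7 anchors
  (best-score-first, each anchor in at most one block), and collapses tandem
  arrays to a representative first. A gene inside ≥ 1 block of ≥ 1
  comparison is classified syntenic.
- **GC3-50** — the GC fraction at third codon positions of the first 50
  codons, a length-independent variant of GC3 (third-position GC declines
  with distance from the start codon, so whole-gene GC3 is confounded with
  gene length). Genes shorter than 50 codons, containing ambiguous bases, or
  not starting with ATG are excluded.
- **Copy number** — hits of the first 150 bp of each CDS against the genome
  assembly (ungapped seed-and-extend, ≥ 90 % identity over ≥ 90 % of the
  query, both strands, overlapping hits merged into loci), binned as
  single copy / 2–9 copies / 10+ copies.
- **Methylation** — the weighted methylation level Σm/Σtotal over covered
  CG, CHG and CHH cytosines in the first 150 bp of each transcript, from
  allc-style per-cytosine bisulfite tables.
- **Association statistics** — Wilcoxon rank-sum comparisons of GC3-50
  between gene classes (exact small-sample path with ties, tie-corrected
  normal approximation otherwise), Pearson/Spearman methylation–GC3-50
  correlations, 2 %-bin histograms and binned methylation curves, and
  one-sided hypergeometric GO-term enrichment by synteny class.
- **Synthetic data** — a genome-pair simulator (inversions, translocations,
  tandem and dispersed duplications, losses; class-dependent bimodal GC3;
  Beta/Binomial bisulfite reads) with full ground truth, so every stage is
  testable end-to-end against known answers.

## Worked example

Simulate a small two-genome fixture and run the full pipeline:

```sh
syngc simulate --out fixture --seed 42
syngc all --config run.yaml --out results
```

where `run.yaml` points at the fixture files:

```yaml
seed: 42
species:
  A: {gff3: fixture/genes_A.gff3, cds: fixture/cds_A.fa,
      genome: fixture/genome_A.fa, allc: fixture/allc_A.tsv, go: fixture/go_A.tsv}
  B: {gff3: fixture/genes_B.gff3, cds: fixture/cds_B.fa,
      genome: fixture/genome_B.fa, allc: fixture/allc_B.tsv}
comparisons:
  - {a: A, b: B, anchors: fixture/anchors_A_B.tsv}
```

Programmatically, on the generator's default conditions (3 chromosomes ×
1000 genes per lineage):

```python
from syngc.pipeline import fixture_run_config, run_pipeline
from syngc.simulate import SimConfig, write_fixture

write_fixture("fixture", SimConfig(seed=1))
result = run_pipeline(fixture_run_config("fixture", seed=1), "results")
cmp = result["stats"]["A"]["synteny_gc3_50"]
print(f"syntenic {cmp.n_x}, non-syntenic {cmp.n_y}")
print(f"mean GC3-50 difference {cmp.mean_difference:.4f}, p = {cmp.p_value:.2e}")
ms = result["stats"]["A"]["meth_by_synteny"]
print(f"mCG syntenic {ms['syntenic'].means['CG']:.3f}, "
      f"non-syntenic {ms['non-syntenic'].means['CG']:.3f}")
```

prints

```
syntenic 2362, non-syntenic 872
mean GC3-50 difference 0.1123, p = 6.46e-22
mCG syntenic 0.223, non-syntenic 0.268
```

i.e. genes still at their ancestral location average ~11 percentage points
higher GC3-50 than relocated genes (overwhelmingly significant by rank-sum
test), and relocated genes carry higher CG methylation over their 5′ ends —
the joint pattern the simulator plants and the pipeline is designed to
detect. `results/` additionally contains the per-gene metrics table, block
lists, the GC3-50 histograms, methylation-by-GC3 curves, correlation and
GO-enrichment tables.

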