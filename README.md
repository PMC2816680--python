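# fiveprime

Local mRNA secondary structure tends to be *less stable than expected* in the
first 30–40 nucleotides of coding sequences: selection on synonymous sites
appears to deplete stable structure right after the start codon, plausibly to
keep the translation-initiation region accessible to the ribosome.
`fiveprime` implements the genome-scale analysis behind that observation, for
anyone who wants to measure the effect in a set of coding sequences (CDS): it
computes sliding-window folding free energies, compares them to
synonymous-codon permutation nulls, and runs the downstream comparative
statistics (GC content, growth temperature, codon usage bias, expression).

## The statistic

For every gene, the minimum free energy ΔG (kcal/mol, RNAfold-style
nearest-neighbor folding at 37 °C) is computed in sliding windows of 30 nt
(step 10 nt, 13 windows) starting at the first nucleotide of the start codon.
The gene's synonymous codons are then reshuffled among positions encoding the
same amino acid — preserving the protein, the codon usage, and the gene's GC
content — N = 1000 times, and each permuted sequence is folded in the same
windows. The per-window Z-score is

    Z_ΔG = (ΔG_wt − mean(ΔG_perm)) / sd(ΔG_perm)

so **positive Z_ΔG means the wild-type window is less stable than expected**
given its amino-acid sequence and codon usage. Z_GC is the analogous score
for the window's G+C fraction. Per genome, the per-window mean Z_ΔG with its
standard error and a one-sample t-test against 0 summarize the signal; a
dinucleotide-preserving shuffle (dicodon shuffle) is available as a control
null.

Downstream, the package correlates per-species 5′ Z_ΔG (window 1) with
genomic GC and optimal growth temperature (Spearman), stratifies genes by GC
content, effective number of codons (ENC, Wright) and expression level
(top vs bottom 5%), and apportions the within-genome variance of 5′ Z_ΔG
among those three predictors by principal-component regression.

Because real analyses need genomes, a synthetic-genome generator is included
as first-class, tested code: it emits CDS sets with controllable GC content,
codon-bias strength, gene lengths, and an injectable 5′ destabilization
signal δ (an excess AT preference in synonymous choice over the first 30 nt),
plus multi-species panels in which δ is coupled to GC and growth temperature.

## Worked example

```python
from fiveprime import (SyntheticGenomeConfig, generate_genome, ShuffleConfig,
                       WindowSpec, scan_genes, summarize_genome, get_backend)

genes, _ = generate_genome(SyntheticGenomeConfig(n_genes=100, seed=7, delta5=1.5))
profiles = scan_genes(genes, WindowSpec(), ShuffleConfig(n_permutations=100, seed=7),
                      get_backend("vienna"))
for s in summarize_genome(profiles, "demo"):
    print(f"window {s.window_index:2d}  mean Z_dG = {s.mean_z_dg:+.3f} "
          f"+/- {s.se_z_dg:.3f}  p = {s.p_value:.2e}")
```

prints

```
window  1  mean Z_dG = +0.572 +/- 0.093  p = 1.47e-08
window  2  mean Z_dG = +0.435 +/- 0.096  p = 1.53e-05
window  3  mean Z_dG = +0.114 +/- 0.108  p = 2.93e-01
window  4  mean Z_dG = +0.056 +/- 0.086  p = 5.18e-01
window  5  mean Z_dG = -0.078 +/- 0.111  p = 4.84e-01
...
window 13  mean Z_dG = -0.165 +/- 0.098  p = 9.73e-02
```

The 100 genes were generated with a 5′ destabilization δ = 1.5 confined to
the first 30 nt; the scan recovers exactly that shape — significantly
positive mean Z_ΔG in the first two windows (reduced stability), decaying to
fluctuation around zero downstream.

The same machinery is scriptable from the shell:

```bash
fiveprime synth --n-species 20 --gc 0.32:0.62 --slope 3.0 --seed 1 panel/
fiveprime run --backend vienna --seed 1 panel/ out/
fiveprime correlate out/genome_summary.tsv out/metadata_enriched.tsv corr.tsv
```

`out/` then holds per-gene window tables (`*.gene_windows.tsv`), per-species
summaries (`genome_summary.tsv`), stratified comparisons, the cross-species
correlation table and a run manifest with config and input hashes.

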