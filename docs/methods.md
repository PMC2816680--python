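# Methods

## Model and procedure

The quantity of interest is the deviation of local mRNA secondary-structure
stability from what a gene's amino-acid sequence and codon usage would
predict. The null model is the set of synonymous recodings of the gene: codons
are permuted uniformly at random among positions encoding the same amino
acid. This conditions exactly on (i) the protein sequence, (ii) the per-gene
codon usage, and therefore (iii) the gene-wide base composition — any signal
that survives is attributable to the *arrangement* of synonymous codons, not
to their identity.

Per gene, the pipeline:

1. folds the wild-type sequence in sliding windows (width 30 nt, step 10 nt,
   up to 13 windows; window 1 starts at the first nucleotide of the start
   codon; coordinates are 1-based inclusive);
2. draws N permuted sequences (default 1000) and folds each one's windows at
   the same coordinates — one permutation set serves all windows of a gene
   (the null is per-sequence, not per-window);
3. computes Z_ΔG = (ΔG_wt − mean ΔG_perm)/sd(ΔG_perm) per window, with the
   sample (N−1) standard deviation, and the analogous Z_GC for window G+C
   fraction. Positive Z_ΔG = less stable than expected.

Per genome, windows are aggregated as the mean Z over genes, its standard
error, and a two-sided one-sample t-test against zero. Windows whose null is
degenerate (all permuted values identical — e.g. a gene with no synonymous
freedom in that window) have undefined Z; they are excluded from genome
means, with exclusion counts reported. Degeneracy is detected by exact
equality of the permuted values, not by a floating-point sd threshold.

## Folding

Windows are folded as RNA (T→U at the folding boundary; sequences are stored
as DNA throughout). Two interchangeable backends:

* **vienna** (default): the ViennaRNA nearest-neighbor minimum-free-energy
  folder, at 37 °C, GU pairs allowed, dangling ends restricted so an unpaired
  base joins at most one dangling end (ViennaRNA `dangles=1`; modern RNAfold
  defaults to `dangles=2`, so the mode is exposed in the backend config
  rather than assumed). Only the MFE structure is evaluated; no partition
  function.
* **simple-nn**: a self-contained simplified nearest-neighbor folder — a
  pair-type stacking-energy table with the usual ordering (GC-rich stacks
  strongest, tandem GU destabilizing), hairpin loops of minimum size 3 with a
  linear length penalty, and one linear penalty covering bulge, interior and
  multibranch loops. It is a legitimate energy-minimization model in its own
  right (deterministic, MFE ≤ 0, monotone under added pairing opportunity)
  and is the backend of the property-test suite. Its dynamic program is
  numba-compiled (~7 µs per 30-nt window), which is what makes
  hundreds of thousands of window folds per test affordable.

Each backend is validated only against its own frozen (sequence, ΔG) fixture
table (`tests/data/`); the two models are not asserted to agree, since the
Z statistic is backend-agnostic. Energies are reported to 0.01 kcal/mol and
compared at that tolerance. Batch folding memoizes identical window strings.

## Shuffles

The codon shuffle fixes the terminal stop codon (and any internal stop — no
amino acid, hence no synonymous family) and the initiator ATG (Met is a
single-codon family). Per-gene RNG streams are derived from (master seed,
CRC32 of gene id), so results are independent of gene processing order and
safe under parallel execution.

The dicodon shuffle additionally preserves the whole-sequence 16-entry
dinucleotide count vector, including codon-junction dinucleotides, per gene.
When the synonymous arrangement space is small (≤ 5000 arrangements, counted
arithmetically before any enumeration) the valid set is enumerated and
sampled uniformly — exact by construction. Otherwise rejection sampling
against the count constraint runs under a configurable attempt budget
(default 200); on exhaustion the input sequence (a valid self-permutation) is
returned. For long genes the constraint is rarely satisfied by a random
synonymous permutation, so the dicodon null is most informative on short
genes and as an exactness control.

## Effective number of codons

ENC follows Wright: F = (nΣp² − 1)/(n − 1) per amino acid with n ≥ 2 observed
codons, averaged within degeneracy classes, ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
3/F̄₆, capped into [20, 61]. The three 6-fold amino acids (Leu, Ser, Arg) are
kept as single families. A class with no usable amino acid is, by default,
interpolated from the nearest available classes (F̄₃ ≈ (F̄₂+F̄₄)/2); the
alternative (`drop`, rescaling the remaining terms to the full 59-codon
weight) is exposed in the function signature.

## Comparative statistics

Cross-species rows are Spearman correlations (average ranks on ties,
two-sided p, pairwise-complete observations, undefined below 3 pairs):
genomic GC vs mean window-1 Z_ΔG with configurable taxon exclusions
(default: plants, birds, mammals, whose isochore-driven within-genome GC
heterogeneity breaks the genome-level signal), a per-window correlation
profile, growth-temperature correlations restricted to prokaryotes with
temperature data, and raw-ΔG analogues (window 1, and window 1 minus
window 10).

Stratified comparisons take the top and bottom `fraction` (default 5%,
group size max(1, ⌊f·n⌋), minimum 40 usable genes) of genes by GC, ENC or
expression; for ENC the *lowest* values (strongest bias) form the "top"
group. Ties at the cut are broken by stable gene-id order; groups are
compared by Welch's t-test.

Principal-component regression standardizes GC, ENC and log expression
(pseudo-count: smallest positive observed value), regresses window-1 Z_ΔG on
all three principal components, maps the PC coefficients back to the
predictors, and reports each predictor's contribution as coefficient ×
covariance with the response over the response variance. Contributions sum
exactly to the regression R²; for uncorrelated predictors each equals that
predictor's squared correlation with the response. This is one defensible
allocation convention among several (a pure squared-loading allocation is
unstable here: standardized predictors give a near-isotropic correlation
matrix whose PCA rotation is arbitrary, smearing even a pure
single-predictor signal); under strong collinearity individual contributions
can be negative, and the output labels the convention.

## Synthetic data

The generator emulates what the analysis needs from a genome and nothing
more. Amino-acid sequences are i.i.d. from a configurable composition
(uniform over the 20 standard amino acids by default — legitimate because
the statistic conditions on the amino-acid sequence). Synonymous codons are
drawn from per-genome family weights ∝ exp(bias_c + β·n_GC(c)); the bias
terms are fixed per-genome normal perturbations scaled by the codon-bias
strength, and β is solved by bisection so the expected pooled GC matches the
target. With uniform amino-acid composition the attainable coding GC is
capped near 0.63 (every family pinned to its most GC-rich codon);
out-of-range targets warn and clip. Genes start with ATG, end with a random
stop, contain no internal stops, and always pass the default IO filter.

5′ destabilization multiplies the synonymous weights by exp(−δ_gene·n_GC(c))
within the first 30 nt (default span), i.e. it acts purely on synonymous
choice — the causal pathway the permutation test is designed to detect — and
never alters amino acids. Per-gene δ varies log-normally around the
configured δ, sharing a latent variable with simulated expression so the
expression–destabilization correlation is tunable. Species panels spread
target GC evenly over a range (default 0.32–0.62), couple δ linearly to GC,
and optionally assign prokaryote growth temperatures linear in δ plus noise.

What the generator does **not** emulate: real amino-acid composition,
operonic structure, ribosome-binding motifs, UTRs, isochores, or any
correlation structure between neighboring genes. Passing tests therefore
demonstrate that the pipeline recovers a synonymous-arrangement signal it is
pointed at, under the stated noise — not that any particular real genome
carries such a signal.

## Problem sizes and test design

The property suites run at: null calibration — 300 genes, 200 permutations
(genome mean Z within 3 SE of 0 per window; pooled per-gene Z with |mean| <
0.1, |sd−1| < 0.15); signal recovery — 250 genes, 120 permutations, δ = 1.5
(window 1 positive at p < 0.01, windows ≥ 6 clean); cross-species recovery —
20 species × 150 genes, 100 permutations (both Spearman signs recovered at
p < 0.05). These sizes put the per-species standard error of mean Z₅ (~0.08)
well below the across-species effect spread (~0.4) while keeping the whole
suite at a few minutes on one CPU with the numba-compiled test folder. The
acceptance script runs the same study designs at comparable sizes with the
ViennaRNA backend (~10 minutes).

## Known limitations

* The dicodon shuffle falls back to the identity permutation on long genes
  when no counting-preserving arrangement is found within budget; its null is
  then conservative (Z → undefined where all permutations collapse).
* Z is undefined for genes with no synonymous freedom in a window; genomes
  dominated by Met/Trp-rich or single-codon-family sequences would lose most
  windows (not a realistic regime).
* The simplified folder's absolute energies are model-specific; only the
  ViennaRNA backend's energies are comparable to published ΔG values.
* ENC interpolation for missing degeneracy classes matters only for short or
  compositionally extreme genes; at the default >50-codon filter with typical
  compositions all four classes are observed.
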