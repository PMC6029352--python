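# Methods

## The model

`kmerfact` infers variation in transcription-factor (TF) activity across
single cells (or samples) from the DNA sequence associated with an
epigenomic mark — here, chromatin accessibility read out by ATAC-seq.  The
causal picture: a TF that opens chromatin leaves its binding words next to
the accessible regions it creates, so a cell with higher activity of that TF
carries relatively more of the TF's cognate k-mers in its accessible
sequence.  Representing each cell as a vector of gapped k-mer frequencies
therefore embeds hidden TF activities in an unsupervised, motif-free feature
space; factorizing the cell x k-mer matrix recovers axes of co-varying
k-mers, and each axis can be interpreted by asking which TF's cognate
k-mers concentrate at its extremes.

### Stage by stage

1. **Regions** (`io_regions`).  Each read's 5' end marks a Tn5 integration
   site; sites are expanded by a flank (default 50 bp each side, so
   `[p-50, p+50)` in 0-based half-open coordinates) and overlapping windows
   merged, which also collapses duplicates.  Cells with fewer than 3162
   (`int(10**3.5)`) distinct merged loci are dropped.  Sequence is extracted
   per cell; repeat-masked (lowercase) or ambiguous bases act as *scan
   breaks* — no k-mer spans them, and coordinates are never shifted.
2. **K-mers** (`kmers`).  The feature space is every DNA word of span 1–8
   over `{A,C,G,T,N}` with specified endpoints (`N` = match-any gap); the
   uncanonicalized universe has `4 + sum_{k=2..8} 16*5^(k-2) = 312,500`
   members, halved (up to palindromes) by reverse-complement
   canonicalization.  Counting is strand-symmetrized: a canonical pattern
   accumulates forward-strand matches of itself and of its reverse
   complement; palindromes count once per site, which makes the canonical
   ungapped span-k counts of a length-L sequence sum to exactly `L-k+1`.
   The engine scans each cell once per span into a 4^k ungapped table and
   marginalizes gap positions into a 5^k table, so cost is O(total bases) +
   O(5^max_span) per cell, independent of the pattern count.  Frequencies
   divide each count by the number of span-k windows scanned in that cell
   (a span-specific denominator), making cells with different locus counts
   comparable.
3. **Factorization** (`factorize`).  Each k-mer row is scaled to mean 0 /
   sample SD 1 across cells (zero-variance rows dropped with a warning) and
   the matrix decomposed by PCA (thin SVD; cells are observations).  Signs
   are fixed so each component's largest-magnitude loading is positive.
   The number of signal components comes from permutation parallel
   analysis: every feature row is permuted independently across cells
   (destroying covariance, preserving marginals), and a component is
   significant while its explained variance exceeds the (1-alpha) quantile
   of permuted explained variance at the same rank (prefix rule; defaults
   100 permutations, alpha 0.05).  Held-out cells are projected with the
   stored means/SDs and loadings, never re-fit.  Because k-mer frequencies
   correlate strongly with G+C content, PC1 usually carries a G+C
   component; the per-PC correlation of loadings with pattern G+C fraction
   is reported instead of silently discarding PC1.  t-SNE on the
   significant PCs is available for visualization only.
4. **Enrichment** (`enrich`).  A TF's cognate set comes from a PWM (max
   log-odds over every offset and both orientations, overhangs and gap
   positions scoring 0; uniform 0.25 background with pseudocount 0.01;
   robust Z over the pattern universe via median/MAD, Z > 2 cognate) or
   from PBM 8-mer Z-scores (Stouffer-combined across experiments,
   Z > 3 cognate; ungapped 8-mers only).  Each PC's ranking of k-mer
   loadings is scanned by the minimum hypergeometric (minHG) statistic over
   prefixes (caps 15,000 for PWM rankings over the gapped universe, 3,000
   for PBM 8-mer rankings), both descending (enriched) and ascending
   (depleted).  Bonferroni correction multiplies by the number of prefixes,
   deliberately treating dependent prefix tests as independent
   (conservative).  Because realistic minima underflow doubles, p-values
   are computed and carried in log space.  Redundant motifs (per-pattern
   score vectors with Pearson R > 0.5 against an already-retained motif in
   the same PC and tail) are pruned greedily in order of significance, ties
   broken by TF name.  Co-enriched TF pairs can be tested against a
   user-supplied interaction list with an exact hypergeometric over all TF
   pairs.
5. **Evaluation** (`evaluate`).  With known labels, grouping quality is the
   number of same-sample cells among each cell's 20 nearest neighbours
   (Euclidean, in significant-PC space, self excluded, ties broken by cell
   index) and the AUROC of -distance for same- vs different-sample pairs,
   pooled over all unordered pairs (midranks for ties).  Two analysis
   variants are compared by 2001 bootstrap rounds over 80% cell subsamples
   (ties split 0.5/0.5; the two-tailed p is floored at 2/n_boot).  Per-PC
   diagnostics: AUROC + rank-sum p against a binary treatment label (ranked
   by |AUROC-0.5|), and batch flagging of PCs that separate any replicate
   from the rest (Bonferroni over PC x replicate tests, corrected p < 0.1),
   with PC1 additionally flagged for its G+C association.
6. **Cell cycle** (`cellcycle`).  Per-phase Repli-seq percent-signal tracks
   are thresholded at 25% (strictly greater) into replication domains for
   G1, S1–S4, G2.  A cell's reads are assigned to domains by 5' end
   (counted once per phase hit when domains overlap), converted to per-cell
   proportions, and summarized as (G2+S1+S2+S3+S4)/G1 — elevated in cycling
   cells and invariant to depth.  Zero G1 reads yield an infinite-ratio
   sentinel with a warning.
7. **Cooperativity** (`coop_model`).  Single-site occupancy is
   `O = 1 - 1/(1 + [x]/Kd_x)`.  With a fraction `f = Ka_xy[y]` of x in
   heterodimer form, monomer and dimer compete for the site and the exact
   partition function gives
   `O_coop = 1 - 1/(1 + [x](1-f)/Kd_x + [x]f/Kd_xy)`,
   which collapses to the plain isotherm exactly at `f = 0` or
   `Kd_xy = Kd_x`.  The frequently used independent-species product
   approximation (`coop_occupancy_independent`) differs by a cross term
   that double-counts simultaneous monomer+dimer binding of the one site;
   it is provided for comparison and satisfies the same steepness
   inequality.  When the dimer binds more tightly the cooperative curve is
   steeper at half occupancy — cooperative TFs traverse their dynamic range
   over a narrower concentration window, which is why cooperatively bound
   loci are intrinsically more variable.  Half-occupancy points are found
   by Brent bisection (tolerance 1e-10) and slopes by central differences
   (relative step 1e-6); curves can be aligned at 50% occupancy for
   plotting.
8. **Expression variability** (`expr_var`).  Raw single-cell counts are
   summarized per gene by mean and CV; the minimum CV attainable at a mean
   follows the negative-binomial law `Var = mu + alpha*mu^2`, i.e.
   `cv_min(mu) = sqrt(1/mu + alpha)` (Poisson at alpha = 0).  `alpha` is
   fitted as a *lower envelope*: genes are binned by mean (20 log-spaced
   bins) and the 10th percentile of variance per bin regressed on the law,
   after dividing out the finite-sample factor
   `chi2.ppf(0.10, n-1)/(n-1)` — the 10th percentile of sample variances of
   genes that all obey the law sits predictably below it.  The correction
   is Gaussian-based, so a small downward bias (~10% at 500 cells for NB
   data, whose variance estimator is heavier-tailed) remains; plain least
   squares (`method="lsq"`) is the config alternative.  A gene's excess CV
   is `log(cv_obs) - log(cv_min(mean))`; TF groups are compared on mean or
   excess CV by two-sided Wilcoxon rank-sum tests.

## The synthetic-data generator

`synth` emits every input the pipeline consumes — genome FASTA, per-read
BED with cell ids, labels TSV, CIS-BP-style PWM files, PBM 8-mer Z tables,
per-phase replication-domain BEDs and signal tracks, NB expression counts —
with full determinism under the seed, and records the planted ground truth.

It implements the generative model the pipeline is meant to invert.  Motif
occurrences (default: two 8-bp motifs, 500 instances each, drawn from sharp
PWMs on random strands) are planted in an iid 200 kb background genome over
2 chromosomes.  Per cell, each occurrence of motif m is *open* with
probability `1 - exp(-a_m)` given the cell group's activity `a_m`; reads
(Poisson around 5000/cell) land near uniformly chosen open sites with
±10 bp Gaussian jitter, except a 20% background share that samples a fixed
universe of 400 motif-free accessible loci.  The default three groups of 60
cells have programs (A: a_1=3.0, a_2=0.1; B: reversed; C: both 0.1), i.e.
open-site probabilities of 0.95 vs 0.10 — a strong but realistic activity
contrast that plants two recoverable axes.  A quarter of cells are
"replicating" and redirect 30% of their reads to a fixed set of 200 loci
inside S/G2 replication domains, consistent with the extra DNA content of
late-replicating regions in cycling cells; the replication tiling itself
cycles 5 kb blocks through G1,S1..S4,G2 with 80%/5% signal so that calling
domains at the 25% cutoff reconstructs it exactly.

Two generator choices deserve emphasis.  First, background and replication
reads sample *fixed locus universes* rather than uniform genome positions:
accessible chromatin is a discrete landscape of regulatory elements shared
across cells, and uniform placement would additionally manufacture strong
locus-subsampling covariance that parallel analysis (correctly) reports as
many extra significant components.  Second, what the generator does *not*
model: Tn5 sequence bias, fragment-length structure, chromatin domains,
per-cell depth gradients, doublets, or TF motif families with correlated
specificities beyond the supplied decoys.  Passing tests therefore
demonstrate that the method inverts its own generative assumptions at
realistic sparsity — not that it is robust to every artifact of real
scATAC-seq.

## Problem sizes and numerical choices

End-to-end runs in the test suite and in `scripts/acceptance.py` use the
default dataset (180 cells, 5000 reads/cell, 200 kb genome) with gapped
k-mers to span 5 (1,274 canonical patterns), 50-permutation parallel
analysis, and a PWM significance cutoff of 1e-20; the pipeline defaults
remain span 8 and 1e-112.  Both cutoffs are elbow calibrations to their
universe sizes: minHG log-p magnitudes scale with the number of patterns
and prefixes, so the threshold appropriate for 312,500 patterns / 15,000
prefixes is unreachable (and unnecessary) at a 1,274-pattern universe,
where planted motifs reach corrected p ~ 1e-35..1e-45 and decoys stay
above ~1e-9.  The span-8 universe and the PBM (8-mer) enrichment route are
exercised by dedicated tests at smaller cell counts.

Other numerics: sample (n-1) SDs throughout; PCA via LAPACK thin SVD with
permutation variances from the cell x cell Gram matrix; hypergeometric
tails via `scipy.stats.hypergeom.logsf`; minHG ties and ranking ties broken
by stable sort order (cell/pattern index); loadings orthonormality holds to
1e-8 and explained variance reproduces the scaled matrix's Frobenius norm
to the same tolerance.  Degenerate inputs fail loudly: all-constant
matrices, zero-scannable-sequence cells, missing patterns at projection
time, MAD-zero score distributions, unbracketed half-occupancy searches.

## Known limitations

- The QC default (3162 loci) is calibrated to real scATAC depth; synthetic
  runs use a lower cutoff because the desk-scale genome bounds the number
  of distinct loci a cell can have.
- The minHG Bonferroni factor treats prefix tests as independent; reported
  corrected p-values are conservative and should be read against
  scale-calibrated cutoffs, not as literal error rates.
- The envelope dispersion estimate retains a ~10% downward bias on NB data
  (Gaussian quantile correction); use `method="lsq"` when an unbiased
  mean-variance fit matters more than minimum-variance semantics.
- `embed_2d` is a visualization contract only; no statistic in the package
  consumes t-SNE coordinates.
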