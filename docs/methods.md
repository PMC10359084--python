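# Methods

## Problem and model

Given a genes × samples expression matrix `X ∈ R^{ng×ns}` and a phenotype
label per sample (≥ 2 phenotypes), the package asks which genes behave
*differently* between phenotypes — in mean level (differential expression,
DE) or in co-expression structure (differential co-expression, DC) — and
groups them into aligned modules rather than ranking genes in isolation.

The central device is the *gene–phenotype instance*: each retained gene
`g` appears once per phenotype as `g^{p}`, and all instances are placed in
one shared space.

**RDE (relative differential expression).** Let `m_a = ⟨X_a⟩` be the mean
expression of instance `a` over its phenotype's samples.  The RDE matrix is

    RDE_{ab} = | m_a − m_b |,     a, b ∈ {g^{p1}, g^{p2}},

a `2·ng × 2·ng` distance matrix; each instance's feature vector is its full
row of distances to all instances.  Because every entry is a difference of
means, adding one constant to every value of both phenotype matrices — a
global offset or a batch shift hitting all genes — cancels exactly.  This
is the representation's anti-noise mechanism, and it is asserted to float
precision in the tests.

**RDC (relative differential co-expression).** Per phenotype, genes form a
graph with edge weights `A_{ij} = |PCC(g_i, g_j)|` (zero diagonal).  With
degrees `D`, the symmetric normalized Laplacian

    L = D^{−1/2} (D − A) D^{−1/2}

is eigendecomposed and each gene receives the entries of the `d`
smallest-eigenvalue eigenvectors (the trivial eigenvector is kept;
eigenvector signs are fixed by making each vector's largest-magnitude entry
positive, so runs are reproducible).  An instance `(g, p)` is embedded as
the concatenation `[coords^{own p}(g), coords^{other p}(g)]` — own phenotype
first.  With identical phenotype data both instances of every gene
coincide; a gene that changes co-expression block membership receives a
large inter-instance distance.  The obvious alternative — giving both
instances the same concatenation `[coords^{p1}, coords^{p2}]` — would make
the two instances of every gene identical by construction and no DC signal
could ever be detected, so the own-first ordering is the only coherent
reading.

**MIX.** The RDE and RDC blocks are each centered and scaled to unit total
variance, then concatenated, so neither block dominates by scale alone.

Embeddings are PCA-reduced before clustering (integer component count, or
the smallest count reaching an explained-variance fraction; default 0.95).
A full-rank projection is an exact isometry of the row geometry, which the
tests assert.

## Clustering and module configurations

All `2·ng` instances are clustered jointly by Lloyd-style K-Means
(`K` default 8; k-means++-style seeding from a single seed; member-mean
centroid updates; assignment ties to the lowest index; empty clusters
re-seeded from the worst-fit point, never stealing a cluster's last member;
stop on stable assignments or 300 iterations).  A gene thus gets two labels
`l^{p1}, l^{p2}` and lands in cell `(l^{p1}, l^{p2})` of the K×K
*module-configuration* (MC) table `M_{n,m} = {g : l^{p1}=n, l^{p2}=m}`.
Diagonal cells are conserved modules, off-diagonal cells differentiated
ones.

Two deliberate choices:

* **Distance.** Two metrics are implemented: Euclidean (default) and the
  absolute-correlation dissimilarity `1 − |PCC(row, centroid)|`.  The
  latter is natural for co-expression profiles but identifies a vector
  with its negation, and on RDE rows this is fatal: for the instance with
  the minimum mean and the instance with the maximum mean, the rows
  `|m_min − x|` and `|m_max − x|` are exact affine negations of each other,
  so the two extremes *always* co-cluster and strong-DE instances collapse
  onto the unshifted mass.  Euclidean K-Means has no such degeneracy and is
  also the standard choice on spectral coordinates, so the pipeline
  defaults to it; `cluster_metric="abscorr"` switches back.
* **Alignment.** Raw K-Means indices are arbitrary, so "diagonal" is
  meaningless until phenotype-2 indices are renamed.  A maximum-weight
  bipartite matching on the count matrix (solved exactly with the
  Hungarian algorithm) permutes the columns to maximize diagonal mass;
  membership is untouched and the permutation is logged.  Disable with
  `align=False`.

The number of spectral eigenvectors defaults to `K` rather than a fixed
constant: using fewer eigenvectors than clusters discards the coordinates
that separate them, and using many more mixes in noise-dominated
directions.  In the noise-stability benchmark this choice is what makes
spectral clustering beat clustering on raw correlation rows.

## Module eigengenes, SNR and gene scores

Each non-empty MC is summarized over the pair's samples by a *module
eigengene* (ME):

* **DE source:** member genes are z-scored across all samples of the pair
  (population sd; constant members dropped with a warning) and the ME is
  the first principal component's sample scores, with sign chosen so the
  ME correlates positively with the mean standardized member profile.
* **DC source:** the member pair whose within-phenotype correlation
  changes most between the two phenotypes (ties broken lexicographically)
  is summarized by the per-sample inter-individual correlation

      IIC(x) = (x_{k1} − ⟨X_{k1}⟩)(x_{k2} − ⟨X_{k2}⟩) / (σ(X_{k1}) σ(X_{k2})),

  with means and population σ taken over the sample's own phenotype.  With
  population σ the per-phenotype mean of the IIC vector equals the pair's
  within-phenotype Pearson correlation *exactly*, which is both the reason
  the per-phenotype reference population was chosen and a machine-precision
  test invariant.

A module's importance for phenotypes A, B is the signal-to-noise ratio

    SNR = |⟨ME_A⟩ − ⟨ME_B⟩| / (σ(ME_A) + σ(ME_B))

(population σ; ∞ is returned as a flagged sentinel when the noise term
vanishes with nonzero signal, 0 when both vanish).  SNR is invariant to
positive affine rescaling of the ME, so the PCA sign convention cannot
change it.  A gene's score is the sum of its modules' SNRs over all
unordered phenotype pairs; genes sharing modules share scores, and ranking
ties are resolved by gene id.  In MIX mode a module's score is the sum of
its DE- and DC-sourced SNRs.  Note the score deliberately does not depend
on whether a module is diagonal: a conserved module whose members shift
coherently still carries a phenotype difference and the SNR reflects it.

For sample-level downstream analysis (subtyping), the MEs of modules with
SNR ≥ a threshold (default 0.5) are concatenated column-wise into a
samples × features matrix.

## Preprocessing

Raw units only (`counts`, `rpkm`, `tpm`): RPKM/FPKM is converted to TPM by
per-sample proportion × 10⁶; genes below `min_expr` (default 1) in
*strictly more than* `max_low_frac` (default 0.9) of samples are dropped —
a gene low in exactly 90 % of samples is kept; values are log-transformed
(`log2(x + 1)` by default — the dominant transcriptomics convention, since
only "a log transform" is specified by the method).  Filtering is applied
jointly across all samples before the phenotype split and never reorders
retained genes.  Data tagged `logtpm` or `arbitrary` (e.g. simulated
Gaussian data, which may be negative) bypass preprocessing.

## Synthetic data generator

The simulator emulates the benchmark's data-generating process.  Expression
is multivariate normal `X ~ N(μ, C)` with unit gene variances.  The
correlation matrix is built from a random binary mask:

    D_{ij} = 1 iff e_{ij} < λ,  e_{ij} ~ U(0,1);
    B_{ij} = sqrt(D_{ij} / Σ_j D_{ij});   C = B Bᵀ.

By construction `C` is PSD with exactly unit diagonal, and the expected
off-diagonal entry approaches λ as `ng` grows (verified by Monte Carlo:
ng = 500, λ = 0.3 gives mean off-diagonal within ±0.02 of λ).  Mask rows
that come out all-zero would leave a gene with no neighbours and an
undefined factor row; they are resampled (cap 100, then an error).

A dataset is nine equal gene groups — every combination of a DE level and a
DC level, each strong/weak/none.  The DE level shifts the phenotype-2 group
mean by Δμ; the DC level gives the phenotypes different λ for the group's
correlation block.  Levels must be made operational with concrete
magnitudes; the defaults, on the unit-variance scale, are Δμ = 2.0 / 0.8 /
0.0 (strong/weak/none) and λ pairs (0.7, 0.1) / (0.5, 0.3) / (0.4, 0.4).
These were chosen once so that strong patterns are unambiguous, weak
patterns are detectable but not trivial at the default sample size
(ns = 100 per phenotype), and "none" genes still carry realistic background
correlation; all are overridable.  A gene is *positive* if either of its
levels is not "none".

Two noise models: i.i.d. `N(0, I)` added to every entry (random noise of
intensity I), and a batch-effect-like constant shift added to a random
`⌊frac·ng⌋` gene subset across **all** samples of a matrix (the shift
formula carries no sample index).  Applying the batch shift to all genes of
both phenotypes is exactly the global-offset case that RDE cancels.

What the generator does **not** emulate: count noise (negative binomial),
dropouts, library-size variation, outlier samples, or baseline mean
differences between genes.  Passing the simulation benchmarks therefore
demonstrates the mechanics of the method under its own generative
assumptions, not performance on real sequencing data.

## Benchmarks and their design

All benchmark sizes were chosen as the smallest instances at which the
phenomena are stable: ng_per_group = 30 (270 genes), ns = 100 per
phenotype, 5 replicate seeds.

* **Pattern recovery.** Pipeline gene scores are ranked against the planted
  truth: RDE scores against DE-positives, RDC scores against DC-positives
  (ROC-AUC, averaged over seeds).
* **Batch robustness.** The batch shift is applied to a 20 % gene subset of
  the *phenotype-2 matrix only* — a residual batch artifact confounded with
  phenotype, the only configuration in which a mean-difference baseline is
  affected at all (a shift applied identically to both phenotypes cancels
  in any mean-difference statistic, module-based or naive).  Shifted
  no-pattern genes then genuinely look differentially expressed, so *every*
  score degrades; the comparison is how gracefully.  Module-level scores
  degrade less than the per-gene |Δmean| baseline on average, because
  module membership pools shifted genes together and the module SNR is
  driven by the module's dominant expression pattern rather than each
  gene's own shifted mean — but the margin is modest and can flip on
  individual replicate sets; the benchmark reports the seed-averaged
  degradation of both rankings so the comparison is visible rather than
  hidden in a pass/fail.
* **Noise stability.** Repeatedly draw 50 genes, cluster them from one
  phenotype's data before and after adding `N(0, 0.5)` noise, and compare
  the before/after ARI of the spectral-embedding route against clustering
  the raw |PCC| adjacency rows directly.  The Laplacian eigenbasis
  truncates to the leading structure, so edge-level correlation jitter is
  filtered out and the spectral route wins in a clear majority of draws.

## Numerical conventions and degenerate inputs

* Population (ddof = 0) standard deviations everywhere a σ appears in the
  IIC and SNR formulas; this is what makes the IIC↔PCC identity exact.
* Constant genes inside a phenotype have undefined correlations: their
  graph edges are set to 0 with a warning (a zero-degree node is then a
  hard error naming the gene); constant members are dropped from MEs; a
  fully constant module raises a degenerate-module error, which the
  pipeline converts to an SNR of 0 for that module.
* Eigensolves use LAPACK `eigh` on the symmetrized matrix; PCA is a plain
  SVD with deterministic sign fixing; rank-deficient component requests
  are clipped to the rank with a warning.
* All randomness flows from one seed: the pipeline spawns one child seed
  per phenotype pair (`numpy` SeedSequence), so identical inputs and seed
  give byte-identical output files.
* K-Means is a heuristic under either metric; convergence is declared on
  stable assignments with a 300-iteration cap and the final inertia is
  logged.

## Known limitations

* The module SNR assigns identical scores to all genes of a module, so
  within-module ranking is flat and ROC curves are step-shaped.
* With no structure at all (every gene "none"), K-Means must still cut the
  single noise blob into K pieces and a gene's two instances fall on either
  side of a cut independently, so the diagonal fraction of the MC table is
  far below 1 even though every module's SNR is near 0.  Conserved-ness of
  individual genes is only meaningful when the embedding has real
  structure; the scores remain well behaved regardless.
* Single-gene modules cannot receive a DC eigengene (no pair), and get a
  DC SNR of 0.
* The DC benchmark detects connectivity *differences*; two phenotypes with
  equal λ but disjoint masks would be indistinguishable in expectation at
  the mean-adjacency level and are not part of the design.
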