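# Methods

## Analysis model

`cernet` infers competing-endogenous-RNA (ceRNA) relationships between
long RNAs (lncRNA, circRNA) and mRNAs through the miRNAs they are predicted
to share. The chain assumes:

* a two-group design (e.g. small vs large yellow follicles) with at least
  two — by default three — biological replicates per group;
* abundances already quantified (FPKM for long RNAs, TPM for miRNAs);
  quantification, alignment and coding-potential classification are out of
  scope and happen upstream;
* a predicted miRNA→target table from external sequence-based tools;
  `cernet` filters it, it never predicts binding sites itself;
* the sponge mechanism leaves two correlation footprints across samples:
  miRNA and target anticorrelated (more free miRNA, more repression), and
  the two targets of a shared miRNA positively co-expressed.

### Stage by stage

**Differential expression.** Welch's unequal-variance t on
log2(x + pseudocount), two-sided; both groups constant and equal gives
p = 1, constant and unequal p = 0. Benjamini–Hochberg step-up runs within
each RNA class separately (the classes are measured and analysed as
separate experiments). Long RNAs are DE at |log2FC| ≥ 1 (non-strict) and
FDR < 0.05 (strict); miRNAs at |log2FC| ≥ 1 and raw p < 0.05 — miRNA DE
screens conventionally use the unadjusted p on the TPM scale. The Welch
surrogate is *not* a count model: it ignores mean–variance coupling and
library-size estimation that negative-binomial DE tools model, and is
labelled `welch_t_on_log2(surrogate)` in every manifest. Fold change is
log2((mean_B + c)/(mean_A + c)) with pseudocount c = 0.01 FPKM/TPM
(configurable), which bounds the fold change of features touching zero.

**Edge filter.** Spearman's ρ is Pearson on mid-ranks (exact under ties;
the 6Σd²/n(n²−1) shortcut is wrong with ties). Predicted pairs where both
members are DE (configurable to all features) are scored across *all*
samples, both groups pooled: the filters describe co-variation along the
biological contrast, not within-group noise. Retention at ρ < −0.7 is
strict; with n = 6 distinct ranks, |ρ| > 0.7 requires near-perfect
monotonicity (a single adjacent rank swap already gives |ρ| = 0.943, and a
random within-group ordering typically falls below 0.8), so this cutoff is
a sharp, nearly-binary gate at small n. Constant vectors have undefined
correlation; such pairs are dropped and counted, never scored.

**Candidate pairs.** Every (lncRNA|circRNA, mRNA) pair sharing ≥ 1 retained
miRNA is scored by Pearson r on log2(x + c) (raw-scale optionally); kept at
r > 0.9 strict. Log scale is the default because FPKM/TPM are heavy-tailed
and a single high-abundance sample would otherwise dominate the moment
correlation; Spearman needs no such choice, being rank-invariant.

**Shared-MRE test.** With universe size N, K miRNAs targeting the ceRNA, M
targeting the mRNA and s shared (targeting = retained-edge relation, so the
test conditions on the same evidence the network displays), the pair
p-value is the hypergeometric upper tail P(X ≥ s), summed in log space
(lgamma binomials + log-sum-exp) and symmetric in (K, M). Pairs pass at
p < 0.05 strict, uncorrected — a deliberate mirror of the conventional raw
p-gate at this stage; BH can be applied downstream from the emitted table.

*Universe choice.* N defaults to **all expressed miRNAs** in the matrix.
The conservative alternative — only miRNAs with ≥ 1 retained edge — sounds
safer but collapses in sparse designs: a pair sharing its sole regulator
has p = 1/N, and with a handful of retained miRNAs 1/N can never reach
0.05, so no sole-sponge pair is ever callable regardless of evidence
strength. Real transcriptomes carry hundreds of expressed miRNAs, which is
the regime the expressed-universe default reproduces. Both alternatives
("retained", "de") remain configurable, and the policy is recorded in the
run manifest because every pair p-value depends on it.

**Triads and network.** One triad per (significant pair, shared miRNA).
Triads merge into an undirected typed graph; edges are deduplicated by
unordered node pair, so an edge appearing in many triads counts once for
degree — connectivity is read off the drawn network, not the triad list.
Hubs are the top-k nodes by degree, ties broken lexicographically for
reproducibility. Per-gene subnetworks take the listed mRNAs, their
neighbours, and all edges among those nodes; the union of per-mRNA
subnetworks covers the full network.

**cis/trans lncRNA targets.** cis: protein-coding genes whose interval gap
to the lncRNA locus is ≤ 10,000 bp ("within 10 kb" is inclusive),
closest-edge to closest-edge, strand-agnostic, overlapping loci at distance
0 — no TSS anchoring or strand rule is imposed because none is part of the
convention being implemented. trans: genome-wide |Pearson r| ≥ 0.95,
non-strict. Note the deliberate asymmetry in strictness: SCC/PCC gates are
printed as strict inequalities, the trans gate as ≥.

**Enrichment.** Generic one-sided over-representation: the same
hypergeometric core with N = background, K = term size (intersected with
the background), M = query size, s = hits; BH across terms. The background
defaults to all features of the query's class in the expression matrix. No
GO/KEGG database is bundled; annotations are an input table.

## Synthetic data

The generator emulates the statistical skeleton the analysis assumes, not
RNA-seq itself.

* **Background features** are mutually independent log-normals: per-feature
  baseline log2 abundance ~ Normal(3.0, 1.5) — spanning roughly 0.5–100
  FPKM, a plausible dynamic range for expressed transcripts — plus additive
  per-sample log2 noise of sd `noise_sd` (default 0.1; multiplicative on
  the raw scale, matching the positive, heavy-tailed character of
  FPKM/TPM).
* **Planted triads** couple three features through a latent per-sample
  follicle-state signal z. z is the group indicator (0/1) plus a stratified
  within-group offset pattern: offsets evenly spaced in
  [−latent_sd, +latent_sd] (default 0.15), shuffled independently within
  each group and per triad. The miRNA decreases in z
  (log2 = a − planted_log2fc·z + ε) while ceRNA and mRNA increase
  (log2 = c + planted_log2fc·z + ε), ε ~ Normal(0, noise_sd²),
  planted_log2fc default 1.5. Latent coupling rather than vector copying
  keeps the three profiles distinct; the stratified offsets make the
  within-group ordering of z noise-free and sum to zero, so (i) at
  noise_sd = 0 planted Spearman is exactly −1 and planted log2-Pearson
  exactly +1, (ii) recovery degrades gracefully and monotonically as
  noise_sd grows, and (iii) the planted group contrast is exactly
  planted_log2fc. An earlier iid-jitter design failed all three at once:
  adjacent latent values could nearly coincide, so measurement noise alone
  flipped ranks and inflated the n = 3 variance estimates.
* **Target table**: the true (miRNA→ceRNA) and (miRNA→mRNA) rows plus
  decoy rows pairing background miRNAs with background long RNAs
  (`decoy_target_fraction` of the table, default 0.5; a dataset with no
  planted triads gets a 20-row all-decoy table).
* **Intervals**: protein-coding loci every 30 kb on one synthetic
  chromosome; the first lncRNA exactly 10,000 bp from gene 0 and the second
  exactly 10,001 bp from gene 1 to pin the cis-window boundary; remaining
  lncRNAs 2 kb from their partner gene; circRNA loci on a separate
  chromosome so they never enter cis assignment.
* **Canonical conditions**: 2 × 3 samples, 60 background features split
  20 mRNA / 10 lncRNA / 6 circRNA / 24 miRNA, 5 planted triads,
  noise_sd 0.05. The 29-miRNA universe is deliberately above 20: a sponge
  pair sharing a single miRNA has p = 1/N, so the universe must exceed 20
  for genuine pairs to clear p < 0.05 — the same regime as a real
  transcriptome with hundreds of expressed miRNAs, scaled to desk size.

What passing tests on this generator do **not** show: robustness to count
noise and library-size effects (no negative-binomial layer), to correlated
background co-expression programs, to partially overlapping MRE sets, or to
the thousands-of-features scale of a real transcriptome. They do show that
the statistics, thresholds and bookkeeping are implemented exactly as
specified and that the chain recovers exactly the structure it claims to
detect.

## Numerical choices

* Hypergeometric tail in log space; P(X ≥ 0) = 1 by convention; results
  clipped to [0, 1].
* Correlations clipped to [−1, 1]; computed via centred dot products.
* BH: stable mergesort ordering, step-up with reverse cumulative minimum,
  capped at 1; output order = input order; q ≥ p always holds.
* All table outputs sorted on deterministic keys; floats written via
  `repr` so write→read round-trips are exact and repeated runs are
  byte-identical.
* Degenerate inputs: constant vectors raise `UndefinedCorrelationError`
  upstream and are dropped with a logged count downstream; empty stages
  propagate empty, correctly-typed tables.
* Single integer seed drives all randomness through one
  `numpy.random.Generator`.

## Problem sizes

The test suite and `scripts/acceptance.py` measure recovery on ensembles of
25 simulated datasets (125 planted triads), DE calibration on 50–100
datasets, and exhaustive oracle checks up to N = 12 (hypergeometric
enumeration over all C(N, M) draws) and n = 6 (all 720 sample orderings for
the Spearman null) — sizes at which brute-force enumeration is exact and
the full suite stays fast on one CPU.

## Known limitations

* The DE surrogate is not DESeq2/edgeR; absolute DE counts on real count
  data will differ from count-model results, especially for low-abundance
  features. The surrogate's place in the chain, not its power, is what the
  package tests.
* The shared-MRE p-value is sensitive to the universe definition; there is
  no universally agreed choice, which is why it is configurable and
  logged.
* "Connectivity" is plain degree; no betweenness or other centrality.
* circRNA identifiers are opaque features: quantification per back-splice
  junction vs host gene is upstream's concern.
* Correlation filters pool both groups; with strong group separation a
  between-group mean shift alone can produce large correlations — this is
  inherent to the method being implemented, not a bug, and is why DE gating
  precedes the filters.
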