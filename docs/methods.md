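# Methods

## Scope and data model

The package analyzes *post-alignment* representations only: BED6 intervals
for CLIP clusters (score = read count), ChIP peaks (score = peak height,
name = bound protein), miRNA loci and 3'UTR/CDS annotations; FASTA for
mature miRNA (RNA alphabet) and target sequences (DNA alphabet); a
4-column TSV for per-CpG bisulfite counts (raw methylated/unmethylated
counts, never percentages); and a per-dataset expression-statistics TSV
(log₂FC, corrected p). Read alignment, peak calling, and the differential
expression fits that produce those statistics are upstream of this package.
All coordinates are 0-based half-open; the miRNA start site is the locus
5' end in transcription direction (interval start on +, end − 1 on −).

## Target calling

CLIP clusters are filtered by the second-quartile cutoff: a cluster
survives when its read count is **strictly greater than the median** of
all cluster counts. The operation is deliberately not idempotent — the
median shifts on reapplication — and it assumes background clusters
dominate the low-count tail. When the input is known to be background-free
the pipeline's `apply_cluster_filter` flag should be off: a median cut on
pure signal discards half of the true clusters by construction.

Surviving clusters are kept only if they overlap ≥ 1 bp of a 3'UTR or CDS
interval on the same chromosome; a cluster overlapping both classes is
labeled 3'UTR (canonical site biology; affects the label, not the edge).
Seeds are mature-sequence positions 2..k+1 (k ∈ {6,7,8}; configurable) and
a site is a perfect reverse-complement match lying strictly inside the
cluster interval (an optional flank widens the search window). No wobble
pairing, no position-1 adenine anchor, no thermodynamic or conservation
scoring. ChIP peaks are assigned to a miRNA when the peak midpoint falls
within 5000 bp upstream to 1000 bp downstream (defaults; configurable) of
the start site in transcription direction.

## Activation selection

Strict inequalities throughout, matching the printed thresholds: per
dataset up ⇔ log₂FC > 1 ∧ p < 0.01; selection ⇔ frequency > 0.5 (genes) or
> 0.25 (miRNAs). The fold-change threshold is applied symmetrically in log
space. The frequency denominator is the number of datasets in which the
entity was measured (a `denominator="all"` switch divides by all datasets
instead). If both directions clear the threshold the larger frequency
wins; an exact tie logs a warning and yields ns. These conflict rules are
this package's choices for cases the selection rule leaves open.

## Network analyses

Edges are typed (miRNA_target: miRNA → protein; promoter_binding:
protein → miRNA), self-loops are rejected, and duplicate evidence merges
into a single edge with an evidence list. The "activated" subnetwork keeps
up-regulated miRNAs and down-regulated proteins. Shortest paths respect
edge direction, so miRNA-to-miRNA influence necessarily alternates through
proteins. Hub ranking counts distinct binding miRNAs per protein
(optionally state-restricted), with dense descending ranks, percentile =
100·rank/n, and hubs at percentile ≤ 1. Module decomposition runs greedy
modularity maximization on the undirected projection with sorted node
insertion for determinism; the algorithm choice is a design decision where
any "densely connected modules" method would do, and it is pluggable.

## Eigengene scoring

SCORE = dᵢ/d_max + 2·|cor(Xᵢ, E)|. E is computed in the WGCNA
module-eigengene convention: first left singular vector of the
column-standardized samples × nodes matrix, unit norm, sign fixed so the
mean correlation with the columns is non-negative. Degree is the node's
total (in+out) degree within the scored subnetwork (in/out-only modes
available) and d_max the maximum among scored miRNAs, so at least one node
attains the full degree term. Constant expression columns get |cor| = 0
with a warning rather than propagating NaN; ties in score break by degree,
then lexical id. The eigengene is computed per supplied (sub)network — the
caller chooses whether that is the whole network or a module.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) per term (scipy's stable survival
function), Bonferroni multiplier = number of terms actually tested (K ≥ 1
in the universe), no DAG propagation, no FDR alternatives. The
dual-reference scheme is `AnnotationSet.restricted_to`, which re-derives
N, K, n for a restricted universe.

## Methylation profiling

Bins are left-open/right-closed, `(edge, edge+bin]`, with edges every
`bin_bp` (default 100) from −2000; a CpG exactly on an edge joins the bin
upstream of it. Bin centers span [−2000, +2000). Offsets are
transcription-oriented (negative = upstream on either strand). Empty bins
are missing, never zero-filled — a zero would masquerade as an
unmethylated observation. Region means are coverage-weighted, which makes
them invariant to bin refinement.

Group comparison is a two-sided Wilcoxon rank-sum on per-miRNA region
means: exact by enumeration of all rank assignments when both groups have
≤ 12 members (with complete ties this correctly yields p = 1), otherwise
the normal approximation with continuity and tie correction. A rank test
was preferred over a t-test for bounded fractions; the per-bin difference
series reports down-group minus up-group means with the argmax offset.
The methylation–expression correlation is Pearson's r between upstream
region means and per-miRNA log₂FC with the usual t-transform p (n − 2 df).

## The synthetic generator

The generator emulates the study conditions as a planted circuit on
per-entity contigs (one chromosome per gene and per miRNA locus — no
whole-genome coordinates). Defaults: 80 genes, 60 miRNAs (30 up / 30 down,
states otherwise ns), 6 TF genes, 6 expression datasets, target density
0.08 plus a planted hub miRNA targeting 60 % of genes, TF→miRNA density
0.25. Methylation: CpGs every 50 bp within ±2000 bp, baseline fraction
0.2, coverage 50, and for down-regulated miRNAs a Gaussian bump (σ =
250 bp) of height 0.4 centered 1000 bp upstream, strand-aware. Expression
rows for up/down entities clear the per-dataset thresholds in every
dataset unless flip/dropout noise is requested (defaults 0). The CLIP
background rate is a free parameter (default 0.5 background clusters per
true site, counts drawn below the true-cluster band) — no empirical noise
model stands behind it.

Two constructions make zero-noise recovery exact rather than merely
likely: miRNA sequences are rejection-sampled so no miRNA's 6-nt seed
motif occurs inside any other miRNA's 8-nt site motif, and emitted true
clusters cover exactly the planted 8-bp site footprint, so a strict
inside-cluster scan can only rediscover the planted pair. The node
expression matrix drives all miRNAs from one latent factor with the hub
loading on it almost noiselessly, so the hub holds both the maximum degree
and the maximum eigengene correlation.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: read-level noise and mapping artifacts,
miRNA family/sequence similarity (real seeds collide constantly),
non-canonical and wobble sites, correlated background clusters at
expressed loci, batch structure across expression datasets, CpG-island
spatial structure, and any coupling between network topology and
methylation beyond the planted group difference.

## Problem sizes and statistical behavior

The validation suite runs the full pipeline on the default-sized circuit
(140 nodes, ~500 edges) across 20 seeds for recovery, and 100 seeds for
the methylation group test's power and calibration. Under the default
conditions the upstream comparison rejects at p < 0.01 in every seed while
the downstream region is a genuine null: its rejection rate at the 5 %
level is ~5 % by construction, so individual seeds (like the worked
example's p = 0.036) occasionally dip below 0.05, and the suite checks the
rate against binomial bounds rather than expecting every seed to stay
above the threshold.

## Known limitations

* The quartile cutoff's interpretation (strictly above the median of all
  cluster counts) is one reading of a loosely specified rule; it is
  configurable at the pipeline level.
* Promoter windows, seed-length sets, and the module algorithm are
  biological conventions, not fitted quantities.
* Exact Wilcoxon enumeration is combinatorial; groups above 12 members per
  side fall back to the normal approximation.
* Activation consumes pre-computed per-dataset statistics; it does not
  re-fit differential expression.
* Enrichment treats annotation terms as flat sets; no ontology structure.
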