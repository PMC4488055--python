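# mircircuit

Systems-level analysis of miRNA function in pluripotent stem cells, built
around a physical miRNA–protein interaction network. The package turns
post-alignment evidence — CLIP-seq binding clusters, ChIP-seq peaks,
per-dataset differential-expression statistics, and bisulfite methylation
counts — into a directed regulatory network and a set of downstream
analyses: cross-dataset activation selection, eigengene-based importance
ranking, hub and module detection, shortest regulatory paths to the
pluripotency core factors, functional enrichment, and strand-aware
methylation profiling around miRNA start sites.

It is aimed at computational biologists who want each of those stages as a
tested, composable library function (plus a thin CLI), together with a
seeded synthetic ground-truth generator that makes the whole pipeline
verifiable by parameter recovery.

## The model

**Network.** Two kinds of directed physical edges: miRNA → protein
(repression, evidenced by a CLIP cluster in the target's 3'UTR/CDS
containing a perfect reverse-complement match of the miRNA seed, positions
2..k+1 for k ∈ {6,7,8}) and protein → miRNA (a ChIP peak in the miRNA's
promoter window, default −5000..+1000 bp around the start site). Only
first-neighbor physical interactions enter the graph. CLIP clusters are
pre-filtered by a second-quartile read-count cutoff (score strictly greater
than the median).

**Activation.** Per dataset, an entity is up (down) when adj. p < 0.01 and
log₂FC > 1 (< −1). The activating frequency is the fraction of datasets
carrying such a call; genes are selected when it strictly exceeds 50 %,
miRNAs when it exceeds 25 %.

**Importance score.** For node *i* with degree *dᵢ* and expression vector
*Xᵢ* over samples,

    SCORE_i = d_i / d_max + 2·|cor(X_i, E)|

where *E* is the network eigengene — the first principal component of the
column-standardized node-expression matrix — and the correlation is
Pearson. Scores lie in [0, 3].

**Hubs.** Proteins are ranked by miRNA binding number (distinct incoming
miRNA-target edges, optionally restricted to up-regulated miRNAs); the top
1 % by dense-rank percentile are flagged as hubs.

**Enrichment.** One-sided hypergeometric over-representation with
Bonferroni correction over the terms tested, supporting a dual-reference
scheme (entire annotation universe vs. a restricted universe such as all
up-regulated genes).

**Methylation.** Per-CpG counts within ±2000 bp of each miRNA start site
are binned (default 100 bp) on a transcription-oriented axis; per-miRNA
upstream/downstream means are compared between up- and down-regulated
miRNA groups with a Wilcoxon rank-sum test (exact for small groups), the
per-bin group difference localizes where the groups diverge, and upstream
methylation is correlated with expression change.

## Worked example

Generate a background-free synthetic circuit and run every stage:

```python
from mircircuit.synthetic_data import TruthConfig, generate_truth, write_dataset
from mircircuit.pipeline import PipelineConfig, run_all

truth = generate_truth(TruthConfig(rng_seed=1, noise_cluster_rate=0.0))
write_dataset(truth, "demo/data")
config = PipelineConfig.for_dataset(
    "demo/data", "demo/out",
    apply_cluster_filter=False,          # no background to remove
    core_factor_ids=truth.core_factor_ids,
    rng_seed=1,
)
result = run_all(config)
print(result.scores[0].node, round(result.scores[0].score, 3))
print(result.enrichment.iloc[0]["term"])
print(result.meth_comparisons[["region", "p_value"]])
print(result.meth_difference.attrs["argmax_offset"])
```

prints

```
miR001 2.999
DEV
       region       p_value
0    upstream  2.987833e-11
1  downstream  3.631412e-02
-1050.0
```

miR001 is the planted hub: it has the maximum degree and near-unit
eigengene correlation, so its SCORE approaches the maximum of 3. The
planted "DEV" annotation term tops the enrichment of the activated
subnetwork's proteins. Down-regulated miRNAs carry significantly higher
upstream methylation than up-regulated ones (p ≈ 3·10⁻¹¹) while the
downstream comparison is a null (p ≈ 0.04 here is an ordinary 5 %-level
fluctuation), and the largest group difference sits at −1050 bp — the bin
containing the planted bump center at −1000 bp.

The same run is available from the shell:

```
mircircuit simulate --seed 1 --outdir demo/data
mircircuit run-all --config demo/config.json
```

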