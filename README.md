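# stimprofiler

Analysis toolkit for bulk RNA-seq of sorted lymphocyte populations (Th,
CTL, NK, B cells) profiled at steady state and after anti-CD3 stimulation,
across healthy donors and two autoimmune patient groups with
disease-activity scores.

The package implements the full downstream pipeline:

| module | what it does |
| --- | --- |
| `synthetic_data` | simulator emulating the study design (3 donor groups, 4 cell types, 3 conditions) with planted DEGs, an interferon-response signature scaled by activity class, co-regulated modules, co-expression partners and ligand-receptor events — plus a matching gene-set catalog (GMT) and ligand-receptor table with ground truth for recovery testing |
| `preprocess` | FPKM normalization, marker-signature and PCA-based sample QC, the 45–99.5 percentile gene filter, per-donor log2 relative expression (stimulated vs PBS control), in-sample centralization (median/SD) of steady-state values |
| `diffexpr` | per-gene Wilcoxon rank-sum between donor groups (exact null for small groups without ties), BH adjustment, FDR-ranked top up/down gene lists, PCA overview |
| `genesets` | GMT I/O, size filtering, hypergeometric over-representation with the forced p=1 rule for sets outside 3–300 in-universe genes, signed KS cumulative-distance regulatory scores, activity-class stratification (Low 1–3 / Moderate 4–7 / High ≥8), driver-gene selection |
| `coexpression` | guilt-by-association: per-stratum Euclidean distances to interferon genes (√n-normalized), permutation null resampled from the pooled distances across strata, BH per (stratum, gene), union hand-off to ORA |
| `clustering` | k-means gene modules over per-stratum mean profiles, retention of clusters with <500 genes, ORA-based marker annotation, silhouette sweep for k |
| `cellcomm` | donor-level ligand-receptor detection (ligand in the top 10 % of up-regulated genes in the sender, receptor expressed in the receiver), Fisher exact group tests, communication-gene enrichment, per-cytokine group statistics on externally supplied activity Z-score matrices (t-test for the stimulated layer, rank-sum for steady state) |

## CLI

```sh
# write a synthetic dataset with planted ground truth
stimprofiler simulate --config cfg.toml --out data/ --seed 1

# counts -> fpkm / relative / centralized layers with QC flags
stimprofiler preprocess --counts data/counts.tsv --lengths data/gene_lengths.tsv \
    --samples data/samples.tsv --markers data/sets.gmt --lo 45 --hi 99.5 --out prep/

# differential expression, gene-set scores, co-expression, modules, cell-cell
stimprofiler deg --matrix prep/relative.tsv --layer relative \
    --samples prep/samples.tsv --groups HD SLE --cell B --out deg.tsv
stimprofiler regscore --matrix prep/centralized.tsv --samples prep/samples.tsv \
    --gmt data/sets.gmt --out regscore.tsv
stimprofiler gba --matrix prep/centralized.tsv --samples prep/samples.tsv \
    --gmt data/sets.gmt --ifn-pattern "IFN" --n-perm 10000 --seed 1 --out gba/
stimprofiler cluster --matrix prep/relative.tsv --layer relative \
    --samples prep/samples.tsv --k 10 --gmt data/sets.gmt --out clusters/
stimprofiler cellcomm --relative prep/relative.tsv --fpkm prep/fpkm.tsv \
    --samples prep/samples.tsv --lr data/lr_pairs.tsv --groups HD SLE \
    --out interactions.tsv

# everything at once on a fresh simulation
stimprofiler run-all --out run/ --seed 1
```

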