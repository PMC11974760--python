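# repdrift

Longitudinal antibody-repertoire drift analysis for AIRR-seq heavy-chain
data: clonotype collapsing, Morisita–Horn repertoire similarity, turnover and
persistence statistics, public-clonotype analysis, and replicate-level
repertoire classification — plus a synthetic V(D)J repertoire generator with
registered ground truth so every stage is verifiable without a
billion-read dataset.

## Who this is for

Immunologists and computational biologists studying how a donor's circulating
B-cell repertoire changes over years: how much of the repertoire turns over,
which clonotypes persist, which are shared between individuals, and whether a
handful of genetic usage features identify a sample's donor and timepoint.
Input is an annotated rearrangement table (AIRR-style TSV with V/J calls,
junction, isotype, mutation count, and subject/timepoint/replicate labels);
raw-read processing and germline annotation are upstream of this package.

## The statistics at its core

**Clonotype** = identical (V gene, J gene, CDRH3 amino-acid sequence), with
CDRH3 defined as the IMGT junction minus its conserved Cys/Trp anchors.

**Morisita–Horn similarity** over (V gene, J gene, CDRH3 length) "species"
with counts xᵢ, yᵢ and totals X, Y:

    CH = 2 Σᵢ xᵢyᵢ / [ (Σᵢ xᵢ²/X² + Σᵢ yᵢ²/Y²) · X · Y ]

0 for disjoint repertoires, 1 for identical composition, abundance-weighted.
Computed with bootstrap rarefaction over a grid of sampling depths, as
pairwise replicate matrices with single-linkage clustering, and stratified by
isotype/mutation compartments.

**Turnover / persistence** between timepoints, at clonotype or
nucleotide-sequence level:

    turnover%    = 100 · (appearing + disappearing species) / total species
    persistence% = 100 − turnover%

**Classification**: a one-versus-rest linear SVM on concatenated V-gene,
J-gene and CDRH3-length frequency blocks, evaluated leave-one-biological-
replicate-out with per-class ROC AUC across training/test sizes.

## Worked example

```python
import repdrift as rd

# Morisita-Horn on two tiny species distributions
ch = rd.morisita_horn({"IGHV3-23|IGHJ4|13": 2, "IGHV1-69|IGHJ6|15": 1},
                      {"IGHV3-23|IGHJ4|13": 1, "IGHV1-69|IGHJ6|15": 3})
print(ch)                     # 0.7058823529411765  (= 12/17 exactly)

# simulate 2 subjects x 2 timepoints x 6 replicates x 1000 sequences,
# 2% of lineages persisting between timepoints
cfg = rd.SimulationConfig(n_sequences_per_replicate=1000,
                          persistent_fraction=0.02, seed=42)
records, truth = rd.simulate_study(cfg)          # 24000 annotated records

s1 = records[records.subject == "S1"]
rep = rd.persistence_report(s1[s1.timepoint == "T1"], s1[s1.timepoint == "T2"])
print(rep.as_dict())
# {'level': 'clonotype', 'n_appearing': 3317, 'n_disappearing': 3145,
#  'n_shared': 65, 'n_total': 6527, 'turnover_pct': 99.004..., 'persistence_pct': 0.9958...}

res = rd.evaluate_loro(records, size_grid=[50, 500], n_repeats=3, seed=0)
print(res.auc_table)
#  class_label  size  mean_auc
#        S1@T1    50  0.660494
#        S1@T1   500  0.993827
#        S1@T2    50  0.842593
#        S1@T2   500  1.000000
#        ...
```

Reading the output: with only 2% of lineages persisting, ~99% of observed
clonotypes turn over between timepoints (`persistence_pct` ≈ 1%), yet the
classifier pins down subject and timepoint nearly perfectly once 500
sequences per replicate are available — repertoires are simultaneously
unstable in content and individually identifiable in composition. Observed
persistence is sampling-depth-bounded; `rd.sharing_vs_depth` quantifies how
sharing grows with depth.

The same pipeline runs from the shell:

```bash
repdrift simulate --out-dir out/ --seed 42
repdrift run-all --seed 42 --out-dir out/        # simulate -> collapse ->
                                                 # similarity -> persistence -> classify
repdrift collapse --input out/rearrangements.tsv --out out/clonotypes.tsv
```

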