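# tadapipe

**Targeted DamID (TaDa) signal processing, RNA-polymerase occupancy gene
calling, metagene aggregation and comparative statistics.**

Targeted DamID profiles gene expression in a tissue of interest without cell
isolation: a fusion of *E. coli* Dam methyltransferase to an RNA-polymerase
subunit (e.g. RPB-6, common to all polymerase complexes) deposits adenine
methylation at GATC motifs within transcribed genes, while a Dam–NLS-GFP
control captures background methylation of accessible chromatin.  Sequencing
the methylated fragments from both channels yields, per **GATC fragment** *f*
(the interval between consecutive GATC motifs — the method's resolution
unit), the occupancy score

```
score_f = log2( (rpm_fusion_f + ψ) / (rpm_control_f + ψ) )
```

with reads-per-million scaling and a symmetric pseudocount ψ (default
0.5 RPM).  Profiles from all fusion × control replicate pairings are averaged
into one signal track per cell type × stage.  A gene is called **expressed**
when its mean fragment score exceeds an empirical permutation null matched on
fragment count, at a Benjamini–Hochberg FDR below 0.05; miRNAs are called on
windows extended 500 bp on each side.  The package also provides
TSS/TES-anchored metagene aggregation with gene-body pseudo-length scaling,
Pearson/PCA sample comparisons with joint-outlier exclusion, rank-binned
comparison against external quantitative transcriptomes, and
hypergeometric / Monte-Carlo significance of gene-set overlaps.

A synthetic experiment generator (`tadapipe.simulate`) produces complete
TaDa experiments — genome, annotation, fusion/control replicate alignments
and a ground-truth table — so every pipeline stage is testable end to end.

## Worked example

Simulate a small experiment (400 kb genome, 80 genes of which 20 are
expressed, 2 fusion + 2 control replicates) and analyse it:

```bash
tada simulate --seed 7 --chrom-length 400000 --genes 80 --mirnas 10 \
    --depth 400000 --out demo               # genome.fa, annotation.gff3, *.bed, truth.tsv
tada fragments --genome demo/genome.fa --out demo/frags.gff3
tada signal --map demo/frags.gff3 \
    --fusion demo/fusion_1.bed,demo/fusion_2.bed \
    --control demo/control_1.bed,demo/control_2.bed \
    --out demo/profile.bedgraph
tada call --profile demo/profile.bedgraph --map demo/frags.gff3 \
    --annotation demo/annotation.gff3 --biotype protein_coding \
    --seed 1 --out demo/gene_calls.tsv
```

which prints

```
1564 fragments over 1 chromosomes
averaged 4 pairwise profiles -> demo/profile.bedgraph
18/80 features expressed at FDR<0.05
```

`gene_calls.tsv` lists, per gene, the number of overlapping GATC fragments,
the mean log2 occupancy score, the permutation p-value, the BH-adjusted FDR
and the expressed flag:

```
feature_id  n_fragments  mean_score  fdr
gene0003    12           2.869403    0.000615
gene0009    17           2.874983    0.000615
gene0023     6           2.450509    0.004705
```

Scoring against `demo/truth.tsv`: all 18 called genes are truly expressed
(18/20 of the simulated expressed genes recovered; no false calls).  Mean
scores of 2–4 log2 units over expressed gene bodies and ≈0 elsewhere match
the dynamic range expected of RNA-polymerase TaDa tracks.

The same steps are available as a single orchestrated run
(`tada run --config run.json`) that writes the fragment map, per-pair and
averaged profiles, gene/miRNA call tables, metagene profile, correlation and
PCA tables, plus a manifest that makes the run byte-reproducible.  Library
use mirrors the CLI: see `tadapipe.simulate_experiment`,
`tadapipe.normalize_ratio`, `tadapipe.call_features`,
`tadapipe.metagene_profile`, `tadapipe.hypergeometric_overlap`.

## Layout

| module | contents |
|---|---|
| `tadapipe.genome` | FASTA IO, GATC motif scan, fragment maps (GFF3/BED), within-gene fragment statistics |
| `tadapipe.annotation` | GFF3 gene models, longest-transcript extents, strand-aware extension |
| `tadapipe.signal` | SAM/BED read counting, log2 ratio normalisation, KDE-mode centering, profile averaging, bedGraph IO |
| `tadapipe.calling` | permutation nulls, expressed-gene/miRNA calling, BH FDR, set intersections |
| `tadapipe.metagene` | TSS/TES-anchored aggregation, pseudo-length scaling, isoform coverage |
| `tadapipe.compare` | binned Pearson/PCA, rank-binned comparison, overlap significance |
| `tadapipe.simulate` | synthetic genomes, annotations, experiments, ground truth |
| `tadapipe.pipeline` | config validation and end-to-end orchestration |

See `docs/methods.md` for the model, parameter and design documentation.
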