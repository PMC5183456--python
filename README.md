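# phagelgt

Reconstruction and analysis of phage-mediated lateral gene transfer
(transduction) networks from annotated bacterial genomes.

Temperate phages occasionally package a gene from one host and deposit it,
still inside a prophage, in another. `phagelgt` finds such events — bacterial
genes residing in prophage regions — infers the donor genome of each one with
a phylogenetic test, assembles the events into a directed donor→phage→recipient
network (the *dLGT network*), and asks which barriers shape transfer: genome
similarity, codon usage, GC content, habitat, and gene function. It also
quantifies purifying selection on transferred genes via pairwise dN/dS. A
configurable simulator with a complete ground-truth ledger supports
end-to-end validation of every stage.

## Quick start (CLI)

```
phagelgt simulate --seed 1 --out data/            # synthetic dataset + ledger
phagelgt validate data/                           # input sanity checks
phagelgt run-all data/ --seed 1 --out run/        # full pipeline
```

`run-all` writes plain-text artifacts (`protein_families.tsv`,
`phage_entities.tsv`, `donor_calls.tsv`, `edges.tsv`, `network.json`,
`randomization.json`, `barriers.json`, `selection.tsv`, `selection.json`) and
a `manifest.json` recording the configuration, seeds, and the filter funnel.
Outputs are byte-identical across runs with the same seed. Individual stages
are also exposed as subcommands (`cluster`, `infer-donors`, `build-network`,
`randomize`, `barriers`, `selection`) and resume from existing artifacts.

## Worked example

The `analysis/` drivers reproduce the study pipeline on a simulated dataset
(50 genomes, 250 CDS each, 200 planted events, 5 expected post-transfer
substitutions per transferred gene, planted dN/dS = 0.12). Run them in order:

```
$ python analysis/01_simulate.py
genomes: 50
planted events: 200 (22 autologs)
dataset written to .../results/data

$ python analysis/02_cluster.py
prophages clustered: 49
phage entities: 47 (46 singletons)

$ python analysis/03_infer_donors.py
queries: 200, resolved: 199
excluded (donor_clade): 1
precision vs ledger: 199/199 = 1.000

$ python analysis/04_network.py
{
  "component_sizes": [97],
  "largest_component": 97,
  "n_bacteria": 50,
  "n_edges": 211,
  "n_phages": 47,
  "total_weight": 399
}
{
  "autolog_fraction": 0.11,
  "genomes_with_autologs": 16,
  "max_genes_per_genome": 2,
  "n_autologs": 22,
  "n_events": 200
}
host range (donor-recipient ranks): {'class': 65, 'domain': 3, 'family': 63,
                                     'genus': 20, 'order': 15, 'species': 33}

$ python analysis/06_barriers.py
AUC s_cds: 0.772 (TPR 0.59, FPR 0.18)
AUC s_gs: 0.772 (TPR 0.59, FPR 0.18)
AUC d_cu: 0.715 (TPR 0.55, FPR 0.21)
AUC s_gc: 0.678 (TPR 0.66, FPR 0.37)
AUC habitat_shared: 0.576 (TPR 0.38, FPR 0.23)
same-habitat fraction (paths): 0.447 (p = 0.000999000999000999)
functional composition p: 0.598

$ python analysis/07_selection.py
{
  "autologs": {
    "median_dn": 0.0015046083721119714,
    "median_ds": 0.018870462558786952,
    "median_omega": 0.08229592324920146,
    "n_tested": 22,
    "n_total": 22,
    "p_ds_gt_dn": 2.384185791015625e-07,
    ...
  },
  "n_events_scored": 199
}
```

Reading the output: donor inference resolved 199 of 200 planted events and
every resolved call matches the ledger. Genome-sequence similarity (`s_gs`,
k-mer Jaccard on prophage-masked chromosomes) is the strongest predictor of
who transfers with whom, habitat sharing the weakest — yet same-habitat
transfer is still far more common than in degree-preserving network
randomizations (p ≈ 0.001). In autologs (donor = recipient, so the genomic
copy is a same-genome reference), synonymous divergence significantly exceeds
non-synonymous divergence and the median dN/dS of 0.082 recovers the planted
purifying regime (0.12, within sampling noise of 22 events).

## Library layout

| Module | Contents |
| --- | --- |
| `phagelgt.simulate` | Synthetic genomes, prophages, planted transfers, ground-truth ledger |
| `phagelgt.seqsim` | Affine-gap global alignment, k-mer Jaccard, GC and codon-usage measures |
| `phagelgt.clustering` | Reciprocal best hits, Markov clustering, orthologous phage entities |
| `phagelgt.trees` | Poisson-corrected distances, neighbor joining, midpoint rooting, consolidation test |
| `phagelgt.donors` | Homolog families and phylogenetic donor calls |
| `phagelgt.network` | dLGT network assembly, components, host range, autolog census |
| `phagelgt.randomize` | Degree-preserving switching nulls and empirical p-values |
| `phagelgt.barriers` | ROC analysis, habitat transfer matrix, functional composition tests |
| `phagelgt.selection` | NG86 pairwise dN/dS, codon adaptation index, autolog summary |
| `phagelgt.pipeline` | Stage orchestration, manifest, deterministic artifacts |
| `phagelgt.io` | FASTA/GFF3/TSV round-trip and input validation |

See `docs/methods.md` for the methods and the design decisions behind them.

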