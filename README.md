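# m6apred

A toolkit for predicting N6-methyladenosine (6mA) sites in fixed-length
DNA/RNA sequence windows. It provides:

- **Sequence I/O** (`m6apred.seqio`): FASTA reading/writing of fixed-length,
  center-adenine sequence sets (one file per class), DNA/RNA alphabet
  inference and normalization, dataset validation, and class balancing.
- **Encoders** (`m6apred.encoders`): five feature families — positional
  one-hot (`binary`), k-mer frequencies (`kmer`), sliding-window base
  composition (`enac`), k-spaced pair composition (`cksnap`), and
  nucleotide chemical properties (`ncp`) — plus the canonical 15-scheme
  benchmark grid (`enumerate_schemes()`).
- **Models** (`m6apred.modeling`): logistic regression and random forest,
  each with a documented default and a tuned configuration
  (LR: C=11.29, max_iter=2500, solver=saga; RF: max_features=sqrt,
  n_estimators=1000), plus a seeded randomized hyperparameter search scored
  by cross-validated accuracy.
- **Evaluation** (`m6apred.evaluation`): Acc/Sens/Spec/MCC computed from the
  confusion table, rank-based AUC, stratified k-fold cross-validation, and
  a cross-species transfer protocol (train on one species, test unchanged
  on another).
- **Synthetic benchmarks** (`m6apred.fixtures`): seeded generators for
  balanced, center-A, motif-enriched datasets with tunable signal strength,
  and species pairs with tunable motif divergence — so everything is
  testable without external downloads.
- **Pipeline + CLI** (`m6apred.pipeline`, `m6apred.cli`): grid experiments
  writing per-cell JSON reports, a flat `summary.csv`, and a reproducibility
  manifest.

## CLI

```sh
# generate a synthetic benchmark (FASTA pair + config sidecar)
m6apred simulate --n-pos 200 --n-neg 200 --signal 0.8 --seed 1 --out-prefix sim

# encode it with one scheme
m6apred encode --pos sim_pos.fasta --neg sim_neg.fasta --scheme enac-2 --out feats.csv

# cross-validate the full 15-scheme grid with both model families
m6apred cv --pos sim_pos.fasta --neg sim_neg.fasta \
    --schemes grid15 --models logistic_regression:default,random_forest:default \
    --k 5 --seed 1 --outdir results/cv

# tuned models: use mode "tuned"; randomized search: mode "search"
m6apred cv --pos sim_pos.fasta --neg sim_neg.fasta \
    --schemes enac-2 --models random_forest:tuned --outdir results/tuned

# randomized hyperparameter search on its own
m6apred tune --pos sim_pos.fasta --neg sim_neg.fasta \
    --family logistic_regression --scheme kmer-4 --n-iter 25 --out tune.json

# cross-species transfer (train on A, test on B, juxtaposed with B's own CV)
m6apred transfer --train-pos a_pos.fasta --train-neg a_neg.fasta \
    --test-pos b_pos.fasta --test-neg b_neg.fasta \
    --schemes binary,enac-2,ncp --models random_forest:tuned --outdir results/xfer

# expected layout of the external benchmark (never downloaded by this tool)
m6apred fetch-benchmark
```

Outputs: one `report_<cell>.json` per (scheme, model) cell, a `summary.csv`
with columns `species,scheme,param,model,tuned,protocol,acc,sens,spec,mcc,auc,seed`,
a `manifest.json` echoing the configuration and library versions, and (for
transfers) a `juxtaposition.csv` with the transfer-minus-CV accuracy deltas.
Reruns with the same configuration are byte-identical.

## Notes

- Sequences must be canonical A/C/G/T/U; IUPAC ambiguity codes are rejected
  at I/O rather than masked, since silent masking would corrupt the
  frequency encoders.
- T and U are interchangeable throughout: every encoder yields identical
  features for a sequence and its T<->U image, so DNA- and RNA-alphabet
  datasets mix freely.
- Similarity-based redundancy filtering (CD-HIT) is an upstream concern and
  is not performed here.
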