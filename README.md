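# metacontact

A two-stage neural-network meta-predictor for protein residue–residue
contacts and directed backbone hydrogen bonds, built from a single
multiple sequence alignment plus per-residue secondary-structure and
solvent-accessibility predictions.

**Stage 1** scores every residue pair with a 672-feature vector: three
column-block windows (9 + 9 + 5 blocks of 27 features: amino-acid + gap
frequencies, SS probabilities, solvent exposure, entropy, missing-data
flag), six coevolution channels (mutual information, normalized MI, mean
contact potential, and three coupling channels), a 16-bin
sequence-separation code, and 29 global alignment-quality features
(composition, SS fractions, log length / depth / effective depth, mean
entropy). **Stage 2** re-scores each pair with a 731-feature vector: two
11-column windows, the separation code, and an 11×11 window of the
stage-1 contact map. Each stage is an ensemble of six single-hidden-layer
networks (55 logistic units), one per contact labelling scheme
(Cβ–Cβ cutoffs 6 / 7.5 / 8 / 8.5 / 10 Å, plus 8 Å with an 11 Å negative
exclusion band); outputs are averaged and mapped to estimated PPVs by a
fitted `a·log(b·x + c)` curve. A variant head (`2HB`) predicts *directed*
backbone hydrogen bonds (donor N within 3.5 Å of acceptor O, separation
≥ 5).

The package also ships the evaluation machinery (top-L/k precision at
sequence separation ≥ 5 / ≥ 23, the adjacent-prediction redundancy
filter, rank-consensus baseline, method-overlap counting) and a
synthetic-family generator (toy folds with permuted sheet topologies,
coevolving alignments, mock SS/solvent predictions) so the entire
pipeline trains and evaluates at desk scale with no downloads.

## Command line

```bash
# build a synthetic fixture tree (PDB + PSICOV/A3M alignments + SS2 + solvent)
metacontact synth -n 10 --seed 1 --out-dir fixtures/

# alignment statistics and coevolution channels
metacontact alnstats fixtures/fam0000/fam0000.aln
metacontact coevo fixtures/fam0000/fam0000.aln --out-dir scores/

# train the two-stage ensembles (plus the hydrogen-bond head)
metacontact train fixtures/ --out-dir models/ --seed 1 --hb

# predict contacts (CASP-RR output) and directed hydrogen bonds
metacontact predict fixtures/fam0000/fam0000.aln \
    --ss2 fixtures/fam0000/fam0000.ss2 --solv fixtures/fam0000/fam0000.solv \
    --model-dir models/ --out fam0000.rr
metacontact hbond fixtures/fam0000/fam0000.aln \
    --ss2 fixtures/fam0000/fam0000.ss2 --solv fixtures/fam0000/fam0000.solv \
    --model-dir models/ --out fam0000.hb

# score a prediction file against a structure
metacontact eval fam0000.rr fixtures/fam0000/fam0000.pdb
```

Externally computed coupling-score files (plain `i j score` lists or
dense matrices) can replace the built-in estimators with
`--external psicov=... --external ccmpred=...`; provenance is logged.

## Layout

```
src/metacontact/
  alignment_io.py     PSICOV / A3M / FASTA readers and writers
  profile_stats.py    column profiles, identity clustering, N_eff, global stats
  coevolution.py      MI, nMI, contact potential, mean-field DCA,
                      inverse-covariance scores, APC, external score files
  structure_labels.py PDB parsing, multi-threshold contact labels,
                      directed hydrogen-bond labels
  feature_assembly.py 672/731-feature vectors, separation code, SS2/solvent IO
  model.py            networks, ensemble training, PPV calibration, prediction
  evaluation.py       top-L/k precision, redundancy filter, consensus, overlap
  synthetic_data.py   toy folds, coupled MSA simulation, fixture rendering
  cli.py              command-line front end
  data/               packaged contact-potential table
```
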