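# transpred

Substrate-specificity prediction for membrane transport proteins from
sequence alone.

Membrane transporters move ions, sugars, amino acids, electrons and
macromolecules across lipid membranes, but sequence similarity within and
between substrate classes is low, so BLAST-style annotation transfer
largely fails at the substrate level. `transpred` takes the
machine-learning route: it encodes each protein as a fixed-length numeric
descriptor, trains one binary RBF-kernel support vector machine per class
(class members positive, all other classes negative), and evaluates the
resulting one-vs-rest ensemble with stratified five-fold cross-validation.

Eight classes are modelled: amino-acid/oligopeptide, anion, cation,
electron, protein/mRNA, sugar and "other" transporters, plus a
non-transporter control class.

## Feature encoders

| encoder | dim | definition |
|---------|-----|------------|
| AAC  | 20  | amino acid composition, 100·n_i/L (sums to 100) |
| DPC  | 400 | dipeptide composition, 100·n_ij/(L−1) (sums to 100) |
| PHC  | 11  | % residues in each physico-chemical class (charged, aliphatic, aromatic, …; classes overlap) |
| AAI  | 49  | mean of 49 0–1-normalised biochemical residue properties: P̄_i = (Σ_k P_i(s_k))/L |
| PSSM | 400 | evolutionary profile: for residue pair (a,b), Σ over positions with query residue a of the log-odds score for b, divided by L, then min–max scaled to [0,1] |

Hybrids concatenate encoders; AAI+PSSM (449 components) is the strongest
combination. PSSM profiles are read from standard PSI-BLAST ASCII files
(`psiblast -num_iterations 3 -evalue 1e-3 -out_ascii_pssm`); the library
parses them but never runs the search.

Per class the evaluator reports sensitivity (= coverage), specificity,
accuracy, the Matthews correlation coefficient

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the ROC-AUC (trapezoidal, equal to the pairwise rank statistic).

A seeded synthetic-data module generates eight-class datasets with
controllable between-class compositional separation and
conservation-shaped PSSM fixtures, so the whole pipeline is testable with
no downloads.

## Worked example

```bash
python examples/simulate_and_crossvalidate.py
```

simulates 30 sequences for each of the 8 classes (separation 0.15, seed 1),
encodes them as amino acid composition, grid-searches the SVM
hyperparameters (γ over 1e-5…10, positive-class cost factor 1…4) and
cross-validates:

```
dataset: 240 sequences, 8 classes of 30
grid search: gamma=0.001, cost_factor=3

stratified 5-fold CV (one-vs-rest, threshold 0):
                 sensitivity  specificity  accuracy  coverage  mcc  auc
amino_acid             80.00        97.62     95.42     80.00 0.80 0.98
anion                  73.33        93.33     90.83     73.33 0.60 0.96
cation                 73.33        98.10     95.00     73.33 0.77 0.98
electron               73.33        96.19     93.33     73.33 0.71 0.97
protein_mrna           83.33        94.29     92.92     83.33 0.71 0.96
sugar                  70.00        98.10     94.58     70.00 0.72 0.98
other                  80.00        97.62     95.42     80.00 0.79 0.94
non_transporter        80.00        97.14     95.00     80.00 0.77 0.98
average                76.67        96.55     94.06     76.67 0.73 0.97
```

Every per-class accuracy sits far above the 87.5% majority baseline and
every AUC is close to 1: the ensemble recovers the planted compositional
signal. With separation 0 the same pipeline stays at the baseline, as it
must. The other example scripts cover feature encoding
(`encode_features.py`), training/persistence/prediction
(`train_and_predict.py`), compositional-bias analysis
(`composition_bias.py`) and the PSSM round-trip (`pssm_workflow.py`).

## Command line

The same workflows are available as subcommands:

```bash
transpred simulate --out-dir data --n-per-class 30 --separation 0.15 --seed 1
transpred encode   --fasta data/sequences.fasta --encoder AAC --out features.tsv
transpred train    --features features.tsv --manifest data/manifest.tsv \
                   --encoder AAC --gamma 1e-3 --cost-factor 3 --out model.joblib
transpred predict  --features features.tsv --model model.joblib --encoder AAC \
                   --out predictions.tsv
transpred evaluate --features features.tsv --manifest data/manifest.tsv \
                   --gamma 1e-3 --cost-factor 3 --out-dir eval
```

## Layout

```
src/transpred/    io, features, model, evaluate, synthetic, cli modules
                  + data/ (residue-class YAML, property table TSV)
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   model, assumptions, parameters, limitations
```
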