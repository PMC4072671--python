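# Methods

## Problem and model

Substrate-level annotation of membrane transporters is a multi-class
sequence classification problem with weak homology signal: proteins
transporting the same substrate often share little sequence identity.
`transpred` therefore classifies on global sequence descriptors rather
than alignments. Eight classes are modelled (amino-acid/oligopeptide,
anion, cation, electron, protein/mRNA, sugar, other transporters, and a
non-transporter control). For each class a binary soft-margin SVM with an
RBF kernel is trained with that class positive and the union of the other
seven negative; the eight binary models form a one-vs-rest ensemble.

Multi-class fusion — the argmax of the eight decision scores with ties
resolved toward the earlier class in the fixed order (amino_acid, anion,
cation, electron, protein_mrna, sugar, other, non_transporter) — is
deliberately simple plumbing. The per-class binary models are the
scientific objects; all reported metrics are per-class one-vs-rest
metrics, and the fusion rule is documented, deterministic and
replaceable. The transporter/non-transporter call is likewise defined on
one model only: a sequence is called a transporter when the
non-transporter model's decision score falls below a threshold (0 by
default, i.e. the model's own boundary).

## Encoders

All component orderings use the single alphabetical residue order
ACDEFGHIKLMNPQRSTVWY, declared once in `constants.py`. PSI-BLAST PSSM
columns are re-mapped to this order at parse time.

* **AAC** (20): percentage of each residue, 100·n_i/L. Sums to 100
  exactly (up to float rounding; the tests assert 1e-9).
* **DPC** (400): percentage of each consecutive dipeptide with the number
  of pairs, L−1, as denominator, so the vector sums to 100. (Normalising
  by L would sum to 100·(L−1)/L; the pair-count denominator keeps the
  "percentage of dipeptides" semantics.) Requires L ≥ 2, enforced at
  sequence validation.
* **PHC** (11): percentage of residues belonging to each physico-chemical
  class. The class table ships as editable YAML. The published table
  prints *polar* and *neutral* with identical member sets {D,E,R,K,Q,N};
  the default table reproduces it verbatim and the loader warns once, so
  users can substitute a corrected neutral set without code changes.
* **AAI** (49): arithmetic mean of each of 49 residue-level biochemical
  properties over the sequence. The property table is configuration data
  (TSV, 49 rows × 20 residue columns, entries in [0,1]), not code. The
  shipped `aaindex49_synthetic.tsv` is a deterministic synthetic stand-in
  with the same contract as the published 0–1-normalised 49-property
  residue scale set, whose source is no longer retrievable; any table
  with the same layout can be passed to `load_property_table`. No test
  or result depends on specific table values beyond the homopolymer
  identity (a homopolymer's AAI vector equals the residue's column).
* **PSSM** (400): for each ordered residue pair (a,b), the sum of the
  log-odds score for b over all positions whose query residue is a,
  divided by L, then linearly (min–max) scaled to [0,1] per vector. If
  the 400-vector is constant the scaling is undefined; it is mapped to
  the all-0.5 vector to keep the encoder total. Per-vector scaling is
  the default; the unscaled vector is available (`scale="none"`) for
  callers who prefer dataset-global scaling — the choice is stated here
  because the published description ("standard linear function") does
  not fix it.
* **Hybrids**: concatenation in caller order with encoder-prefixed
  component names; AAI+PSSM has 449 components.

Only the 20 standard residues are encoded. FASTA input is strict by
default (non-standard letters are an error naming residue and position);
a lenient mode drops them with a logged count, since curated datasets
may retain B/X/Z placeholders.

## SVM layer

The backend is scikit-learn's `SVC`. Two knobs map onto the classical
SVM-Light options: `cost_factor` (the `-j` analogue) is implemented as
`class_weight={1: cost_factor}`, multiplying the error penalty of
positive examples — essential when one class is a small fraction of the
dataset; `gamma` is the RBF width. The shared regularisation constant C
defaults to 1. Grid search maximises mean K-fold CV accuracy over a
default grid of 7 log-spaced gammas (1e-5…10) × cost factors {1,2,3,4},
with deterministic tie-breaking toward smaller gamma, then smaller cost
factor. Feature matrices are consumed as-is: encoders already produce
bounded components, and no hidden standardisation is applied (asserted
by test).

Model persistence uses a joblib archive containing a format-version tag,
the encoder tag, component names and the fitted estimators; version
mismatch and truncation raise explicit errors.

## Evaluation

Stratified five-fold cross-validation: fold assignment is drawn once per
dataset from the eight-class labels (seeded `StratifiedKFold`), so all
eight one-vs-rest problems share the same splits, and per-class fold
sizes differ by at most one. Stratification is a deliberate choice over
plain random partitions: with classes of a few dozen members,
unstratified folds can lose a class entirely. Per-fold metrics are
arithmetically averaged (a pooled-count mode exists for diagnostics);
AUC is computed per fold and averaged the same way.

Definitions: Sn = TP/(TP+FN)·100 (identical to coverage by definition —
asserted as an invariant), Sp = TN/(TN+FP)·100, Acc = (TP+TN)/N·100, and
MCC with the convention that a zero factor in the denominator yields 0,
the random-prediction value. Scores exactly at the threshold count as
positive. The ROC curve is computed over all distinct thresholds and its
trapezoidal area equals the pairwise rank statistic
P(s⁺ > s⁻) + ½P(tie); the test suite checks this equality exactly
against an O(n²) oracle.

## Synthetic data

The generator emulates the one structural fact the classifiers rely on:
transporter classes differ in amino acid composition, concentrated in a
small set of residues (D, E, K, F, G, I, L, S show the highest
across-class variance in real data). Each synthetic class starts from a
background residue-frequency vector (approximate average composition of
globular proteins) and adds `separation` worth of probability mass to a
rotating window of three of those eight residues (weights 0.5/0.3/0.2),
renormalised with a 1e-4 frequency floor. `separation=0` gives eight
identical classes (null model); the default 0.15 plants a signal of a
few percentage points per residue — comparable to the compositional
differences seen between real transporter classes — which is detectable
but not trivial at the default length of 150 residues.

Sequences are i.i.d. draws from the class frequency vector with Gaussian
lengths (mean 150, CV 0.15, floor 10). Default class size is 30
sequences, giving 240-sequence studies that cross-validate in seconds.
PSSM fixtures put scores around +conservation·10 on the true-residue
column and −conservation·10 elsewhere, plus integer-rounded Gaussian
noise, and are written in the full 40-column PSI-BLAST ASCII dialect so
the parser is exercised against the real format.

What the generator does **not** emulate: residue order structure
(sequences are i.i.d., so DPC carries no extra signal beyond AAC),
transmembrane topology, realistic evolutionary profiles, length–class
correlations, and the class-size imbalance of real datasets (synthetic
classes are balanced). Passing tests therefore demonstrate that the
pipeline recovers compositional class structure when present and reports
chance-level performance when absent — not that any particular accuracy
will be achieved on real transporter data.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the full simulate → encode → train →
evaluate pipeline is bit-for-bit reproducible, and the acceptance script
re-runs it twice to prove it.

## Numerical and design choices

* MCC zero-denominator → 0; degenerate Sn/Sp (no positives/negatives
  evaluated) → 0.
* Score == threshold counts positive (documented, tested).
* Grid-search ties break toward smaller gamma then smaller cost factor.
* Fold assignment, not fold iteration order, is the reproducibility
  contract: the same seed yields the same assignment array.
* Problem sizes in the test and acceptance runs (30/class for recovery,
  15–20/class elsewhere) were chosen so a full study is a few seconds of
  CPU while keeping ≥6 positives per CV fold, the minimum for stable
  per-fold ROC estimates.

## Known limitations

* The shipped property table is a synthetic stand-in; AAI-based results
  on real proteins require substituting a real 49-property table.
* One-vs-rest decision scores from separately trained SVMs are not
  calibrated against each other; the argmax fusion is a heuristic and no
  abstention rule is provided.
* PSSM generation is external; the library documents the `psiblast`
  invocation but never runs it.
* Real-data benchmarks (curated transporter sets, homology-filtered
  splits, comparisons against alignment-based baselines) are outside the
  package's scope.
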