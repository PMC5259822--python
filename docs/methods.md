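# Methods

## Model

MoRF prediction is cast as per-residue binary classification on windowed
profile features. For a sequence of length *L*, an HH-suite `.hhm` file
supplies an *L*×20 matrix of match-emission scores *N*, converted to linear
probabilities *p* = 2^(−N/1000); the `*` entry (an effectively infinite
score) maps to *p* = 0, the limit of the transform. The 10 insert/transition
columns of the 30-column profile are parsed and discarded — only emission
composition enters the features.

A residue's feature vector is the flattened `w × 20` block of probability
rows centred on it, `w = 2·flank + 1`, rows ordered N→C terminal.
Positions outside the sequence contribute all-zero rows, at training and at
prediction time alike, so every vector has the fixed dimension the SVM
needs. (The window/flank relation `w = 2·flank + 1` reconciles the two
parameterisations in which ensemble members are specified.)

### Region labels and sampling

Each training sequence is partitioned into **MoRF** residues (annotated
intervals), **Flank** residues (within 12 positions of a MoRF boundary,
truncated at the termini), and **Others**. When two MoRFs lie closer than
two flank lengths, the residues between them stay Flank — a conservative
choice that keeps ambiguous residues out of the negative pool. Positives
are one window per MoRF residue. Negatives are windows centred on Other
residues, drawn uniformly **without replacement from the pool of all Other
positions across the training set**, `ratio` per positive. Pooling globally
(rather than per sequence) keeps the ratio exact even for sequences with
tiny or empty Other segments; requesting more negatives than the pool holds
is an error rather than silent sampling with replacement.

### The ensemble

Nine support-vector classifiers, all with penalty C = 1000:

| model | window | kernel  | gamma  | neg:pos |
|------:|-------:|---------|-------:|--------:|
| 1     | 11     | rbf     | 0.0038 | 2       |
| 2     | 7      | rbf     | 5      | 2       |
| 3     | 3      | sigmoid | 5      | 2       |
| 4     | 13     | rbf     | 0.0038 | 2       |
| 5     | 9      | rbf     | 5      | 1       |
| 6     | 5      | sigmoid | 5      | 2       |
| 7     | 7      | rbf     | 0.0038 | 2       |
| 8     | 13     | rbf     | 5      | 2       |
| 9     | 7      | sigmoid | 5      | 1       |

Member *i* draws its negatives and seeds its classifier with
`master_seed + i`, so the nine members train on different negative sets
while the whole run is reproducible from one seed. Raw SVM decision values
of RBF and sigmoid kernels live on incompatible scales, so each member
emits a sigmoid-calibrated (Platt) class probability — implemented with
scikit-learn's `CalibratedClassifierCV(SVC(...), method="sigmoid", cv=5,
ensemble=False)`, which calibrates on unshuffled stratified 5-fold
cross-validated decision values and refits the SVC on all data. The fused
propensity at each residue is the plain arithmetic mean of the nine member
probabilities; no per-model normalisation is applied beyond calibration,
which already makes the scores commensurable.

## Evaluation

* **AUC** over pooled residues: trapezoidal area under the empirical ROC,
  identical to the Mann–Whitney pairwise statistic with ties counted ½.
* **FPR / accuracy at fixed TPR** (operating points 0.222 and 0.389): the
  threshold is the *largest* score cutoff whose TPR reaches the requested
  level — a vertex of the empirical ROC, no interpolation — so results are
  exactly reproducible from finite score sets. Note this rule makes
  accuracy at low TPR levels reflect a deliberately conservative operating
  point, not the best achievable accuracy.
* **Success rate**: fraction of sequences whose mean propensity over MoRF
  residues *strictly* exceeds the mean over non-MoRF residues; ties fail,
  and sequences lacking one of the classes leave the denominator (logged).
* All non-MoRF residues, flanks included, count as negatives.

## Synthetic data generator

The generator emulates the *compositional* footprint of MoRFs in profile
space, nothing more. Per sequence: a background amino-acid composition is
drawn from a symmetric Dirichlet(10) (moderately uneven, as real
disordered-region compositions are); the MoRF composition is the background
interpolated with weight *s* (signal strength) toward a fixed contrast
composition concentrated on hydrophobic/aromatic residues (F I L M V W Y),
the residue classes enriched in real binding interfaces. Per-residue
emission rows are Dirichlet draws around their region's composition with
concentration κ = 100 (small row-to-row noise, mimicking a reasonably deep
alignment); flank rows blend linearly from MoRF to background composition
over the 12-residue flank (soft boundaries). Rows are quantised to integer
hhm scores by inverting the transform with rounding (probabilities below
2^(−32.767) become `*`), so written files round-trip through the parser
within the score grid's quantisation error. Residue letters are sampled
from each row's composition.

Defaults, chosen once as a realistic desk-scale regime: 50 sequences of
60–120 residues, one MoRF of 5–25 residues each, *s* = 0.8.

**What passing tests show — and don't.** At *s* = 0 the MoRF and background
rows are exchangeable and held-out AUC sits at chance; at *s* = 0.9 the
default ensemble recovers the planted signal nearly perfectly. This
validates the plumbing (features see exactly the planted contrast, sampling
and fusion behave, no label leakage), not biological performance: real
MoRFs differ from their context in subtler, position-dependent ways, real
profiles carry phylogenetic correlation and alignment-depth artefacts, and
none of that is modelled. Numbers on synthetic data say nothing about AUC
on curated benchmarks with HHblits profiles.

## Numerical choices and degenerate inputs

* Score quantisation: nearest integer; exact round trip on the grid.
* Windows at the termini zero-pad; a zero row contributes nothing to an
  RBF/sigmoid kernel product beyond its constant term.
* Sampling is without replacement; an exhausted negative pool raises with
  advice to lower the ratio.
* Identical positive and negative inputs drive calibrated scores to ≈ 0.5.
* Sequences present in FASTA but lacking a profile are skipped with a
  warning; annotations without a sequence are an error.
* Benchmark problem sizes (60 training / 40 held-out sequences, five
  null replicates) were chosen as the package's desk-scale study
  conditions; they keep a full pipeline run in single-digit minutes on one
  core.

## Known limitations

* The ensemble hyper-parameters are fixed constants of the method; the
  grid search that selected them is not re-run here.
* Platt calibration on ~10³ samples carries its own variance; member
  scores near 0/1 should not be read as probabilities in the strict sense.
* The terminal zero-padding convention means residues near sequence ends
  carry systematically sparser windows; on data where MoRFs avoid the
  termini this can contribute a small positional signal, visible as
  null-signal AUC slightly off 0.5 on some seeds.
* Multi-model `.hhm` files and binary HH-suite formats are not read.
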