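# morfhmm

Per-residue prediction of **molecular recognition features (MoRFs)** —
short (5–25 residue) segments of intrinsically disordered protein regions
that fold upon binding a partner — from evolutionary sequence profiles.

The predictor consumes HH-suite `.hhm` profile files (produced by HHblits
from iterative multiple-sequence-alignment search). Each residue *i* of a
length-*L* sequence is represented by the `w × 20` block of match-emission
probabilities of a sliding window centred on it (`w = 2·flank + 1`,
zero-padded at the termini), where profile scores *N* become linear
probabilities through

```
p = 2^(−N / 1000)
```

and only the 20 match-emission columns of the 30-column profile are used.
Nine support-vector classifiers — differing in kernel (RBF / sigmoid),
kernel width γ, window size w ∈ {3, 5, 7, 9, 11, 13} and negative sampling
ratio, all with penalty C = 1000 — each score every residue, and the final
propensity is their plain arithmetic mean ("common averaging"). Training
positives are windows centred on annotated MoRF residues; negatives are
drawn only from residues at least 12 positions away from any MoRF (the
12-residue *flanks* around each MoRF belong to neither class), each model
with its own random negative set.

A synthetic-data module fabricates FASTA + annotations + `.hhm` triplets
with planted MoRF composition signal of tunable strength, so the whole
pipeline can be trained and evaluated without running HHblits.

## Worked example

```bash
morfhmm simulate --n 30 --signal 0.9 --seed 5 --out sim/
morfhmm train --fasta sim/sequences.fasta --annotations sim/annotations.tsv \
              --profiles sim/profiles --seed 7 --out model/
morfhmm predict --model model/ --profiles sim/profiles --out scores.tsv
morfhmm evaluate --scores scores.tsv --annotations sim/annotations.tsv \
                 --out report.json
```

The prediction table has one row per residue:

```
seq_id	position	residue	score
syn0001	1	K	0.116914
syn0001	2	I	0.117814
syn0001	3	R	0.133638
...
```

`score` is the fused propensity in [0, 1]; higher means more MoRF-like.
No binary cutoff is shipped — different sequences support different
thresholds, so downstream users threshold the track themselves.
`evaluate` prints (here for the 30 training sequences themselves, so the
numbers are optimistic):

```json
{
  "auc": 0.9841918814675036,
  "success_rate": 1.0,
  "fpr_at_tpr": {"0.222": 0.0031876138433515485, "0.389": 0.009107468123861567},
  "accuracy_at_tpr": {"0.222": 0.8733256792958285, "0.389": 0.8951396861844623},
  "n_pos": 417, "n_neg": 2196, "n_sequences": 30
}
```

* **auc** — probability that a random MoRF residue outscores a random
  non-MoRF residue.
* **success_rate** — fraction of sequences whose mean MoRF score strictly
  exceeds the mean non-MoRF score.
* **fpr_at_tpr / accuracy_at_tpr** — false-positive rate and accuracy at
  the most conservative score threshold reaching the given true-positive
  rate (operating points 0.222 and 0.389).

To score real proteins, generate profiles externally, e.g.
`hhblits -i query.fasta -d <NR20> -ohhm query.hhm -n 4 -e 0.001`, then run
`morfhmm predict` on the directory of `.hhm` files.

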