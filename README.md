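# idrlig

Prediction of small-molecule interaction sites and interacting ligand
substructures in intrinsically disordered protein regions (IDRs).

IDRs lack a stable tertiary structure, so the lock-and-key tools of
structure-based drug design do not apply to them, and experimental data on
IDR–drug interactions is scarce. `idrlig` implements a sequence-only
pipeline that works around both problems: sequences are represented in a
fixed-size form that needs no alignment or structure, and the scarcity of
labelled IDR–ligand data is addressed by stepwise transfer learning from
large unlabelled corpora.

## The model

**Featurization.** A sequence of length *L* becomes a 20 × 20 × 20 tensor
of amino-acid pair frequencies

    f(a_i, a_j, k) = n(a_i, a_j, k) / Σ n,    k = j − i ≤ 19,

where `n(a_i, a_j, k)` counts ordered residue pairs at separation *k* and
layer *k* = 0 is a diagonal amino-acid frequency matrix, attenuated by a
factor 20. The tensor is then smoothed along the separation axis with
weights 1/4^|k−l| over a ±3 window. This representation accepts sequences
of any length and explicitly preserves two-residue motif information.

**Network.** Three parts share one architecture family:

* *encoder* — one convolution (filters spanning the full 20 × 20
  amino-acid plane, sliding along the separation axis), two dense layers,
  tanh at the 20-unit encoding vector `ve`;
* *decoder* — two dense layers expanding `ve` back to a 20 × 20 × 20
  decoded tensor `fd`;
* *predictor* — a mirror convolution over `fd`, a dense layer, and a
  softmax over the protogroup vocabulary `vp`.

**Training** proceeds in three steps, freezing earlier parts: (1) encoder +
decoder as an autoencoder under the loss 1 − |Pearson r| (Adam); (2) the
decoder alone against tensors restricted to ligand-interacting sites;
(3) the predictor alone with categorical cross-entropy (Adamax). A full
simultaneous retrain is available as an overfitting control.

**Decoding predictions.** Per-residue site scores are

    s_i = Σ_{l≤i} fd(a_l, a_i, i−l) + Σ_{l>i} fd(a_i, a_l, l−i),
    sn_i = s_i / max_l s_l,

and per-protogroup scores are `tn_m = vp_m / max vp`. Evaluation uses
ROC/AUC over a 0.00–1.00 threshold grid, operating points chosen by the
positive likelihood ratio (PLR = sensitivity/FPR) or the 2 × 2 chi-square
−log₁₀P, and GO enrichment (one-sided binomial) among encoding-space
nearest neighbours.

**Protogroups** are small compounds (≥ 4 heavy atoms) that act as
standalone ligands and recur as substructures of larger ligands. The miner
ranks library members by how many ligands contain them as an
element-labelled subgraph and selects a vocabulary in two passes (≥ 5
atoms first, then ≥ 4).

## Worked example

Evaluating a site predictor's operating point from its confusion matrix
(17 true positives, 26 false positives, 113 false negatives, 534 true
negatives):

```python
>>> from idrlig import confusion_metrics
>>> m = confusion_metrics(17, 26, 113, 534)
>>> round(m.sensitivity, 3), round(m.specificity, 3), round(m.PLR, 3)
(0.131, 0.954, 2.817)
>>> round(m.chi2_neglog10p, 2)
3.14
```

The predictor calls few sites but calls them accurately: sensitivity is
low (0.131) while specificity (0.954) and the positive likelihood ratio
(2.8 — positives are called almost three times more often among true sites
than non-sites) are high, a profile suited to drug design campaigns that
start from a small number of reliable target sites.

Training the desk-scale profile end to end on synthetic planted-motif
families and predicting on a held-out sequence:

```python
>>> from idrlig import NetworkConfig, Sequence, predict, train_autoencoder
>>> from idrlig.sequences import featurize
>>> from idrlig.synth import FamilySpec, gen_idr_sequences
>>> cfg = NetworkConfig.reduced(output_classes=3)
>>> seqs = gen_idr_sequences(FamilySpec("famA", motif=("Y", "G", 3)), 60, seed=11)
>>> bundle, history = train_autoencoder([featurize(s) for s in seqs], cfg, rng_seed=1)
>>> round(history[-1]["test_corr"], 2)   # held-out reconstruction correlation
0.64
>>> encoding, scores, groups = predict(bundle, seqs[0])
>>> len(encoding), len(scores.normalized) == len(seqs[0]), round(float(groups.raw.sum()), 6)
(20, True, 1.0)
```

The same pipeline is available from the shell:

```
idrlig make-fixtures --out fixtures --seed 1
idrlig train --step 1 --fasta fixtures/sequences.fasta --out w1.h5 --seed 1 --classes 3
idrlig train --step 2 --manifest fixtures/records.tsv --weights-in w1.h5 --out w2.h5 --seed 1 --classes 3
idrlig predict --fasta fixtures/sequences.fasta --weights w2.h5 --out predictions.json
```

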