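# toxqsar

QSAR (quantitative structure–activity relationship) binary toxicity
classification for chemical screening, built around the Tox21
nuclear-receptor and stress-response endpoints (AhR, AR, AR-LBD, ARE,
Aromatase, ATAD5, ER, ER-LBD, HSE, MMP, p53, PPARγ). The package is for
computational toxicologists and cheminformaticians who need to triage
compounds by predicted activity when experimental toxicity data are
missing: new industrial chemicals, environmental contaminants, candidate
structures.

## What it does

Given compounds as SMILES with binary activity labels, the pipeline is:

1. **Featurize** — validate and canonicalize SMILES, then compute 2D
   descriptor or fingerprint matrices (RDKit 2D descriptor set, MACCS,
   path-based, atom-pair, circular and E-state fingerprints, or all
   combined). Descriptor columns containing any missing value are deleted;
   compounds are never dropped.
2. **Split** — stratified 8:2 train/test partition, seeded.
3. **Screen features** — rank descriptors by information gain
   (IG(X) = H(Y) − Σ_b p(b)·H(Y|b), base-2, equal-width bins) and run
   backward elimination: drop the lowest-ranked feature, retrain, record the
   validation AUC of every subset down to two features, keep the subset with
   the best validation AUC.
4. **Train and evaluate** — any of seven classifier families (DT, NB, SVM,
   kNN, RF, XGB, MLP) behind one train/score interface; metrics are
   ACC = (TP+TN)/(TP+FP+TN+FN), F1 = 2TP/(2TP+FP+FN), SE, SP, and ROC-AUC
   with the usual interpretive bands (≥0.8 excellent, 0.7–0.8 good,
   0.6–0.7 fair, 0.5–0.6 poor).
5. **Gate by applicability domain** — min-max normalize to the training
   range (X_nom = (X − X_min)/(X_max − X_min)), take the training centroid
   μ, and flag any query whose Euclidean distance
   D_E(x, μ) = √((x−μ)ᵀ(x−μ)) exceeds the maximum training distance as
   out-of-domain.
6. **Explain** — interventional Shapley attributions of the model score
   (exact coalition enumeration for small feature counts, seeded permutation
   sampling otherwise), summarized as the top-6 descriptors with their
   percentage share of total importance, summing to 100.

Synthetic generators (a Gaussian class-conditional descriptor table and a
toxicophore-labeled SMILES builder with a nitroaromatic alert) provide
offline, seeded test data for the whole pipeline.

## Worked example

```bash
toxqsar generate-fixture --kind smiles --n 120 --seed 5 --out tox_demo.csv
toxqsar train tox_demo.csv --descriptor-set rdkit_2d --algorithm RF \
    --seed 5 --step 20 --min-features 10 --out-dir demo_run
```

The training log (stderr) reports each stage:

```
[toxqsar] featurize: compounds=120 descriptors=210
[toxqsar] clean: descriptors_in=210 descriptors_kept=210
[toxqsar] split: train=96 test=24
[toxqsar] select: candidates=210 selected=10
[toxqsar] evaluate: auc=1.0 acc=1.0 band=excellent
[toxqsar] applicability_domain: threshold=1.6698 test_in_domain=24
```

120 substituted benzenes were featurized into 210 RDKit 2D descriptors,
information-gain elimination reduced them to 10, and the random forest
classifies the 24 held-out compounds perfectly (AUC 1.0 — the fixture's
activity is exactly the presence of an aromatic nitro group, which several
2D descriptors encode directly). All 24 test compounds fall inside the
applicability domain (threshold 1.67).

Prediction gates each query through SMILES validation and the domain check:

```bash
toxqsar predict demo_run/bundle \
    --smiles "Cc1ccc(cc1)[N+](=O)[O-]" --smiles "CCOC(=O)c1ccccc1" --smiles "C1CC"
```

```
id,input_smiles,canonical_smiles,valid,score,call,ad_distance,in_domain
s0,Cc1ccc([N+](=O)[O-])cc1,Cc1ccc([N+](=O)[O-])cc1,True,1.0,active,1.0588...,True
s1,CCOC(=O)c1ccccc1,CCOC(=O)c1ccccc1,True,0.0,inactive,0.8498...,True
s2,C1CC,,False,,invalid_smiles,,
```

4-nitrotoluene scores 1.0 (active, in-domain), ethyl benzoate 0.0
(inactive, in-domain), and the malformed SMILES `C1CC` is flagged per-row
without aborting the batch. `toxqsar explain` adds the top-6 descriptor
share table, and `toxqsar experiment` runs descriptor-set × algorithm grids
with paired before/after-screening metrics.

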