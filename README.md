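# xylact

Sequence-to-activity prediction for GH11 xylanases. Given only the amino-acid
sequence of a xylanase, `xylact` predicts (i) the halo-zone class the
producing *Bacillus subtilis* strain would show on xylan agar (Low / Medium /
High) and (ii) the enzyme's specific activity (IU ml⁻¹) under a fixed
pH/temperature assay condition. It is aimed at enzyme screeners who want to
rank candidate xylanases — e.g. from metagenome mining — before committing to
plate screening and DNS assays.

## The representation and the models

Each enzyme `E = E₁E₂…E_L` is encoded as an **amphiphilic pseudo amino acid
composition** (PseAAC) vector of `20 + 2λ` elements. The first 20 elements
are the residue frequencies `f₁…f₂₀`; the remaining `2λ` are sequence-order
correlation factors built from standardized hydrophobicity (`h¹`) and
hydrophilicity (`h²`) indices:

    τ₂ₖ₋₁ = (1/(L−k)) Σᵢ h¹(Eᵢ)·h¹(Eᵢ₊ₖ)
    τ₂ₖ   = (1/(L−k)) Σᵢ h²(Eᵢ)·h²(Eᵢ₊ₖ)        k = 1…λ,  λ < L

    eₖ = fₖ / (Σf + w·Στ)             1 ≤ k ≤ 20
    eₖ = w·τₖ₋₂₀ / (Σf + w·Στ)        21 ≤ k ≤ 20 + 2λ

With the defaults `λ = 7`, `w = 0.05` the vector has 34 elements and sums to
one. Both index tables (Tanford-type hydrophobicity, Hopp–Woods
hydrophilicity) are swappable CSV data files.

On top of the features sit the study's learner presets behind one
train/predict contract: 1-NN halo classification and 5-NN activity
regression (implemented natively, with deterministic tie-breaking), a
linear-kernel SVM, a 30-tree majority-vote random forest, a 10-tree random
forest regressor, AdaBoost over 50 regression trees, and Gaussian naive
Bayes. Models are evaluated by stratified 10-fold cross-validation and by
the jackknife (leave-one-out), with metrics computed once on the pooled
out-of-fold predictions: AUC / CA / F1 / precision / recall for
classification, MSE / RMSE / MAE / R² for regression.

The package ships the screening table of the 41 study strains (halo
diameters, printed classes, and activities for the 28 assayed strains in
three conditions: pH 4 / 60 °C, pH 4 / 26 °C, pH 6 / 26 °C) as a fixture,
plus a synthetic-study generator so every stage is testable without
laboratory data. The feature encoder is an sklearn transformer
(`PseAACEncoder`) and the native KNN models are sklearn estimators, so
everything composes with pipelines and model selection.

## Worked example

Simulate a 41-strain study, then jackknife the 5-NN activity regressor on
it:

```sh
$ xylact simulate --n 41 --sigma 50 --seed 7 --outdir demo
INFO xylact: simulated 41 sequences into demo (clipped 0 activities)

$ xylact evaluate --features demo/features.csv --table demo/strains.csv \
    --model knn_regressor --scheme jackknife --condition pH4_T26
{
  "condition": "pH4_T26",
  "config": {
    "family": "knn_regressor",
    "hyperparameters": {"metric": "euclidean", "n_neighbors": 5, "weights": "uniform"},
    "standardize": false
  },
  "metrics": {"MAE": 85.497835, "MSE": 11762.714681, "R2": 0.420264, "RMSE": 108.45605},
  ...
}
```

Each held-out strain's activity is predicted as the mean of its 5 nearest
feature-space neighbours; MAE ≈ 85 IU ml⁻¹ and R² ≈ 0.42 say the simulated
sequence signal explains a bit under half of the activity variance at this
noise level. The halo-threshold rule on the packaged fixture:

```sh
$ xylact label | head -4
accession,strain,halo_mm,printed_class,threshold_class,selected
AGO02713,a14h,4.6,M,M,1
AGO02715,d16d,5.7,H,H,1
AGO02724,d19d,5.0,M,M,1
```

The rule (L < 3.5 mm ≤ M ≤ 5.5 mm < H) matches the printed class for 40 of
the 41 strains, and the 4.0 mm selection cutoff recovers exactly the 28
assayed strains. `xylact reproduce` emits the full model × scheme ×
condition metric grid, flagging the deterministic KNN jackknife cells
`exact` and everything seed- or hyperparameter-dependent `approximate`.

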