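# Methods

## The encoding

A protein sequence of length `L` over the 20 canonical residues is mapped to
an amphiphilic pseudo amino acid composition vector of `20 + 2λ` elements.
The composition part is the vector of relative residue frequencies (fixed
alphabetical residue order A,C,D,…,Y). The sequence-order part consists of λ
tiers of correlation factors: the tier-k factor is the mean, over all L−k
residue pairs separated by k positions, of the product of a standardized
amino-acid index at the two positions. Each tier is computed twice — through
a hydrophobicity index and through a hydrophilicity index — interleaved so
that odd τ positions carry hydrophobicity and even positions hydrophilicity.
The final vector divides both parts by `Σf + w·Στ`, so with relative
frequencies (`Σf = 1`) all elements sum to one exactly.

Index standardization subtracts the 20-residue mean and divides by the
population standard deviation (denominator 20, not 19), matching the
conversion of the original pseudo-composition method. A constant index table
is rejected rather than silently producing zeros.

### Parameters

| parameter | default | meaning |
|---|---|---|
| λ | 7 | correlation depth; output dimension 20 + 2λ = 34; requires λ < L |
| w | 0.05 | weight of order terms against composition in the normalization |
| hydrophobicity | Tanford-type table | swappable CSV (`residue,value`) |
| hydrophilicity | Hopp–Woods table | swappable CSV |
| non-canonical residues | error | or `drop`, which shortens L and every τ denominator — deliberate opt-in |

The source study does not name its index tables or weight; the defaults here
are the tables and weight of the classic amphiphilic pseudo-composition
web-server formulation. `compare_feature_matrices` exists precisely to
calibrate these choices against an externally computed feature matrix (it
reports per-column maximum absolute deviation); until such a matrix is
supplied, features computed here are internally consistent but not verified
against the original extraction.

### Numerical notes and degenerate inputs

- The τ computation is vectorized (`dot` over shifted slices); a double-loop
  oracle in the tests pins it to 1e-12.
- The denominator `1 + w·Στ` can be non-positive when Στ is strongly
  negative (anticorrelated sequences under a large w). This raises an
  explicit normalization error naming the sequence rather than clipping,
  because a clipped vector would silently break the sum-to-one contract.
- λ = 0 reduces exactly to plain amino-acid composition; w = 0 zeroes the
  order terms.
- Reversing a sequence leaves the whole vector unchanged (each pair multiset
  is reversal-invariant); permuting residues changes only the order terms.

## Halo classes and assay selection

Halo diameters bin into Low (< 3.5 mm), Medium (3.5–5.5 mm inclusive) and
High (> 5.5 mm). Boundary diameters are Medium because the study's table
labels 3.5 mm halos M while its text assigns only strictly smaller halos to
L. On the packaged 41-strain table this rule reproduces the printed class
for 40 rows; strain t41a (5 mm, printed High) is the documented exception
and is stored verbatim. The assay-selection cutoff defaults to 4.0 mm: the
nominal "above 3.5 mm" rule would select 29 strains, whereas exactly the 28
strains with halo ≥ 4.0 mm carry activities. Both knobs are configurable.

## Models

Nearest-neighbour prediction is implemented natively because it is the only
learner whose published jackknife cells are exactly reproducible: with
uniform weights and Euclidean distance the whole path is deterministic once
ties are fixed. Ties in distance rank by training-row index (stable sort);
classification vote ties go to the tied class seen earliest in the
neighbour ranking. Features are not standardized before distance computation
— the encoding already normalizes every vector to unit sum — but a
`standardize` switch wraps any model in a scaler for sensitivity checks.

The other learners are configured scikit-learn estimators: linear-kernel
SVM (C = 1.0, ε = 0.1 — unstated in the source and documented as
non-reproducible knobs), Gaussian naive Bayes, a 10-tree random-forest
regressor (unlimited depth, all features per split), and AdaBoost fusing 50
regression trees (min 2 per leaf, min 5 per internal node, depth ≤ 100).
The 30-tree random-forest classifier decides by hard majority vote over the
individual trees, with per-class vote fractions as ranking scores; this is a
thin wrapper because the stock implementation averages soft probabilities
instead.

## Validation and metrics

Both schemes pool out-of-fold predictions (exactly one per sample) and
compute each metric suite once on the pooled vectors. Stratified 10-fold
splitting applies to the classification target; a continuous regression
target cannot be stratified, so regression uses plain shuffled k-fold.
Multiclass AUC is one-vs-rest, prevalence-weighted; F1/precision/recall are
support-weighted. R² is computed about the mean of the pooled true values,
which is why jackknifed regressions can go negative: each held-out
prediction is made without the held-out point, so pooled squared error may
exceed total variance. Only native-KNN jackknife cells are declared exact
reproductions; every 10-fold, SVM, AdaBoost, forest and naive-Bayes cell is
emitted with an `approximate` flag plus the seed and configuration used.

## The synthetic study generator

The generator emulates the statistical structure the method assumes, not
xylanase biochemistry: residues are i.i.d. (uniform by default; a fixed
GH11-like composition — a synthetic profile, rich in G/S/T/N/Y, nearly
cysteine-free — is available for composition-sensitivity tests), activities
are linear in the true 34 features with per-condition Gaussian coefficients
(scale 2000, intercept 350 IU ml⁻¹, chosen so simulated activities span the
0–900 IU ml⁻¹ range of the real assays) plus Gaussian noise of SD σ
(default 50 IU ml⁻¹, mild relative to the ≈150–200 IU ml⁻¹ signal SD),
clipped at zero with the clip count surfaced. Halo diameters are a monotone
min–max map of mean activity onto 2–8 mm plus optional noise, labelled
through the threshold rule. Default problem sizes: 41 strains of length
180–230; the recovery checks in the tests use 120–200 sequences to keep the
leave-one-out loops fast.

What passing synthetic tests show — and what they do not: they certify that
the pipeline recovers a planted sequence–activity relationship and degrades
monotonically with noise (jackknife MSE strictly increases with σ; the
noiseless R² at n = 200 reaches ≈ 0.5–0.6). They do not certify performance
on real xylanases, whose sequences are highly similar family variants
(dense local neighbourhoods) rather than i.i.d. strings: i.i.d. features in
34 dimensions leave 5-NN with an irreducible bias floor, which is why the
noiseless R² plateaus near 0.5 here instead of approaching 1, and why
thresholded halo classes (which place samples arbitrarily close to the
class boundaries) cap jackknife accuracy near 0.65 rather than the near-
perfect separation reported on the real strain panel. The separable-
classification property is therefore exercised on well-separated blob
constructions instead.

## Known limitations

- The published supplementary feature matrix and the 41 sequences are not
  redistributable with the package; the exact-reproduction checks against
  the published jackknife cells run only when the user supplies the
  spreadsheet at `data/s1_pseaac_features.xlsx`, and the index-table/weight
  calibration is open until then.
- SVM probability calibration, the 10-fold seed, and several ensemble
  details of the original analysis are unknown; those cells are approximate
  by construction.
- Activities are treated as exact integers in IU ml⁻¹; no assay-error model
  is applied to the real table.
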