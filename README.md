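# dbpkit

Staged feature selection and accuracy-weighted soft-voting ensembles for
sequence-based **DNA-binding protein (DBP) classification**, built on
residue-level protein representations.

A protein of length *L* enters as an *L* × *d* matrix: either a PSI-BLAST
position-specific scoring matrix (PSSM, *d* = 20 log-odds mutation scores
per position) or a per-residue embedding from a pretrained protein
language model (e.g. *d* = 1280 for ESM-1b). `dbpkit` is for researchers
who want to compare such representations on the same footing: it pools
both into one unified sequence-level descriptor family, pushes them
through an identical selection/evaluation protocol, and combines the
resulting models.

## The method

Each raw matrix is squashed entrywise with the logistic sigmoid, giving
`R = {R_1, …, R_L}`, `R_i ∈ (0,1)^d`. Four averaging operators pool it:

| block | definition | width |
|---|---|---|
| `Avg` | `(1/L) Σ_i R_i` | *d* |
| `Sep(k, s)` | mean of `R_s, R_{s+k}, R_{s+2k}, …` over `N_{k,s} = ⌊(L−s+k)/k⌋` rows, for `k ∈ {2,3}`, `s = 1..k` | 5 *d* |
| `AA(t)` | mean of `R_i` over residues of amino-acid type `t` (20 standard types; zero vector if absent) | 20 *d* |
| `Corr(φ)` | `(1/(L−φ)) Σ_i (R_i − R_{i+φ}) ⊙ (R_i − R_{i+φ})`, the PsePSSM-style sequence-order term, `φ ∈ {1,2,3}` | 3 *d* |

Concatenated in that order this yields **29 d named features** per protein
— 580 for a PSSM, 37 120 for an ESM-1b embedding.

On a labelled feature table the protocol then runs: MinMax normalization →
stratified 5-fold cross-validation (metrics ACC, MCC, SN, SP pooled from
held-out confusion counts) → stage-1 selection (variance / χ² / MIC
filters and LR / linear-SVM / random-forest importances, cut at top
10–80 %, refined to 1–9 % when the optimum sits at the grid boundary;
plus Lasso / LassoLars / ElasticNet supports) → stage-2 recursive feature
elimination with CV. One model per surviving selection is trained; the
full configuration yields **34 members** which are soft-voted with
weights `w_i = ACC_i / Σ_k ACC_k` from their CV accuracies:
`p_c = Σ_i w_i p_{i,c}`.

The hand-authored maximal-information-coefficient (MIC) ranking uses an
exact dynamic program over one axis with the other rank-equipartitioned,
under the grid bound `B(n) = max(n^0.6, 4)`; it is verified in the tests
against exhaustive grid enumeration.

## Worked example

```python
import dbpkit as dk

# a two-class synthetic dataset: 30+30 proteins, PSSM-like 20-dim matrices,
# a 0.3-sigma raw-score shift planted on 5 informative dimensions
spec = dk.SyntheticSpec(n_pos=30, n_neg=30, d=20, length_range=(50, 80),
                        informative_dims=5, effect_size=0.3, kind="pssm",
                        seed=42)
records, matrices, labels = dk.generate_dataset(spec)
pairs = [(r, dk.sigmoid_normalize(m)) for r, m in zip(records, matrices)]
table = dk.build_table(pairs, labels, dk.FeatureSetSpec(d=20))
print(f"feature table: {table.n_samples} proteins x {table.n_features} features")

ranking = dk.score_embedded(dk.minmax_normalize(table), "lr", seed=0)
subset = dk.select_top_percent(ranking, 20)
print(f"{subset.origin}: kept {len(subset.selected_names)} of {table.n_features} features")

for name, sub in [("NFS", table), ("LR20", table.subset(subset.selected_names))]:
    m = dk.cross_validate(sub, "svm-rbf", folds=5, seed=0).pooled
    print(f"{name:5s} 5-fold CV (pooled): ACC={m.ACC:.4f} MCC={m.MCC:.4f} "
          f"SN={m.SN:.4f} SP={m.SP:.4f}")
```

prints

```
feature table: 60 proteins x 580 features
LR20: kept 116 of 580 features
NFS   5-fold CV (pooled): ACC=0.8833 MCC=0.7671 SN=0.9000 SP=0.8667
LR20  5-fold CV (pooled): ACC=1.0000 MCC=1.0000 SN=1.0000 SP=1.0000
```

The 580-feature table is the full descriptor assembly at *d* = 20; `LR20`
is the top-20 % cut (⌈0.2 · 580⌉ = 116 features) of the
logistic-regression importance ranking, which here lifts the pooled CV
accuracy of the Gaussian-kernel SVM from 0.88 (no selection, `NFS`) to
1.00 — the planted 5-dimension signal is strong enough that a ranked
subset separates the classes perfectly while the full table dilutes it.

A `dbpkit` console script exposes the same stages for shell use:
`simulate`, `extract`, `rank`, `select`, `cv`, `rfe`, `ensemble` and
`run-all` (see `dbpkit --help`).

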