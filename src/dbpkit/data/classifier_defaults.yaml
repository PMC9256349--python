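# Pinned default hyperparameters of the classifier roster, version-tagged so
# reports can cite the exact configuration they were produced under.
version: 1
classifiers:
  gnb: {}
  knn: {n_neighbors: 5}
  dt: {}
  lr: {max_iter: 2000}
  svm-rbf: {kernel: rbf, C: 1.0, gamma: scale, probability: true}
  linsvm: {kernel: linear, C: 1.0, probability: true}
  rf: {n_estimators: 100}
  gbdt: {n_estimators: 100}
  xgb: {n_estimators: 100, eval_metric: logloss, verbosity: 0}
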