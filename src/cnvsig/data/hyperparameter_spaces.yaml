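# Randomized-search spaces per architecture. Values are sampled uniformly
# (with a fixed seed) by sklearn's ParameterSampler; lists enumerate the
# admissible settings for each hyperparameter.
random_forest:
  n_estimators: [50, 100, 200, 300, 500]
  max_depth: [null, 4, 8, 12, 16, 24]
  min_samples_split: [2, 4, 8, 16]
  min_samples_leaf: [1, 2, 4, 8]
  max_features: [sqrt, log2, 0.5, null]
  class_weight: [null, balanced]
extra_trees:
  n_estimators: [50, 100, 200, 300, 500]
  max_depth: [null, 4, 8, 12, 16, 24]
  min_samples_split: [2, 4, 8, 16]
  min_samples_leaf: [1, 2, 4, 8]
  max_features: [sqrt, log2, 0.5, null]
gradient_boosting:
  n_estimators: [50, 100, 200]
  learning_rate: [0.01, 0.05, 0.1, 0.2]
  max_depth: [2, 3, 4, 6]
  subsample: [0.6, 0.8, 1.0]
hist_gradient_boosting:
  max_iter: [50, 100, 200]
  learning_rate: [0.01, 0.05, 0.1, 0.2]
  max_depth: [null, 3, 6, 12]
  min_samples_leaf: [5, 10, 20, 40]
logistic_regression:
  C: [0.01, 0.1, 1.0, 10.0, 100.0]
  penalty: [l2]
  class_weight: [null, balanced]
decision_tree:
  max_depth: [null, 2, 4, 8, 16]
  min_samples_split: [2, 4, 8, 16]
  min_samples_leaf: [1, 2, 4, 8]
  criterion: [gini, entropy]
knn:
  n_neighbors: [3, 5, 9, 15, 25]
  weights: [uniform, distance]
  p: [1, 2]
gaussian_nb:
  var_smoothing: [1.0e-11, 1.0e-9, 1.0e-7, 1.0e-5]
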